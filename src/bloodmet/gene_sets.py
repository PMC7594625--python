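"""Gene-set scoring by average sign probability.

Collections are read from GMT files (one set per line: name, description,
then member symbols, tab-separated — the MSigDB dialect).  A set's score
is the arithmetic mean of the sign probabilities of its members that are
present in the expression data; members that were not measured carry no
evidence and are excluded from the mean, with the measured-member count
reported so the choice is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

TOY_GMT = Path(__file__).parent / "data" / "toy_sets.gmt"


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets with optional descriptions."""

    name: str
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate symbols within set {set_name!r}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file into a collection.

    Duplicate symbols within a line are kept once (warning); a line with
    fewer than three fields is a parse error naming the line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs set name, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            set_name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning("%s:%d: duplicated symbols in %s deduplicated",
                               path.name, lineno, set_name)
            if set_name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate set name {set_name!r}")
            sets[set_name] = unique
            descriptions[set_name] = desc
    return GeneSetCollection(name=name or path.stem, sets=sets, descriptions=descriptions)


def set_sign_scores(
    collection: GeneSetCollection,
    sign_probs: Mapping[str, float],
) -> pd.DataFrame:
    """Average sign probability per set over its measured members.

    Returns a table with columns ``set``, ``score``, ``n_measured`` and
    ``n_members``.  Sets without any measured member are skipped with a
    warning.
    """
    if len(collection) == 0:
        raise ValueError("cannot score an empty collection")
    rows = []
    for set_name, members in collection.sets.items():
        measured = [g for g in members if g in sign_probs]
        if not measured:
            logger.warning("set %s has no measured members; skipped", set_name)
            continue
        score = sum(sign_probs[g] for g in measured) / len(measured)
        rows.append({"set": set_name, "score": score,
                     "n_measured": len(measured), "n_members": len(members)})
    return pd.DataFrame(rows, columns=["set", "score", "n_measured", "n_members"])


def rank_sets(scores: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Top-k sets by average sign probability, descending.

    Ties break by measured-member count (descending) then set name.
    ``k`` larger than the number of scored sets returns the full ordering.
    """
    if scores.empty:
        raise ValueError("no scored sets to rank")
    ordered = scores.sort_values(
        by=["score", "n_measured", "set"], ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out = ordered.head(k).copy()
    out.insert(0, "rank", range(1, len(out) + 1))
    return out


def genes_in_multiple_sets(
    top_sets: list[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Genes appearing in at least two of the given top sets.

    Returns columns ``gene``, ``n`` and ``sets`` (comma-joined sorted set
    names), ordered by count descending then gene symbol.
    """
    membership: dict[str, list[str]] = {}
    for set_name in top_sets:
        for g in collection.sets.get(set_name, []):
            membership.setdefault(g, []).append(set_name)
    rows = [
        {"gene": g, "n": len(names), "sets": ", ".join(sorted(names))}
        for g, names in membership.items() if len(names) >= 2
    ]
    rows.sort(key=lambda r: (-r["n"], r["gene"]))
    return pd.DataFrame(rows, columns=["gene", "n", "sets"])
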