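"""Beadchip preprocessing: from raw probe intensities to a standardized
differential-expression matrix.

The chain mirrors a standard whole-blood Illumina workflow for a paired
case-control design:

1. background correction against negative-control probes,
2. log2 transform,
3-4. detection filter (detected means detection p < 0.01; probes detected
   in fewer than 15% of samples are dropped),
5-7. annotation-quality filter and probe-to-gene collapse keeping, per
   gene, the probe with the largest inter-quartile range,
8. per-pair differential expression (case minus matched control),

followed by a low-variation gene filter (|mean| > 20 x SD removed) and
per-gene standardization to mean zero / unit SD.

Every filtering step logs how many rows it removed; the convenience driver
:func:`preprocess_bundle` returns the full audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .config import STRATA

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import RawIntensityBundle

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DesignTable:
    """Per-sample study metadata for a paired case-control design.

    ``frame`` holds one row per sample with columns ``pair_id``, ``role``
    (case/control), ``detection_mode`` (screening/interval; required for
    cases), ``metastasis`` (0/1; required for cases) and any optional
    covariates (age, BMI, smoking, HT use, parity).
    """

    frame: pd.DataFrame

    REQUIRED = ("pair_id", "role", "detection_mode", "metastasis")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        roles = set(df["role"].unique())
        if not roles <= {CASE, CONTROL}:
            raise ValueError(f"unknown roles: {roles - {CASE, CONTROL}}")
        counts = df.groupby("pair_id")["role"].agg(list)
        for pid, rs in counts.items():
            if sorted(rs) != [CASE, CONTROL]:
                raise ValueError(
                    f"pair {pid!r} must appear exactly twice, once per role; got {rs}"
                )
        cases = self.cases
        if cases["detection_mode"].isna().any() or cases["metastasis"].isna().any():
            raise ValueError("every case needs a detection mode and metastasis status")
        bad_mode = set(cases["detection_mode"].unique()) - set(STRATA)
        if bad_mode:
            raise ValueError(f"unknown detection modes: {bad_mode}")

    @property
    def cases(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == CASE]

    @property
    def pair_ids(self) -> list:
        """Pair ids in order of first appearance."""
        return list(dict.fromkeys(self.frame["pair_id"]))

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def pair_frame(self) -> pd.DataFrame:
        """One row per pair with the case's detection mode and outcome."""
        cases = self.cases.set_index("pair_id")
        return cases.loc[self.pair_ids, ["detection_mode", "metastasis"]]

    def sample_id(self, pair_id, role: str) -> str:
        return f"{pair_id}_{role}"

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DesignTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


@dataclass
class DiffExpressionMatrix:
    """Genes x pairs matrix of differential log2 expression.

    ``values`` is indexed by unique gene symbol with one column per
    case-control pair (case minus control, log2 scale).  After
    :func:`standardize_genes`, ``standardized`` is True and ``center`` /
    ``scale`` record the per-gene mean and population SD that were removed.
    """

    values: pd.DataFrame
    standardized: bool = False
    center: pd.Series | None = None
    scale: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dupes)[:5]}")
        if self.standardized:
            vals = self.values.to_numpy(float)
            if not np.allclose(vals.mean(axis=1), 0.0, atol=1e-6):
                raise ValueError("standardized matrix must have per-gene mean 0")
            if not np.allclose(vals.std(axis=1), 1.0, atol=1e-6):
                raise ValueError("standardized matrix must have per-gene SD 1")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    def gene(self, symbol: str) -> np.ndarray:
        return self.values.loc[symbol].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "DiffExpressionMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene")
        return cls(df, **kwargs)


@dataclass
class AuditTrail:
    """Row-count bookkeeping across the preprocessing chain."""

    steps: list[dict] = field(default_factory=list)

    def record(self, step: str, removed: int, remaining: int) -> None:
        self.steps.append({"step": step, "removed": int(removed), "remaining": int(remaining)})
        logger.info("%s: removed %d, %d remaining", step, removed, remaining)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "removed", "remaining"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

def background_correct(raw: "RawIntensityBundle", floor: float = 1.0) -> pd.DataFrame:
    """Subtract each sample's mean negative-control intensity.

    Corrected values below ``floor`` are clipped to ``floor`` so the
    subsequent log2 transform is defined.  The number of floored entries is
    stored in ``result.attrs['n_floored']``.
    """
    if raw.negctrl is None or raw.negctrl.empty:
        raise ValueError("background correction requires negative-control probes")
    bg = raw.negctrl.mean(axis=0)
    corrected = raw.intensities.sub(bg, axis=1)
    n_floored = int((corrected < floor).to_numpy().sum())
    corrected = corrected.clip(lower=floor)
    corrected.attrs["n_floored"] = n_floored
    if n_floored:
        logger.info("background correction floored %d entries at %g", n_floored, floor)
    return corrected


def log2_transform(corrected: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; input must be strictly positive."""
    vals = corrected.to_numpy(float)
    if (vals <= 0).any():
        raise ValueError("log2 transform requires strictly positive intensities")
    return pd.DataFrame(np.log2(vals), index=corrected.index, columns=corrected.columns)


def detection_pvalues(raw: "RawIntensityBundle") -> pd.DataFrame:
    """Empirical detection p-values against the negative controls.

    For probe g in sample j: the proportion of that sample's
    negative-control intensities that are >= the probe's intensity.  Small
    p means the probe clearly exceeds background.
    """
    if raw.negctrl is None or raw.negctrl.empty:
        raise ValueError("detection p-values require negative-control probes")
    neg = raw.negctrl.to_numpy(float)              # (n_ctrl, n_samples)
    obs = raw.intensities.to_numpy(float)          # (n_probes, n_samples)
    # column-wise exceedance via sorted controls
    p = np.empty_like(obs)
    for j in range(obs.shape[1]):
        srt = np.sort(neg[:, j])
        # number of controls >= value = n - searchsorted_left(value)
        p[:, j] = (len(srt) - np.searchsorted(srt, obs[:, j], side="left")) / len(srt)
    return pd.DataFrame(p, index=raw.intensities.index, columns=raw.intensities.columns)


def detection_filter(
    log_matrix: pd.DataFrame,
    detect_p: pd.DataFrame,
    p_threshold: float = 0.01,
    min_frac: float = 0.15,
) -> pd.DataFrame:
    """Drop probes not reliably detected.

    A probe counts as detected in a sample when its detection p-value is
    below ``p_threshold``; probes detected in fewer than ``min_frac`` of
    samples are removed.  A probe detected in exactly ``min_frac`` of
    samples is retained (boundary kept).
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must lie in (0, 1]")
    detected = (detect_p.loc[log_matrix.index, log_matrix.columns] < p_threshold)
    frac = detected.mean(axis=1)
    keep = frac >= min_frac
    removed = int((~keep).sum())
    logger.info("detection filter removed %d of %d probes", removed, len(keep))
    out = log_matrix.loc[keep]
    out.attrs["n_removed"] = removed
    return out


def collapse_probes(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Low-quality-annotation filter plus probe-to-gene collapse.

    ``annotation`` needs columns ``probe_id``, ``symbol`` and ``quality``
    (``high`` / ``low``).  Probes flagged ``low`` are dropped; among the
    remaining probes sharing a gene symbol, the one with the largest
    inter-quartile range of its measurements is kept.  IQR ties keep the
    first probe in input order (logged).
    """
    ann = annotation.set_index("probe_id")
    unannotated = matrix.index.difference(ann.index)
    if len(unannotated):
        raise ValueError(f"unannotated probes: {list(unannotated)[:5]}")
    ann = ann.loc[matrix.index]
    low = ann["quality"] == "low"
    n_low = int(low.sum())
    if n_low:
        logger.info("removed %d probes with low annotation quality", n_low)
    kept = matrix.loc[~low.to_numpy()]
    symbols = ann.loc[~low.to_numpy(), "symbol"]

    vals = kept.to_numpy(float)
    q75, q25 = np.percentile(vals, [75, 25], axis=1)
    iqr = pd.Series(q75 - q25, index=kept.index)

    pos = {p: i for i, p in enumerate(kept.index)}
    chosen: list = []
    for sym, probe_ids in symbols.groupby(symbols, sort=False).groups.items():
        probe_ids = list(probe_ids)  # groupby preserves input order within groups
        sub = iqr.loc[probe_ids]
        best = sub.max()
        winners = [p for p in probe_ids if sub[p] == best]
        if len(winners) > 1:
            logger.info("IQR tie for gene %s among %s; keeping %s", sym, winners, winners[0])
        chosen.append((sym, winners[0]))
    chosen.sort(key=lambda t: pos[t[1]])
    out = kept.loc[[p for _, p in chosen]]
    out.index = pd.Index([s for s, _ in chosen], name="gene")
    out.attrs["n_low_quality"] = n_low
    out.attrs["n_collapsed"] = len(kept) - len(out)
    return out


def differential_expression(gene_matrix: pd.DataFrame, design: DesignTable) -> DiffExpressionMatrix:
    """Per-pair case-minus-control difference on the log2 scale.

    Any additive offset shared by both members of a pair (a batch effect,
    when pairs are processed together) cancels exactly.
    """
    cols = set(gene_matrix.columns)
    diffs = {}
    for pid in design.pair_ids:
        case_id = design.sample_id(pid, CASE)
        ctrl_id = design.sample_id(pid, CONTROL)
        if case_id not in cols or ctrl_id not in cols:
            raise ValueError(f"incomplete pair {pid!r}: need both {case_id} and {ctrl_id}")
        diffs[pid] = gene_matrix[case_id] - gene_matrix[ctrl_id]
    return DiffExpressionMatrix(pd.DataFrame(diffs, index=gene_matrix.index))


def low_variation_filter(diff: DiffExpressionMatrix, ratio: float = 20.0) -> DiffExpressionMatrix:
    """Drop genes whose mean differential signal dwarfs their variation.

    A gene is removed when |mean| > ratio x SD; such genes carry a large
    constant offset but essentially no between-pair variation.  Genes with
    SD exactly 0 are removed and logged as degenerate.
    """
    if diff.standardized:
        raise ValueError("low-variation filter expects unstandardized input")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    vals = diff.values.to_numpy(float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.info("removing %d zero-SD (degenerate) genes", int(degenerate.sum()))
    low_var = np.abs(mean) > ratio * sd
    drop = low_var | degenerate
    logger.info("low-variation filter removed %d of %d genes", int(drop.sum()), len(drop))
    out = DiffExpressionMatrix(diff.values.loc[~drop])
    out.values.attrs["n_removed"] = int(drop.sum())
    return out


def standardize_genes(diff: DiffExpressionMatrix) -> DiffExpressionMatrix:
    """Center and scale each gene to mean 0, SD 1 (population convention).

    The removed mean and SD are stored so effect sizes can be mapped back
    to the log2 scale.  Idempotent up to floating tolerance.
    """
    vals = diff.values.to_numpy(float)
    center = vals.mean(axis=1)
    scale = vals.std(axis=1)  # population SD (divide by n)
    if (scale == 0).any():
        bad = diff.values.index[scale == 0]
        raise ValueError(f"zero-SD genes cannot be standardized: {list(bad)[:5]}")
    std = (vals - center[:, None]) / scale[:, None]
    return DiffExpressionMatrix(
        pd.DataFrame(std, index=diff.values.index, columns=diff.values.columns),
        standardized=True,
        center=pd.Series(center, index=diff.values.index),
        scale=pd.Series(scale, index=diff.values.index),
    )


def preprocess_bundle(
    raw: "RawIntensityBundle",
    design: DesignTable,
    *,
    floor: float = 1.0,
    p_threshold: float = 0.01,
    min_frac: float = 0.15,
    ratio: float = 20.0,
) -> tuple[DiffExpressionMatrix, AuditTrail]:
    """Run the full chain and return the standardized matrix plus audit trail."""
    audit = AuditTrail()
    audit.record("input_probes", 0, raw.intensities.shape[0])

    corrected = background_correct(raw, floor=floor)
    logged = log2_transform(corrected)

    detect_p = detection_pvalues(raw)
    filtered = detection_filter(logged, detect_p, p_threshold=p_threshold, min_frac=min_frac)
    audit.record("detection_filter", len(logged) - len(filtered), len(filtered))

    genes = collapse_probes(filtered, raw.annotation)
    audit.record("annotation_quality", genes.attrs["n_low_quality"],
                 len(filtered) - genes.attrs["n_low_quality"])
    audit.record("probe_collapse", genes.attrs["n_collapsed"], len(genes))

    diff = differential_expression(genes, design)
    kept = low_variation_filter(diff, ratio=ratio)
    audit.record("low_variation_filter", diff.n_genes - kept.n_genes, kept.n_genes)

    std = standardize_genes(kept)
    audit.record("standardize", 0, std.n_genes)
    return std, audit
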