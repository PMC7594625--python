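"""End-to-end orchestration, study-summary tables and the exclusion ledger.

:func:`run_pipeline` composes the whole analysis on a synthetic study:
simulate a paired cohort and its raw beadchip bundle, preprocess to a
standardized differential matrix, fit the per-gene hierarchical model,
summarize excess risk, rank genes and gene sets, and write every table as
tab-separated text with the run seed in the header, plus an audit log and
a machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

from . import __version__
from .config import INTERVAL, SCREENING, GeneModelConfig
from .gene_sets import TOY_GMT, genes_in_multiple_sets, rank_sets, read_gmt, set_sign_scores
from .model import fit_genes, per_gene_seed
from .preprocess import DesignTable, preprocess_bundle
from .risk import (estimate_detection_weights, prior_predictive, rank_genes,
                   summarize_gene)
from .synthetic import (DEFAULT_P_SCREEN, simulate_differential_cohort,
                        simulate_parameters, simulate_raw_beadchip, write_bundle)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    When the four input paths (probes, negctrl, annotation, design) are
    all set, the pipeline analyses those files; otherwise it simulates a
    study of ``n_genes`` genes and ``n_pairs`` case-control pairs.
    """

    out_dir: str = "bloodmet_run"
    seed: int = 0
    # simulation block
    n_genes: int = 30
    n_pairs: int = 60
    p_screen: float = DEFAULT_P_SCREEN
    # optional file inputs
    probes: str | None = None
    negctrl: str | None = None
    annotation: str | None = None
    design: str | None = None
    gmt: str | None = None
    # model + ranking
    chains: int = 4
    warmup: int = 300
    draws: int = 500
    z: float = 0.1
    max_rhat: float = 1.01
    min_ess: float = 0.0  # 0 -> min(400, half the total draw count)
    genes_k: int = 100
    sets_k: int = 50
    verbosity: str = "INFO"

    def model_config(self) -> GeneModelConfig:
        min_ess = self.min_ess or min(400.0, self.chains * self.draws / 2)
        return GeneModelConfig(chains=self.chains, warmup=self.warmup,
                               draws=self.draws, z=self.z, seed=self.seed,
                               max_rhat=self.max_rhat, min_ess=min_ess)

    @property
    def has_file_inputs(self) -> bool:
        paths = (self.probes, self.negctrl, self.annotation, self.design)
        if any(paths) and not all(paths):
            raise ValueError("probes, negctrl, annotation and design must be set together")
        return all(paths)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a plain ``key = value`` text file ('#' comments)."""
        kwargs: dict = {}
        types = {f.name: f.type for f in dc_fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (t.strip() for t in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                ann = str(types[key])
                if "int" in ann:
                    kwargs[key] = int(value)
                elif "float" in ann:
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bloodmet {__version__}\tseed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


@dataclass
class Crosstab:
    """Detection mode x metastasis status summary of the cases."""

    counts: pd.DataFrame  # index screening/interval, columns non_met / met

    @classmethod
    def from_counts(cls, screening_non_met: int, screening_met: int,
                    interval_non_met: int, interval_met: int) -> "Crosstab":
        counts = pd.DataFrame(
            {"non_metastasized": [screening_non_met, interval_non_met],
             "metastasized": [screening_met, interval_met]},
            index=pd.Index([SCREENING, INTERVAL], name="detection_mode"),
        )
        return cls(counts)

    @classmethod
    def from_design(cls, design: DesignTable) -> "Crosstab":
        cases = design.cases
        if cases["detection_mode"].isna().any() or cases["metastasis"].isna().any():
            raise ValueError("crosstab needs complete case metadata")
        n = {(m, int(y)): 0 for m in (SCREENING, INTERVAL) for y in (0, 1)}
        for _, row in cases.iterrows():
            n[(row["detection_mode"], int(row["metastasis"]))] += 1
        return cls.from_counts(n[(SCREENING, 0)], n[(SCREENING, 1)],
                               n[(INTERVAL, 0)], n[(INTERVAL, 1)])

    @property
    def pct_without_metastasis(self) -> pd.Series:
        """Percent of each detection mode's cases that did not metastasize."""
        non = self.counts["non_metastasized"]
        return (100 * non / self.counts.sum(axis=1)).round().astype(int)

    @property
    def pct_screening_detected(self) -> pd.Series:
        """Percent of each metastasis group that was screening-detected."""
        scr = self.counts.loc[SCREENING]
        tot = self.counts.sum(axis=0)
        return (100 * scr / tot).round().astype(int)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["pct_without_metastasis"] = self.pct_without_metastasis
        return out


def crosstab_detection_metastasis(design: DesignTable) -> Crosstab:
    """2x2 detection-mode / metastasis summary with row percentages."""
    return Crosstab.from_design(design)


def exclusion_ledger(
    initial_pairs: int,
    exclusions: list[tuple[str, int]],
) -> tuple[int, pd.DataFrame]:
    """Sequential case-control pair exclusions with named reasons."""
    if initial_pairs < 0:
        raise ValueError("initial count must be non-negative")
    rows = [{"reason": "initial", "removed": 0, "remaining": initial_pairs}]
    remaining = initial_pairs
    for reason, count in exclusions:
        if count < 0:
            raise ValueError(f"negative exclusion count for {reason!r}")
        remaining -= count
        if remaining < 0:
            raise ValueError(f"exclusion {reason!r} drives the pair count negative")
        rows.append({"reason": reason, "removed": int(count), "remaining": remaining})
    return remaining, pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute preprocess -> per-gene fits -> risk statistics -> gene sets.

    Returns a dict with the main in-memory results and writes all output
    tables under ``config.out_dir``.  Fully deterministic for a fixed
    seed: per-gene sampler seeds are derived from the global seed by gene
    index, so serial and parallel execution agree.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    root_logger = logging.getLogger("bloodmet")
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger.addHandler(log_handler)
    try:
        return _run_pipeline_inner(config, out, seed)
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()


def _run_pipeline_inner(config: RunConfig, out: Path, seed: int) -> dict:

    if config.has_file_inputs:
        from .synthetic import RawIntensityBundle
        design = DesignTable.from_tsv(config.design)
        bundle = RawIntensityBundle(
            intensities=pd.read_csv(config.probes, sep="\t", comment="#", index_col="probe_id"),
            negctrl=pd.read_csv(config.negctrl, sep="\t", comment="#", index_col="probe_id"),
            annotation=pd.read_csv(config.annotation, sep="\t", comment="#"),
            ledger={},
        )
    else:
        params = simulate_parameters(config.n_genes, seed=seed)
        diff0, design, cohort_ledger = simulate_differential_cohort(
            params, config.n_pairs, p_screen=config.p_screen, seed=seed,
            mode="causal_set",
        )
        bundle = simulate_raw_beadchip(design, config.n_genes, seed=seed,
                                       diff_signal=diff0.values)
        write_bundle(bundle, design, out / "inputs")

    std, audit = preprocess_bundle(bundle, design)
    audit.to_tsv(out / "audit_log.tsv")

    weights = estimate_detection_weights(design)
    pairs = design.pair_frame()
    y = pairs["metastasis"].astype(int).to_numpy()
    s = pairs["detection_mode"].to_numpy()

    model_cfg = config.model_config()
    fits = fit_genes(std.values, y, s, model_cfg)

    diagnostics = pd.concat([f.diagnostics for f in fits.values()], ignore_index=True)
    _write_tsv(diagnostics, out / "diagnostics.tsv", seed)

    summaries = [
        summarize_gene(fits[g], weights, z=config.z,
                       seed=per_gene_seed(seed ^ 0x5EED, i))
        for i, g in enumerate(std.genes)
    ]
    ranking = rank_genes(summaries, k=config.genes_k)
    _write_tsv(ranking, out / "gene_ranking.tsv", seed)

    collection = read_gmt(config.gmt or TOY_GMT)
    sign_probs = {s_.gene: s_.sign_prob for s_ in summaries if s_.converged}
    scores = set_sign_scores(collection, sign_probs)
    outputs = {"ranking": ranking, "diagnostics": diagnostics, "audit": audit,
               "weights": weights, "summaries": summaries, "design": design}
    if not scores.empty:
        top_sets = rank_sets(scores, k=config.sets_k)
        top20 = rank_sets(scores, k=20)
        multi = genes_in_multiple_sets(top_sets["set"].tolist(), collection)
        _write_tsv(top_sets, out / "gene_set_ranking_top50.tsv", seed)
        _write_tsv(top20, out / "gene_set_ranking_top20.tsv", seed)
        _write_tsv(multi, out / "genes_in_multiple_sets.tsv", seed)
        outputs.update({"set_ranking": top_sets, "set_ranking_top20": top20,
                        "multiplicity": multi})

    pp = prior_predictive(model_cfg, n_draws=200_000, seed=seed)
    pp_row = {"z": config.z, "central60_half_width": pp.half_width(0.6)}
    pp_row.update(pp.quantiles())
    _write_tsv(pd.DataFrame([pp_row]), out / "prior_predictive.tsv", seed)

    crosstab = crosstab_detection_metastasis(design)
    _write_tsv(crosstab.to_frame(), out / "crosstab.tsv", seed, index=True)
    outputs["crosstab"] = crosstab

    n_unconverged = sum(1 for s_ in summaries if not s_.converged)
    manifest = {
        "package": "bloodmet",
        "version": __version__,
        "seed": seed,
        "n_pairs": design.n_pairs,
        "n_genes_input": int(bundle.intensities.shape[0]),
        "n_genes_analyzed": std.n_genes,
        "n_unconverged": n_unconverged,
        "detection_weights": {"screening": weights.p_screening,
                              "interval": weights.p_interval},
        "audit": audit.steps,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    outputs["manifest"] = manifest
    return outputs
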