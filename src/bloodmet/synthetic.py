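"""Synthetic study generator with known ground truth.

Two layers of simulation are provided:

* :func:`simulate_parameters` / :func:`simulate_differential_cohort` draw
  gene-level parameters from the model's own generative hierarchy and then
  simulate a paired case-control cohort (standardized differential log2
  expression, detection modes, binary metastasis outcomes).  This is the
  fixture for parameter recovery, calibration and ranking experiments.

* :func:`simulate_raw_beadchip` builds a raw probe-level intensity bundle
  (signal probes, negative controls, below-detection probes, rarely
  detected probes, duplicated probes with crafted IQRs, low-annotation
  probes, near-constant genes) together with a ground-truth ledger of the
  survivor count expected after each preprocessing filter, so the whole
  preprocessing chain can be asserted exactly.

The raw-intensity model is log-normal signal around a per-probe baseline
plus additive background matching the negative-control distribution.  It
emulates the shape of beadchip data, not scanner physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import INTERVAL, SCREENING, PriorConfig
from .preprocess import CASE, CONTROL, DesignTable, DiffExpressionMatrix

DEFAULT_P_SCREEN = 111 / 156  # screening share of cases in the study design


# ---------------------------------------------------------------------------
# parameters and cohort
# ---------------------------------------------------------------------------

@dataclass
class TrueParameters:
    """Ground-truth gene-level parameters of the generative hierarchy."""

    alpha_screen: np.ndarray
    alpha_interval: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    beta_screen: np.ndarray
    beta_interval: np.ndarray
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.alpha_screen)
        arrays = (self.alpha_interval, self.mu, self.sigma,
                  self.beta_screen, self.beta_interval)
        if any(len(a) != n for a in arrays):
            raise ValueError("parameter arrays must all have length n_genes")
        if not (np.asarray(self.sigma) > 0).all():
            raise ValueError("sigma must be strictly positive for every gene")
        if not self.genes:
            self.genes = [f"G{i + 1:04d}" for i in range(n)]
        elif len(self.genes) != n:
            raise ValueError("genes must have length n_genes")

    @property
    def n_genes(self) -> int:
        return len(self.alpha_screen)

    def alpha(self, stratum: str) -> np.ndarray:
        return self.alpha_screen if stratum == SCREENING else self.alpha_interval

    def beta(self, stratum: str) -> np.ndarray:
        return self.beta_screen if stratum == SCREENING else self.beta_interval


def simulate_parameters(
    n_genes: int,
    hyper: PriorConfig = PriorConfig(),
    seed: int = 0,
) -> TrueParameters:
    """Draw gene-level parameters exactly from the prior hierarchy.

    Per gene and stratum: alpha ~ normal(alpha_loc, alpha_scale); pooled
    slope mean mu ~ normal(mu_loc, mu_scale); slope scale
    sigma = exp(normal(log_sigma_loc, log_sigma_scale)); and per-stratum
    slope beta ~ normal(mu, sigma).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be a positive integer")
    rng = np.random.default_rng(seed)
    alpha_screen = rng.normal(hyper.alpha_loc, hyper.alpha_scale, n_genes)
    alpha_interval = rng.normal(hyper.alpha_loc, hyper.alpha_scale, n_genes)
    mu = rng.normal(hyper.mu_loc, hyper.mu_scale, n_genes)
    sigma = np.exp(rng.normal(hyper.log_sigma_loc, hyper.log_sigma_scale, n_genes))
    if hyper.degenerate:
        # fully degenerate hyperpriors collapse every parameter to its prior
        # mean, slopes included, giving a deterministic parameter set
        beta_screen = mu.copy()
        beta_interval = mu.copy()
    else:
        beta_screen = rng.normal(mu, sigma)
        beta_interval = rng.normal(mu, sigma)
    return TrueParameters(alpha_screen, alpha_interval, mu, sigma,
                          beta_screen, beta_interval)


def simulate_differential_cohort(
    params: TrueParameters,
    n_pairs: int,
    p_screen: float = DEFAULT_P_SCREEN,
    seed: int = 0,
    mode: str = "single_gene",
    causal_genes: list[str] | None = None,
) -> tuple[DiffExpressionMatrix, DesignTable, dict]:
    """Simulate a paired cohort of differential expression and outcomes.

    Each pair gets a detection mode (screening with probability
    ``p_screen``) and per-gene differential expression x ~ normal(0, 1),
    i.e. already on the standardized scale the model expects.  Outcomes:

    ``mode="single_gene"`` (default)
        One outcome vector per gene, generated marginally from that gene's
        own (alpha_s, beta_s) — matching a workflow of independent
        single-gene regressions.  The returned ledger carries the full
        gene x pair outcome matrix ``y_matrix``; the design table's
        ``metastasis`` column holds the first gene's outcomes.

    ``mode="causal_set"``
        One shared outcome per pair driven by a designated causal gene
        set: logit(p) = mean(alpha_s over the set) + sum of beta_s * x
        over the set.  All non-causal genes are pure noise.

    Returns ``(diff, design, ledger)``; the ledger records the true
    outcome-generating mechanism.
    """
    if params.n_genes < 1:
        raise ValueError("params must contain at least one gene")
    if not 0 < p_screen < 1:
        raise ValueError("p_screen must lie strictly between 0 and 1")
    if n_pairs < 1:
        raise ValueError("n_pairs must be a positive integer")
    if mode not in ("single_gene", "causal_set"):
        raise ValueError(f"unknown outcome mode {mode!r}")

    rng = np.random.default_rng(seed)
    pair_ids = [f"P{i + 1:04d}" for i in range(n_pairs)]
    is_screen = rng.random(n_pairs) < p_screen
    modes = np.where(is_screen, SCREENING, INTERVAL)

    x = rng.standard_normal((params.n_genes, n_pairs))
    diff = DiffExpressionMatrix(pd.DataFrame(x, index=params.genes, columns=pair_ids))

    alpha = np.where(is_screen, params.alpha_screen[:, None], params.alpha_interval[:, None])
    beta = np.where(is_screen, params.beta_screen[:, None], params.beta_interval[:, None])

    if mode == "single_gene":
        p = expit(alpha + beta * x)
        y_matrix = (rng.random(p.shape) < p).astype(int)
        y_design = y_matrix[0]
        ledger = {
            "mode": mode,
            "p_screen": p_screen,
            "y_matrix": pd.DataFrame(y_matrix, index=params.genes, columns=pair_ids),
            "causal_genes": None,
        }
    else:
        if causal_genes is None:
            causal_genes = params.genes[: min(5, params.n_genes)]
        idx = [params.genes.index(g) for g in causal_genes]
        logit_p = alpha[idx].mean(axis=0) + (beta[idx] * x[idx]).sum(axis=0)
        y_design = (rng.random(n_pairs) < expit(logit_p)).astype(int)
        ledger = {
            "mode": mode,
            "p_screen": p_screen,
            "y_matrix": None,
            "causal_genes": list(causal_genes),
        }

    rows = []
    for j, pid in enumerate(pair_ids):
        rows.append({"pair_id": pid, "role": CASE, "detection_mode": modes[j],
                     "metastasis": int(y_design[j])})
        rows.append({"pair_id": pid, "role": CONTROL, "detection_mode": modes[j],
                     "metastasis": pd.NA})
    design = DesignTable(pd.DataFrame(rows))
    return diff, design, ledger


# ---------------------------------------------------------------------------
# raw beadchip bundle
# ---------------------------------------------------------------------------

@dataclass
class RawIntensityBundle:
    """Raw probe intensities plus everything preprocessing needs.

    ``intensities``: probes x samples, strictly positive fluorescence.
    ``negctrl``: negative-control probes x samples.
    ``annotation``: probe_id, symbol, quality (high/low).
    ``ledger``: ground truth — which probes are below detection, rare,
    duplicated or near-constant, the expected survivor count after each
    preprocessing filter, and the expected surviving probe per duplicated
    gene.
    """

    intensities: pd.DataFrame
    negctrl: pd.DataFrame
    annotation: pd.DataFrame
    ledger: dict

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy(float) <= 0).any():
            raise ValueError("all probe intensities must be strictly positive")
        if (self.negctrl.to_numpy(float) <= 0).any():
            raise ValueError("all negative-control intensities must be strictly positive")
        if self.intensities.index.has_duplicates:
            raise ValueError("probe ids must be unique")
        if not self.intensities.index.isin(self.annotation["probe_id"]).all():
            raise ValueError("every probe needs an annotation row")
        exp = self.ledger.get("expected_survivors", {})
        counts = list(exp.values())  # insertion order follows the chain
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("ledger survivor counts must be non-increasing along the chain")


def simulate_raw_beadchip(
    design: DesignTable,
    n_genes: int,
    dup_frac: float = 0.1,
    below_detect_frac: float = 0.05,
    rare_frac: float = 0.05,
    low_var_frac: float = 0.1,
    low_qual_frac: float = 0.05,
    n_negctrl: int = 50,
    seed: int = 0,
    diff_signal: pd.DataFrame | None = None,
) -> RawIntensityBundle:
    """Generate a raw intensity bundle exercising every preprocessing filter.

    Genes are partitioned into categories by the given fractions (rounded
    to counts of ``n_genes``): below-detection everywhere, rarely detected
    (in fewer than 15% of samples), low annotation quality, near-constant
    differential signal (|mean| > 20 x SD), and ordinary genes.  A
    ``dup_frac`` share of ordinary genes receives three probes whose
    log-scale amplitudes differ, so their IQR ranking — and hence the probe
    the collapse step must keep — is deterministic.

    ``diff_signal`` (genes x pairs, log2 scale) optionally injects a known
    case-minus-control difference into matching ordinary genes, so a
    cohort simulated on the differential scale can be pushed through the
    whole raw-intensity chain.
    """
    if design.n_pairs < 1:
        raise ValueError("design must contain at least one pair")
    if n_genes < 1:
        raise ValueError("n_genes must be a positive integer")
    if n_negctrl < 1:
        raise ValueError("n_negctrl must be a positive integer")
    fracs = dict(below_detect_frac=below_detect_frac, rare_frac=rare_frac,
                 low_var_frac=low_var_frac, low_qual_frac=low_qual_frac)
    for name, f in fracs.items():
        if not 0 <= f < 1:
            raise ValueError(f"{name} must lie in [0, 1)")
    if not 0 <= dup_frac < 1:
        raise ValueError("dup_frac must lie in [0, 1)")
    if sum(fracs.values()) >= 1:
        raise ValueError("category fractions must sum to less than 1")

    rng = np.random.default_rng(seed)
    n_below = round(below_detect_frac * n_genes)
    n_rare = round(rare_frac * n_genes)
    n_lowq = round(low_qual_frac * n_genes)
    n_lowvar = round(low_var_frac * n_genes)
    n_normal = n_genes - n_below - n_rare - n_lowq - n_lowvar
    if n_normal < 0:
        raise ValueError("category fractions leave no ordinary genes")
    n_dup = round(dup_frac * n_normal)

    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    cat = (["below"] * n_below + ["rare"] * n_rare + ["low_quality"] * n_lowq
           + ["low_var"] * n_lowvar + ["dup"] * n_dup
           + ["normal"] * (n_normal - n_dup))
    rng.shuffle(cat)

    pair_ids = design.pair_ids
    sample_ids = [design.sample_id(p, r) for p in pair_ids for r in (CASE, CONTROL)]
    n_samples = len(sample_ids)

    # background: negative controls around 100 fluorescence units
    neg = np.exp(rng.normal(math.log(100.0), 0.25, (n_negctrl, n_samples)))
    # detected-in-k samples for "rare" probes: just below the 15% boundary
    k_rare = max(0, math.ceil(0.15 * n_samples) - 1)

    def background() -> np.ndarray:
        return np.exp(rng.normal(math.log(100.0), 0.25, n_samples))

    def undetectable() -> np.ndarray:
        # half the background level: far below any plausible negative control
        return 0.55 * background()

    pair_offset = np.repeat(rng.normal(0.0, 0.3, len(pair_ids)), 2)  # shared in pair

    probe_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    ann_rows: list[dict] = []
    dup_survivors: dict[str, str] = {}
    categories: dict[str, str] = {}
    counter = 0

    def new_probe_id() -> str:
        nonlocal counter
        counter += 1
        return f"ILMN_{counter:06d}"

    dup_amps = (0.3, 0.6, 1.2)  # log2 amplitudes -> strictly ordered IQRs

    for g, c in zip(genes, cat):
        categories[g] = c
        if c == "below":
            pid = new_probe_id()
            probe_ids.append(pid)
            probe_rows.append(undetectable())
            ann_rows.append({"probe_id": pid, "symbol": g, "quality": "high"})
            continue
        if c == "rare":
            pid = new_probe_id()
            vals = undetectable()
            if k_rare > 0:
                hot = rng.choice(n_samples, size=k_rare, replace=False)
                vals[hot] = 2.0 ** (12.0 + rng.normal(0, 0.3, k_rare)) + vals[hot]
            probe_ids.append(pid)
            probe_rows.append(vals)
            ann_rows.append({"probe_id": pid, "symbol": g, "quality": "high"})
            continue
        if c == "low_var":
            base = 13.0 + rng.normal(0, 0.3)
            ctrl = base + rng.normal(0.0, 0.01, len(pair_ids))
            case = ctrl + 1.0 + rng.normal(0.0, 0.01, len(pair_ids))
            log2 = np.empty(n_samples)
            log2[0::2] = case
            log2[1::2] = ctrl
            log2 += pair_offset
            pid = new_probe_id()
            probe_ids.append(pid)
            probe_rows.append(2.0 ** log2 + background())
            ann_rows.append({"probe_id": pid, "symbol": g, "quality": "high"})
            continue

        # ordinary signal gene (possibly duplicated or low-quality)
        base = rng.normal(12.0, 0.7)
        ctrl = base + rng.normal(0.0, 0.2, len(pair_ids))
        if diff_signal is not None and g in diff_signal.index:
            case = ctrl + diff_signal.loc[g, pair_ids].to_numpy(float)
        else:
            case = ctrl + rng.normal(0.0, 0.6, len(pair_ids))
        log2 = np.empty(n_samples)
        log2[0::2] = case
        log2[1::2] = ctrl
        log2 += pair_offset

        if c == "dup":
            shared = rng.standard_normal(n_samples)  # one deviate, scaled per probe
            ids = []
            for amp in dup_amps:
                pid = new_probe_id()
                ids.append(pid)
                probe_ids.append(pid)
                probe_rows.append(2.0 ** (log2 + amp * shared) + background())
                ann_rows.append({"probe_id": pid, "symbol": g, "quality": "high"})
            dup_survivors[g] = ids[int(np.argmax(dup_amps))]
        else:
            pid = new_probe_id()
            probe_ids.append(pid)
            probe_rows.append(2.0 ** log2 + background())
            quality = "low" if c == "low_quality" else "high"
            ann_rows.append({"probe_id": pid, "symbol": g, "quality": quality})

    intensities = pd.DataFrame(np.vstack(probe_rows), index=pd.Index(probe_ids, name="probe_id"),
                               columns=sample_ids)

    negctrl = pd.DataFrame(neg, index=[f"NEG_{i + 1:04d}" for i in range(n_negctrl)],
                           columns=sample_ids)
    annotation = pd.DataFrame(ann_rows)

    n_probes = len(probe_ids)
    after_detection = n_probes - n_below - n_rare
    after_quality = after_detection - n_lowq
    after_collapse = n_genes - n_below - n_rare - n_lowq  # one probe per surviving gene
    after_low_var = after_collapse - n_lowvar

    ledger = {
        "seed": seed,
        "n_genes": n_genes,
        "n_probes": n_probes,
        "n_samples": n_samples,
        "categories": categories,
        "n_below_detection": n_below,
        "n_rare": n_rare,
        "n_low_quality": n_lowq,
        "n_low_variation": n_lowvar,
        "n_duplicated_genes": n_dup,
        "dup_survivors": dup_survivors,
        "expected_survivors": {
            "input_probes": n_probes,
            "detection_filter": after_detection,
            "annotation_quality": after_quality,
            "probe_collapse": after_collapse,
            "low_variation_filter": after_low_var,
        },
    }
    return RawIntensityBundle(intensities, negctrl, annotation, ledger)


# ---------------------------------------------------------------------------
# plain-text output
# ---------------------------------------------------------------------------

def write_bundle(bundle: RawIntensityBundle, design: DesignTable, out_dir) -> dict[str, Path]:
    """Write a bundle as tab-separated files plus a key-value ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": out / "probe_intensities.tsv",
        "negctrl": out / "negative_controls.tsv",
        "annotation": out / "probe_annotation.tsv",
        "design": out / "design.tsv",
        "ledger": out / "ground_truth_ledger.txt",
    }
    bundle.intensities.to_csv(paths["intensities"], sep="\t", index_label="probe_id")
    bundle.negctrl.to_csv(paths["negctrl"], sep="\t", index_label="probe_id")
    bundle.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    design.to_tsv(paths["design"])
    with open(paths["ledger"], "w") as fh:
        for key in ("seed", "n_genes", "n_probes", "n_samples", "n_below_detection",
                    "n_rare", "n_low_quality", "n_low_variation", "n_duplicated_genes"):
            fh.write(f"{key}\t{bundle.ledger[key]}\n")
        for step, n in bundle.ledger["expected_survivors"].items():
            fh.write(f"expected_survivors.{step}\t{n}\n")
        for gene, probe in bundle.ledger["dup_survivors"].items():
            fh.write(f"dup_survivor.{gene}\t{probe}\n")
    return paths
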