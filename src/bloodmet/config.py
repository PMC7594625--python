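"""Model configuration: prior constants and sampler settings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SCREENING = "screening"
INTERVAL = "interval"
STRATA = (SCREENING, INTERVAL)


@dataclass(frozen=True)
class PriorConfig:
    """Constants of the gene-level hierarchical prior.

    The per-stratum intercept alpha_s has a normal(alpha_loc, alpha_scale)
    prior; the slope hierarchy is beta_s ~ normal(mu, sigma) with
    mu ~ normal(mu_loc, mu_scale) and sigma = exp(normal(log_sigma_loc,
    log_sigma_scale)), i.e. a lognormal scale.  The default intercept
    location corresponds to a baseline metastasis risk of roughly 25%
    (invlogit(-1) ~ 0.269).

    Scales may be zero only for degenerate prior-predictive checks; model
    fitting requires strictly positive scales.
    """

    alpha_loc: float = -1.0
    alpha_scale: float = 1.0
    mu_loc: float = 0.0
    mu_scale: float = 0.1
    log_sigma_loc: float = 0.0
    log_sigma_scale: float = 0.2

    def __post_init__(self) -> None:
        for name in ("alpha_scale", "mu_scale", "log_sigma_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def degenerate(self) -> bool:
        return self.alpha_scale == 0 and self.mu_scale == 0 and self.log_sigma_scale == 0


@dataclass(frozen=True)
class GeneModelConfig:
    """Settings for one per-gene model fit.

    Parameters
    ----------
    priors
        The prior constants (see :class:`PriorConfig`).
    z
        Probe point for excess risk: expression `z` standard deviations
        above average.  Must be positive; default 0.1.
    chains, warmup, draws
        MCMC layout: number of independent chains (>= 2 so split-R-hat is
        defined), discarded warmup iterations, and kept draws per chain.
    seed
        Base seed for the sampler; chains derive child streams from it.
    max_rhat, min_ess
        Convergence thresholds applied by :func:`bloodmet.model.check_convergence`.
    """

    priors: PriorConfig = field(default_factory=PriorConfig)
    z: float = 0.1
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    max_rhat: float = 1.01
    min_ess: float = 400.0

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be strictly positive")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.warmup < 0 or self.draws < 1:
            raise ValueError("warmup must be >= 0 and draws >= 1")

    def with_seed(self, seed: int) -> "GeneModelConfig":
        return replace(self, seed=int(seed))
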