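"""Dense-grid numerical integration oracle for the per-gene posterior.

Independent of the MCMC code path: evaluates the unnormalized posterior of
the hierarchical logistic model on a dense grid and integrates by direct
summation.  Conditional on (mu, log sigma) the two detection strata are
independent, and each stratum's factor depends only on (alpha_s, beta_s),
so the stratum likelihood table is computed once on an (alpha, beta) grid
and reweighted by the normal(mu, sigma) slope prior for every outer grid
point.  Practical for n <= ~20 observations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from bloodmet.config import GeneModelConfig
from bloodmet.model import _encode_strata


def grid_posterior_moments(
    x,
    y,
    s,
    config: GeneModelConfig = GeneModelConfig(),
    n_outer: int = 41,
    n_alpha: int = 61,
    n_beta: int = 121,
    span: float = 5.0,
):
    """Posterior means and SDs of the six gene-level parameters by quadrature.

    Returns a dict parameter -> (mean, sd) for alpha_screen,
    alpha_interval, beta_screen, beta_interval, mu and sigma.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    s_idx = _encode_strata(s)
    pr = config.priors

    mu_g = np.linspace(pr.mu_loc - span * pr.mu_scale, pr.mu_loc + span * pr.mu_scale, n_outer)
    ls_g = np.linspace(pr.log_sigma_loc - span * pr.log_sigma_scale,
                       pr.log_sigma_loc + span * pr.log_sigma_scale, n_outer)
    a_g = np.linspace(pr.alpha_loc - span * pr.alpha_scale,
                      pr.alpha_loc + span * pr.alpha_scale, n_alpha)
    # beta must cover normal(mu, sigma) for all plausible (mu, sigma)
    b_max = abs(pr.mu_loc) + span * pr.mu_scale + (span + 1) * np.exp(
        pr.log_sigma_loc + span * pr.log_sigma_scale) * 0.6
    b_g = np.linspace(-b_max, b_max, n_beta)

    sig_g = np.exp(ls_g)
    # slope prior: (n_outer mu, n_outer ls, n_beta)
    log_bprior = norm.logpdf(b_g[None, None, :], loc=mu_g[:, None, None],
                             scale=sig_g[None, :, None])
    log_aprior = norm.logpdf(a_g, loc=pr.alpha_loc, scale=pr.alpha_scale)

    stats = {}
    strat_terms = []
    for k, name in ((0, "screen"), (1, "interval")):
        xs, ys = x[s_idx == k], y[s_idx == k]
        # log-likelihood on the (alpha, beta) grid
        eta = a_g[:, None, None] + b_g[None, :, None] * xs[None, None, :]
        loglik = (ys * eta - np.logaddexp(0.0, eta)).sum(axis=2)  # (n_alpha, n_beta)
        m = loglik + log_aprior[:, None]
        # conditional-on-beta alpha moments
        c_b = logsumexp(m, axis=0)                        # (n_beta,)
        w_ab = np.exp(m - c_b[None, :])
        a1_b = (w_ab * a_g[:, None]).sum(axis=0)
        a2_b = (w_ab * (a_g ** 2)[:, None]).sum(axis=0)
        # stratum evidence and conditional moments per outer point
        t = c_b[None, None, :] + log_bprior               # (mu, ls, beta)
        s_ml = logsumexp(t, axis=2)                       # (mu, ls)
        w_b = np.exp(t - s_ml[:, :, None])
        strat_terms.append({
            "evidence": s_ml,
            "b1": (w_b * b_g).sum(axis=2),
            "b2": (w_b * b_g ** 2).sum(axis=2),
            "a1": (w_b * a1_b).sum(axis=2),
            "a2": (w_b * a2_b).sum(axis=2),
            "name": name,
        })

    log_w = (norm.logpdf(mu_g, pr.mu_loc, pr.mu_scale)[:, None]
             + norm.logpdf(ls_g, pr.log_sigma_loc, pr.log_sigma_scale)[None, :]
             + strat_terms[0]["evidence"] + strat_terms[1]["evidence"])
    w = np.exp(log_w - logsumexp(log_w))

    def moments(m1, m2):
        mean = float((w * m1).sum())
        var = float((w * m2).sum()) - mean ** 2
        return mean, float(np.sqrt(max(var, 0.0)))

    for term in strat_terms:
        stats[f"alpha_{term['name']}"] = moments(term["a1"], term["a2"])
        stats[f"beta_{term['name']}"] = moments(term["b1"], term["b2"])
    stats["mu"] = moments(mu_g[:, None] + 0 * w, (mu_g ** 2)[:, None] + 0 * w)
    stats["sigma"] = moments(sig_g[None, :] + 0 * w, (sig_g ** 2)[None, :] + 0 * w)
    return stats
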