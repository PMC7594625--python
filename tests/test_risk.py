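import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

import bloodmet as bm
from bloodmet.model import per_gene_seed

from conftest import make_design


def draws_from(a_scr, a_int, b_scr, b_int):
    shape = np.broadcast(a_scr, b_scr).shape
    return bm.PosteriorDraws(draws={
        "alpha_screen": np.broadcast_to(a_scr, shape).reshape(1, -1).astype(float),
        "alpha_interval": np.broadcast_to(a_int, shape).reshape(1, -1).astype(float),
        "beta_screen": np.broadcast_to(b_scr, shape).reshape(1, -1).astype(float),
        "beta_interval": np.broadcast_to(b_int, shape).reshape(1, -1).astype(float),
        "mu": np.zeros(shape).reshape(1, -1),
        "sigma": np.ones(shape).reshape(1, -1),
    }, gene="G")


class TestDetectionWeights:
    def test_empirical_case_proportions(self):
        design = make_design(["screening"] * 111 + ["interval"] * 45)
        w = bm.estimate_detection_weights(design)
        assert w.p_screening == pytest.approx(111 / 156)
        assert w.p_screening + w.p_interval == pytest.approx(1.0)

    def test_balanced_and_degenerate(self):
        design = make_design(["screening", "interval"])
        w = bm.estimate_detection_weights(design)
        assert (w.p_screening, w.p_interval) == (0.5, 0.5)
        with pytest.raises(ValueError):
            bm.estimate_detection_weights(make_design(["screening", "screening"]))

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            bm.DetectionWeights(0.7, 0.7)


class TestMarginalize:
    def test_degenerate_weights_reproduce_stratum(self):
        rng = np.random.default_rng(0)
        d = draws_from(rng.normal(size=100), rng.normal(size=100),
                       rng.normal(size=100), rng.normal(size=100))
        a, b = bm.marginalize_draws(d, bm.DetectionWeights(1.0, 0.0), seed=1)
        assert np.array_equal(a, d.stacked("alpha_screen"))
        assert np.array_equal(b, d.stacked("beta_screen"))

    def test_identical_strata_unchanged(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=50)
        d = draws_from(v, v, v, v)
        a, b = bm.marginalize_draws(d, bm.DetectionWeights(0.5, 0.5), seed=2)
        assert np.array_equal(a, v) and np.array_equal(b, v)

    def test_mixture_mean_of_point_masses(self):
        n = 40_000
        d = draws_from(np.zeros(n), np.ones(n), np.zeros(n), np.ones(n))
        a, _ = bm.marginalize_draws(d, bm.DetectionWeights(0.5, 0.5), seed=3)
        assert abs(a.mean() - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_average_method_is_per_draw_weighted_sum(self):
        rng = np.random.default_rng(5)
        d = draws_from(rng.normal(size=30), rng.normal(size=30),
                       rng.normal(size=30), rng.normal(size=30))
        a, b = bm.marginalize_draws(d, bm.DetectionWeights(0.7, 0.3), method="average")
        assert np.allclose(a, 0.7 * d.stacked("alpha_screen") + 0.3 * d.stacked("alpha_interval"))
        with pytest.raises(ValueError):
            bm.marginalize_draws(d, bm.DetectionWeights(0.5, 0.5), method="bogus")

    def test_joint_selection_keeps_pairs(self):
        """alpha and beta must come from the same stratum per draw."""
        n = 1000
        d = draws_from(np.zeros(n), np.ones(n), np.zeros(n), np.ones(n))
        a, b = bm.marginalize_draws(d, bm.DetectionWeights(0.5, 0.5), seed=4)
        assert np.array_equal(a, b)


class TestExcessRisk:
    def test_closed_form_values(self):
        assert bm.excess_risk(np.array([-1.0]), np.array([0.0]))[0] == 0.0
        rho = bm.excess_risk(np.array([-1.0]), np.array([1.0]), z=0.1)[0]
        assert rho == pytest.approx(expit(-0.9) - expit(-1.0), abs=1e-12)
        assert rho == pytest.approx(0.02011, abs=5e-6)

    def test_worked_example_baseline_25_plus_2_is_27(self):
        alpha = logit(0.25)
        beta = (logit(0.27) - logit(0.25)) / 0.1
        rho = bm.excess_risk(np.array([alpha]), np.array([beta]), z=0.1)[0]
        assert expit(alpha) == pytest.approx(0.25)
        assert expit(alpha) + rho == pytest.approx(0.27, abs=1e-12)

    def test_invalid_z(self):
        with pytest.raises(ValueError):
            bm.excess_risk(np.zeros(2), np.zeros(2), z=0.0)

    @given(alpha=st.floats(-5, 5),
           beta=st.floats(-10, 10).filter(lambda b: b == 0 or abs(b) > 1e-6),
           z=st.floats(0.01, 1))
    @settings(max_examples=100, deadline=None)
    def test_sign_matches_slope_and_bounded(self, alpha, beta, z):
        rho = bm.excess_risk(np.array([alpha]), np.array([beta]), z=z)[0]
        assert -1 < rho < 1
        assert np.sign(rho) == np.sign(beta)


class TestSignProbability:
    def test_examples(self):
        assert bm.sign_probability(np.array([0.1, 0.2, 0.3])) == 1.0
        assert bm.sign_probability(np.array([-1.0, 2.0, 3.0, 4.0])) == 0.75
        sym = np.concatenate([np.linspace(-1, -0.01, 500), np.linspace(0.01, 1, 500)])
        assert bm.sign_probability(sym) == pytest.approx(0.5, abs=0.01)
        with pytest.raises(ValueError):
            bm.sign_probability(np.array([]))

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_monotone_transforms(self, vals):
        rho = np.array(vals)
        p = bm.sign_probability(rho)
        assert bm.sign_probability(3.7 * rho) == p
        assert bm.sign_probability(np.tanh(rho)) == p


class TestRanking:
    def _summary(self, gene, sign_prob, med=0.01, converged=True):
        rho = np.array([med] * 10)
        return bm.GeneRiskSummary(gene=gene, alpha=rho, beta=rho, rho=rho,
                                  rho_median=med, direction="up" if med > 0 else "down",
                                  sign_prob=sign_prob, converged=converged)

    def test_descending_order_and_truncation(self):
        s = [self._summary("A", 0.90), self._summary("B", 0.99), self._summary("C", 0.95)]
        top = bm.rank_genes(s, k=2)
        assert top["gene"].tolist() == ["B", "C"]
        full = bm.rank_genes(s, k=10)  # k beyond gene count truncates
        assert full["gene"].tolist() == ["B", "C", "A"]

    def test_tie_break_by_median_then_symbol(self):
        s = [self._summary("B", 0.9, med=0.01), self._summary("A", 0.9, med=0.01),
             self._summary("C", 0.9, med=-0.05)]
        top = bm.rank_genes(s, k=3)
        assert top["gene"].tolist() == ["C", "A", "B"]

    def test_unconverged_excluded(self):
        s = [self._summary("A", 0.99, converged=False), self._summary("B", 0.8)]
        top = bm.rank_genes(s, k=2)
        assert top["gene"].tolist() == ["B"]

    def test_causal_genes_rank_high_in_recovery_experiment(self):
        """Genes with strong true slopes surface at the top of the ranking."""
        n_genes, n_pairs = 40, 300
        rng = np.random.default_rng(21)
        alpha = np.full(n_genes, -1.0)
        beta = np.zeros(n_genes)
        causal = [0, 1, 2]
        beta[causal] = 2.0
        params = bm.TrueParameters(alpha, alpha.copy(), np.zeros(n_genes),
                                   np.ones(n_genes), beta, beta.copy())
        diff, design, ledger = bm.simulate_differential_cohort(params, n_pairs, seed=22)
        s = design.pair_frame()["detection_mode"].to_numpy()
        w = bm.estimate_detection_weights(design)
        cfg = bm.GeneModelConfig(chains=2, warmup=200, draws=300, seed=23,
                                 min_ess=100.0, max_rhat=1.05)
        summaries = []
        for i, g in enumerate(diff.genes):
            fit = bm.fit_gene_model(diff.gene(g), ledger["y_matrix"].loc[g].to_numpy(),
                                    s, cfg.with_seed(per_gene_seed(23, i)), gene=g)
            summaries.append(bm.summarize_gene(fit, w, seed=per_gene_seed(24, i)))
        top10 = set(bm.rank_genes(summaries, k=10)["gene"])
        assert {"G0001", "G0002", "G0003"} <= top10


class TestMLE:
    def test_grouped_data_closed_form(self):
        # x = -1 with outcome rate 0.2, x = +1 with rate 0.8, in both strata
        x, y, s = [], [], []
        for stratum in ("screening", "interval"):
            for xv, rate in ((-1.0, 0.2), (1.0, 0.8)):
                for i in range(10):
                    x.append(xv)
                    y.append(1 if i < rate * 10 else 0)
                    s.append(stratum)
        res = bm.mle_excess_risk(np.array(x), np.array(y), np.array(s),
                                 bm.DetectionWeights(0.5, 0.5))
        assert res.beta == pytest.approx(np.log(4), abs=1e-4)
        assert res.alpha == pytest.approx(0.0, abs=1e-6)
        assert not res.separated

    def test_null_gene_near_zero(self):
        rng = np.random.default_rng(30)
        n = 5000
        x = rng.standard_normal(n)
        s = np.where(rng.random(n) < 0.7, "screening", "interval")
        y = (rng.random(n) < expit(-1.0)).astype(int)
        res = bm.mle_excess_risk(x, y, s, bm.DetectionWeights(0.7, 0.3))
        assert abs(res.rho) < 0.02

    def test_perfect_separation_flagged(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0] * 2)
        y = np.array([0, 0, 1, 1] * 2)
        s = np.array(["screening"] * 4 + ["interval"] * 4)
        res = bm.mle_excess_risk(x, y, s, bm.DetectionWeights(0.5, 0.5))
        assert res.separated and np.isnan(res.rho)


class TestPriorPredictive:
    def test_interval_half_width_near_paper_value(self):
        pp = bm.prior_predictive(n_draws=10 ** 6, seed=31)
        assert pp.half_width() == pytest.approx(0.014, abs=0.002)

    def test_baseline_risk_quarter(self):
        pp = bm.prior_predictive(n_draws=200_000, seed=32)
        assert np.median(expit(pp.alpha)) == pytest.approx(expit(-1.0), abs=0.005)

    def test_degenerate_priors_give_zero_rho(self):
        cfg = bm.GeneModelConfig(priors=bm.PriorConfig(
            alpha_scale=0.0, mu_scale=0.0, log_sigma_scale=0.0))
        pp = bm.prior_predictive(cfg, n_draws=1000, seed=33)
        assert np.all(pp.rho == 0.0)

    def test_half_width_stable_across_seeds(self):
        widths = [bm.prior_predictive(n_draws=10 ** 6, seed=s).half_width()
                  for s in (1, 2)]
        assert abs(widths[0] - widths[1]) < 5e-4
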