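import numpy as np
import pytest

import metafuse as mf
from metafuse.datamodel import MetaboliteBlock, SampleTable
from metafuse.errormodel import (MedianErrorModel, ReplicateSet, RockeLorenzatoFit,
                                 RockeLorenzatoModel, build_weights, fit_median_model,
                                 fit_rocke_lorenzato, huber_location, huber_regress,
                                 pair_stats, predict_sigma, _piecewise_objective)

from conftest import make_replicate_set


def _exact_law_replicates(sigma_add=0.05, sigma_mult=0.1, alpha=1.0, n=201, hi=2.0):
    """(μ, σ²) points lying exactly on the piecewise variance law."""
    mu = np.linspace(0.0, hi, n)
    s2 = sigma_add ** 2 + np.where(mu > alpha, (sigma_mult * (mu - alpha)) ** 2, 0.0)
    half = np.sqrt(s2 / 2.0)
    return make_replicate_set((mu + half)[:, None], (mu - half)[:, None])


class TestPairStats:
    def test_pair_mean_and_variance(self):
        b = MetaboliteBlock(np.array([[4.0], [2.0]]), ["a", "b"], ["m"], ["amine"])
        t = SampleTable(["a", "b"], ["other", "other"], ["r1", "r1"])
        rs = pair_stats(b, t)
        assert rs.pair_mean[0, 0] == 3.0 and rs.pair_var[0, 0] == 2.0

    def test_identical_repeats_zero_variance(self):
        b = MetaboliteBlock(np.array([[5.0], [5.0]]), ["a", "b"], ["m"], ["amine"])
        t = SampleTable(["a", "b"], ["other", "other"], ["r1", "r1"])
        assert pair_stats(b, t).pair_var[0, 0] == 0.0

    def test_study_layout_yields_15_pairs(self, study_replicates):
        assert study_replicates.n_pairs == 15

    def test_missing_replicate_sample_fails(self):
        b = MetaboliteBlock(np.array([[1.0]]), ["a"], ["m"], ["amine"])
        t = SampleTable(["a", "b"], ["other", "other"], ["r1", "r1"])
        with pytest.raises(ValueError, match="missing from block"):
            pair_stats(b, t)


class TestHuberFit:
    """The in-house IRLS against statsmodels RLM as independent oracle."""

    def test_regression_with_intercept_matches_rlm(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 10, 200)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.3, 200)
        y[:10] += 8.0  # outliers
        X = np.column_stack([np.ones(200), x])
        ours = huber_regress(X, y)
        rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit().params
        np.testing.assert_allclose(ours, rlm, rtol=1e-4)

    def test_no_intercept_slope_and_location_match_rlm(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 10, 200)
        y = 0.7 * x + rng.normal(0, 0.2, 200)
        y[:5] += 5.0
        ours = huber_regress(x[:, None], y)[0]
        rlm = sm.RLM(y, x[:, None], M=sm.robust.norms.HuberT()).fit().params[0]
        assert abs(ours - rlm) < 1e-5
        z = rng.normal(3, 1, 150)
        z[:8] += 20
        rlm_loc = sm.RLM(z, np.ones((150, 1)), M=sm.robust.norms.HuberT()).fit().params[0]
        assert abs(huber_location(z) - rlm_loc) < 1e-5

    def test_perfect_fit_degenerate_scale(self):
        x = np.arange(1.0, 6.0)
        np.testing.assert_allclose(huber_regress(x[:, None], 3.0 * x)[0], 3.0)


class TestRockeLorenzato:
    def test_exact_law_recovered_to_one_percent(self):
        rs = _exact_law_replicates()
        fit = fit_rocke_lorenzato(rs, "amine")
        assert abs(fit.sigma_add - 0.05) / 0.05 < 0.01
        assert abs(fit.sigma_mult - 0.1) / 0.1 < 0.01
        assert abs(fit.alpha - 1.0) < 0.01

    def test_objective_at_recovered_not_worse_than_truth(self, rng):
        mu = rng.uniform(0, 10, 400)
        x1 = mu * np.exp(rng.normal(0, 0.1, 400)) + rng.normal(0, 0.05, 400)
        x2 = mu * np.exp(rng.normal(0, 0.1, 400)) + rng.normal(0, 0.05, 400)
        rs = make_replicate_set(x1[:, None], x2[:, None])
        fit = fit_rocke_lorenzato(rs, "amine", step2="ls")
        m, s2 = rs.pooled_group_points("amine")
        obj_true = _piecewise_objective(m, s2, 0.0, 0.05 ** 2, 0.1 ** 2)
        assert fit.objective <= obj_true + 1e-9

    def test_all_points_below_cutoff_degenerates_to_constant(self):
        # constant variance everywhere: the multiplicative part must vanish
        mu = np.linspace(0, 1, 50)
        half = np.sqrt(0.04 / 2)
        rs = make_replicate_set((mu + half)[:, None], (mu - half)[:, None])
        fit = fit_rocke_lorenzato(rs, "amine")
        pv = fit.predict_var(np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(pv, pv[0], rtol=1e-9)

    def test_fit_invariant_to_point_order(self, rng):
        rs = _exact_law_replicates()
        perm = rng.permutation(rs.n_pairs)
        rs2 = ReplicateSet(rs.x1[perm], rs.x2[perm], rs.metabolite_ids,
                           rs.metabolite_group, [rs.pair_ids[p] for p in perm])
        f1, f2 = fit_rocke_lorenzato(rs, "amine"), fit_rocke_lorenzato(rs2, "amine")
        assert f1.alpha == f2.alpha
        assert f1.sigma_add == pytest.approx(f2.sigma_add, rel=1e-9)
        assert f1.sigma_mult == pytest.approx(f2.sigma_mult, rel=1e-9)

    def test_too_few_points_rejected(self):
        rs = make_replicate_set(np.array([[1.0, 2.0]]), np.array([[1.1, 2.2]]))
        with pytest.raises(ValueError, match="≥4"):
            fit_rocke_lorenzato(rs, "amine")

    def test_single_seed_recovery_sanity(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(0, 10, 500)
        x1 = mu * np.exp(rng.normal(0, 0.1, 500)) + rng.normal(0, 0.05, 500)
        x2 = mu * np.exp(rng.normal(0, 0.1, 500)) + rng.normal(0, 0.05, 500)
        fit = fit_rocke_lorenzato(make_replicate_set(x1[:, None], x2[:, None]), "amine")
        assert abs(fit.sigma_mult - 0.1) / 0.1 < 0.5


class TestMedianModel:
    def test_median_robust_to_outlier(self):
        pv = np.array([[1.0], [2.0], [100.0]])
        rs = make_replicate_set(np.sqrt(2 * pv), np.zeros_like(pv))
        model = fit_median_model(rs)
        np.testing.assert_allclose(model.sigma2, [2.0])

    def test_single_pair_uses_its_variance(self):
        rs = make_replicate_set(np.array([[4.0]]), np.array([[2.0]]))
        np.testing.assert_allclose(fit_median_model(rs).sigma2, [2.0])

    def test_all_zero_variances_warn(self):
        x = np.ones((3, 2))
        with pytest.warns(UserWarning, match="capped"):
            model = fit_median_model(make_replicate_set(x, x))
        np.testing.assert_allclose(model.sigma2, 0.0)


class TestPredictSigma:
    @pytest.fixture
    def rl(self):
        fit = RockeLorenzatoFit(sigma_add=2.0, sigma_mult=0.5, alpha=10.0,
                                objective=0.0, n_points=10)
        return RockeLorenzatoModel({"amine": fit}, {"m0": "amine"})

    def test_below_and_above_cutoff(self, rl):
        assert predict_sigma(rl, 5.0, group="amine") == 2.0
        np.testing.assert_allclose(predict_sigma(rl, 12.0, group="amine"), np.sqrt(5.0))

    def test_continuous_at_cutoff(self, rl):
        eps = np.array([1e-12, 1e-9, 1e-6])
        np.testing.assert_allclose(predict_sigma(rl, 10.0 - eps, group="amine"),
                                   predict_sigma(rl, 10.0 + eps, group="amine"), rtol=1e-6)

    def test_monotone_nondecreasing(self, rl):
        mu = np.linspace(0, 50, 500)
        assert np.all(np.diff(predict_sigma(rl, mu, group="amine")) >= 0)

    def test_unknown_group_and_metabolite(self, rl):
        with pytest.raises(KeyError):
            predict_sigma(rl, 1.0, group="TG")
        with pytest.raises(KeyError):
            predict_sigma(rl, 1.0, metabolite="nope")
        assert predict_sigma(rl, 5.0, metabolite="m0") == 2.0

    def test_median_model_ignores_level(self):
        model = MedianErrorModel(np.array([4.0]), ["m0"])
        np.testing.assert_allclose(predict_sigma(model, np.array([0.1, 100.0]),
                                                 metabolite="m0"), 2.0)


class TestWeights:
    def test_median_model_constant_weights(self):
        model = MedianErrorModel(np.array([4.0, 1.0]), ["m0", "m1"])
        b = MetaboliteBlock(np.ones((3, 2)), ["a", "b", "c"], ["m0", "m1"], ["amine"] * 2)
        w = build_weights(b, model)
        np.testing.assert_allclose(w[:, 0], 0.5)
        np.testing.assert_allclose(w[:, 1], 1.0)

    def test_rl_weights_nonincreasing_above_cutoff(self):
        fit = RockeLorenzatoFit(0.1, 0.2, 1.0, 0.0, 10)
        model = RockeLorenzatoModel({"amine": fit}, {})
        vals = np.linspace(0, 20, 50)[None, :].repeat(2, axis=0)
        b = MetaboliteBlock(vals, ["a", "b"],
                            [f"m{j}" for j in range(50)], ["amine"] * 50)
        w = build_weights(b, model)
        assert np.all(np.diff(w[0]) <= 1e-12)

    def test_missing_entries_get_zero_weight(self):
        model = MedianErrorModel(np.array([1.0]), ["m0"])
        vals = np.array([[1.0], [np.nan]])
        b = MetaboliteBlock(vals, ["a", "b"], ["m0"], ["amine"])
        w = build_weights(b, model)
        assert w[0, 0] == 1.0 and w[1, 0] == 0.0

    def test_zero_variance_weight_capped(self):
        model = MedianErrorModel(np.array([0.0, 1.0]), ["m0", "m1"])
        b = MetaboliteBlock(np.ones((2, 2)), ["a", "b"], ["m0", "m1"], ["amine"] * 2)
        w = build_weights(b, model, cap_factor=1e3)
        assert np.all(np.isfinite(w))
        assert w[0, 0] == 1e3 * 1.0  # cap at 1e3 × median positive weight
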