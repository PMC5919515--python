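import numpy as np
import pytest
from scipy import stats

import metafuse as mf
from metafuse.datamodel import FusedBlocks, MetaboliteBlock, SampleTable
from metafuse.validation import (fit_fold, importance_table, make_fold_plan,
                                 predict_fold, run_cv, ttest_screen,
                                 valid_configurations)


def _labels_16_15():
    return np.array(["h"] * 16 + ["d"] * 15)


class TestFoldPlan:
    def test_study_pattern_sizes(self):
        rng = np.random.default_rng(0)
        plan = make_fold_plan(_labels_16_15(), ("h", "d"), rng)
        sizes = [p.size for p in plan.parts]
        assert sizes == [4] * 7 + [3]
        labels = _labels_16_15()
        for p in plan.parts[:7]:
            assert sum(labels[p] == "h") == 2 and sum(labels[p] == "d") == 2
        assert sum(labels[plan.parts[7]] == "d") == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_partition_and_determinism(self, seed):
        labels = _labels_16_15()
        p1 = make_fold_plan(labels, ("h", "d"), np.random.default_rng(seed))
        p2 = make_fold_plan(labels, ("h", "d"), np.random.default_rng(seed))
        allidx = np.sort(np.concatenate(p1.parts))
        np.testing.assert_array_equal(allidx, np.arange(31))
        for a, b in zip(p1.parts, p2.parts):
            np.testing.assert_array_equal(a, b)

    def test_incompatible_counts_warn_and_fall_back(self):
        labels = np.array(["h"] * 5 + ["d"] * 5)
        with pytest.warns(UserWarning, match="parts"):
            plan = make_fold_plan(labels, ("h", "d"), np.random.default_rng(0))
        np.testing.assert_array_equal(np.sort(np.concatenate(plan.parts)), np.arange(10))


class TestRunCv:
    def test_rejects_unsupported_configuration(self, small_data):
        blocks, table, _ = small_data
        with pytest.raises(ValueError, match="not one of the supported"):
            run_cv(blocks, table, "weighted_med", "center")
        assert len(valid_configurations()) == 14

    def test_perfectly_separable_classes_give_zero_error(self):
        spec = mf.SyntheticSpec(n_metabolites=(8, 12), lipid_split={"TG": 1},
                                effect_size=12.0, sigma_mult=0.02, sigma_add=0.005,
                                seed=2)
        blocks, table, _ = mf.generate(spec)
        res = run_cv(blocks, table, "raw", "auto", repeats=3, seed=1)
        assert all(a == 0.0 for a in res.averages.values())

    def test_permuted_labels_give_chance_level_error(self):
        spec = mf.SyntheticSpec(n_metabolites=(8, 12), lipid_split={"TG": 1}, seed=11)
        blocks, table, _ = mf.generate(spec)
        rng = np.random.default_rng(0)
        lab = list(table.class_label)
        analysis = [i for i, c in enumerate(lab) if c != "other"]
        perm = rng.permutation([lab[i] for i in analysis])
        for i, p in zip(analysis, perm):
            lab[i] = str(p)
        table_perm = SampleTable(table.sample_ids, lab, table.replicate_group)
        res = run_cv(blocks, table_perm, "raw", "auto", repeats=25,
                     components=(5,), seed=3)
        assert 12.0 <= res.averages[5] <= 19.0

    def test_deterministic_given_master_seed(self, small_data):
        blocks, table, _ = small_data
        r1 = run_cv(blocks, table, "sqrt", "auto", repeats=2, seed=9)
        r2 = run_cv(blocks, table, "sqrt", "auto", repeats=2, seed=9)
        for R in r1.components:
            np.testing.assert_array_equal(r1.counts[R], r2.counts[R])
            np.testing.assert_array_equal(r1.importance[R], r2.importance[R])
        assert r1.repeat_seeds == r2.repeat_seeds

    def test_counts_bounded_and_average_consistent(self, small_data):
        blocks, table, _ = small_data
        res = run_cv(blocks, table, "raw", "center", repeats=3, components=(3,), seed=0)
        c = res.counts[3]
        assert np.all((0 <= c) & (c <= res.n_samples))
        assert c.min() <= res.averages[3] <= c.max()

    @pytest.mark.parametrize("method,scaling", [
        ("glog", "auto"), ("mals_med", "center"), ("weighted_rl", "auto")])
    def test_all_route_families_run(self, small_data, method, scaling):
        blocks, table, _ = small_data
        res = run_cv(blocks, table, method, scaling, repeats=1, components=(3,), seed=4)
        assert 0 <= res.averages[3] <= res.n_samples


class TestLeakageGuard:
    """Training-fold parameters must be identical whatever the test rows contain."""

    @pytest.mark.parametrize("method,scaling", [
        ("sqrt", "auto"), ("mals_med", "auto"), ("weighted_med", "auto")])
    def test_corrupting_test_rows_leaves_fit_unchanged(self, small_data, method, scaling):
        blocks, table, _ = small_data
        classes = ("healthy_obese", "diabetic_obese")
        label_of = dict(zip(table.sample_ids, table.class_label))
        rows = [i for i, s in enumerate(blocks.sample_ids) if label_of[s] in classes]
        analysis = blocks.subset_samples(rows)
        labels = np.array([label_of[s] for s in analysis.sample_ids])
        test_idx = np.arange(4)
        train_idx = np.arange(4, analysis.n_samples)
        train = analysis.subset_samples(train_idx)
        emodel = None
        if method in ("mals_med", "weighted_med"):
            from metafuse.errormodel import fit_median_model, merge_replicates, pair_stats

            reps = merge_replicates([pair_stats(b, table) for b in blocks.blocks])
            emodel = fit_median_model(reps)
        # a second dataset identical on training rows, garbage on test rows
        corrupted_full = analysis.subset_samples(np.arange(analysis.n_samples))
        for blk in corrupted_full.blocks:
            blk.values[test_idx] = blk.values[test_idx] * 3.7 + 11.0
        train_corrupt = corrupted_full.subset_samples(train_idx)

        def features(fused):
            return [np.sqrt(b.values) if method == "sqrt" else b.values
                    for b in fused.blocks]

        fm1 = fit_fold(train, features(train), labels[train_idx], method, scaling,
                       classes, components=(3,), error_model=emodel)
        fm2 = fit_fold(train_corrupt, features(train_corrupt), labels[train_idx],
                       method, scaling, classes, components=(3,), error_model=emodel)
        for a, b in zip(fm1.scaling_params, fm2.scaling_params):
            np.testing.assert_array_equal(a.center, b.center)
        sca1, dm1, b1 = fm1.per_component[3]
        sca2, dm2, b2 = fm2.per_component[3]
        np.testing.assert_array_equal(sca1.loadings, sca2.loadings)
        np.testing.assert_array_equal(dm1.beta, dm2.beta)
        np.testing.assert_array_equal(b1, b2)
        # predicting test rows mutates nothing in the frozen fold model
        test = analysis.subset_samples(test_idx)
        p_clean = predict_fold(fm1, test, features(test))
        sca1b, _dm, _b = fm1.per_component[3]
        assert np.array_equal(sca1b.loadings, sca1.loadings)
        assert set(p_clean[3]) <= set(classes)


class TestImportance:
    def test_importance_table_sorted_and_ranked(self, small_data):
        blocks, table, _ = small_data
        res = run_cv(blocks, table, "raw", "auto", repeats=2, components=(3,), seed=1)
        df = importance_table(res, 3, top=10)
        assert list(df.index) == list(range(1, 11))
        assert (np.diff(df["importance"].to_numpy()) <= 0).all()

    def test_single_informative_metabolite_ranks_first(self):
        hits, n_sim = 0, 20
        for s in range(n_sim):
            rng = np.random.default_rng(400 + s)
            n1 = n2 = 10
            X = 5.0 + 0.5 * rng.standard_normal((n1 + n2, 12))
            X[:n1, 0] += 3.0  # the only class difference
            blk = MetaboliteBlock(X, [f"s{i}" for i in range(n1 + n2)],
                                  [f"m{j}" for j in range(12)], ["amine"] * 12)
            tab = SampleTable(blk.sample_ids, ["c1"] * n1 + ["c2"] * n2, [""] * (n1 + n2))
            res = run_cv(FusedBlocks([blk]), tab, "raw", "center", repeats=1,
                         components=(3,), seed=s)
            hits += importance_table(res, 3, top=1).iloc[0]["metabolite"] == "m0"
        assert hits >= 0.95 * n_sim


class TestTtestScreen:
    def test_matches_closed_form_pooled_t(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        labels = ["a"] * 3 + ["b"] * 3
        res = ttest_screen(x, labels, classes=("a", "b"))
        # closed-form oracle: pooled SD 1, se = sqrt(2/3), df = 4
        t = (2.0 - 5.0) / np.sqrt(2.0 / 3.0)
        p = 2 * stats.t.sf(abs(t), df=4)
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert res.pvalues[0] == pytest.approx(p, abs=1e-12)
        assert res.pvalues[0] == pytest.approx(0.0213116, abs=1e-6)

    def test_identical_groups_nothing_significant(self):
        base = np.arange(10, dtype=float)[:, None] * np.ones((1, 6))
        x = np.vstack([base, base])
        labels = ["a"] * 10 + ["b"] * 10
        res = ttest_screen(x, labels)
        assert res.n_significant == 0 and res.n_bonferroni == 0
        assert np.all(res.pvalues > 0.99)

    def test_invariant_under_sample_reordering(self, rng):
        x = rng.normal(size=(20, 8))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        perm = rng.permutation(20)
        r1 = ttest_screen(x, labels)
        r2 = ttest_screen(x[perm], labels[perm])
        np.testing.assert_allclose(r1.pvalues, r2.pvalues, atol=1e-12)

    def test_bonferroni_counts_use_total_tests(self, rng):
        x = rng.normal(size=(12, 10))
        x[:6, 0] += 50.0
        labels = ["a"] * 6 + ["b"] * 6
        res = ttest_screen(x, labels, alpha=0.05)
        assert res.bonferroni_alpha == pytest.approx(0.005)
        assert res.n_bonferroni >= 1

    def test_class_with_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ttest_screen(np.ones((3, 2)), ["a", "b", "b"])
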