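import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vttml.containers import FeatureTable, concat_tables
from vttml.exceptions import ValidationError
from vttml.preprocess import (PreprocessModel, assemble_dynamic,
                              fold_change_features, iterative_impute,
                              minmax_scale, spearman_prune)


def make_table(arr, columns=None):
    arr = np.asarray(arr, dtype=float)
    columns = columns or [f"f{j}" for j in range(arr.shape[1])]
    return FeatureTable(pd.DataFrame(
        arr, index=[f"P{i}" for i in range(arr.shape[0])], columns=columns))


class TestFoldChange:
    def plasma(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "marker", "week", "value"])

    def test_identity_and_sevenfold(self):
        plasma = self.plasma([
            ("A", "PlGF", 1, 10.0), ("A", "PlGF", 3, 70.0),
            ("B", "PlGF", 1, 5.0), ("B", "PlGF", 3, 5.0),
        ])
        fc = fold_change_features(plasma, markers=["PlGF"])
        assert fc.values.loc["A", "PlGF FC w3"] == pytest.approx(7.0)
        assert fc.values.loc["B", "PlGF FC w3"] == pytest.approx(1.0)
        assert (fc.meta["kind"] == "fold_change").all()
        assert (fc.meta["timepoint"] == "week3").all()

    def test_zero_baseline_becomes_missing(self, caplog):
        plasma = self.plasma([
            ("A", "PlGF", 1, 0.0), ("A", "PlGF", 3, 70.0),
            ("B", "PlGF", 1, 5.0), ("B", "PlGF", 3, 10.0),
        ])
        fc = fold_change_features(plasma, markers=["PlGF"])
        assert np.isnan(fc.values.loc["A", "PlGF FC w3"])
        assert fc.values.loc["B", "PlGF FC w3"] == pytest.approx(2.0)


class TestImpute:
    def test_complete_table_unchanged(self, toy_table):
        out = iterative_impute(toy_table)
        pd.testing.assert_frame_equal(out.values, toy_table.values)

    def test_exact_linear_dependence_recovered(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        x3 = 2.0 * x1
        arr = np.column_stack([x1, x2, x3])
        masked = arr.copy()
        holes = [(3, 2), (10, 2), (25, 2), (33, 2), (47, 2)]
        for i, j in holes:
            masked[i, j] = np.nan
        out = iterative_impute(make_table(masked), max_iter=20, tol=1e-8)
        for i, j in holes:
            assert out.values.iloc[i, j] == pytest.approx(arr[i, j], abs=1e-6)

    def test_observed_cells_bitwise_preserved(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(30, 5))
        masked = arr.copy()
        masked[rng.random(arr.shape) < 0.1] = np.nan
        out = iterative_impute(make_table(masked))
        obs = ~np.isnan(masked)
        assert (out.values.to_numpy()[obs] == arr[obs]).all()

    def test_all_missing_column_rejected(self):
        arr = np.ones((5, 3))
        arr[:, 1] = np.nan
        with pytest.raises(ValidationError, match="f1"):
            iterative_impute(make_table(arr))

    def test_all_missing_row_rejected(self):
        arr = np.ones((5, 3))
        arr[2, :] = np.nan
        with pytest.raises(ValidationError, match="P2"):
            iterative_impute(make_table(arr))


class TestMinMaxScale:
    def test_basic_mapping(self):
        t = make_table(np.array([[2.0], [4.0], [6.0]]))
        scaled, params = minmax_scale(t)
        assert scaled.values.iloc[:, 0].tolist() == [0.0, 0.5, 1.0]
        assert params.loc["f0", "min"] == 2.0 and params.loc["f0", "max"] == 6.0

    def test_constant_feature_maps_to_zero(self):
        t = make_table(np.array([[3.0], [3.0], [3.0]]))
        scaled, _ = minmax_scale(t)
        assert (scaled.values.to_numpy() == 0.0).all()

    def test_heldout_extrapolates_not_clips(self):
        from vttml.preprocess import apply_minmax
        t = make_table(np.array([[2.0], [6.0]]))
        _, params = minmax_scale(t)
        held = pd.DataFrame([[0.0]], index=["Q"], columns=["f0"])
        assert apply_minmax(held, params).iloc[0, 0] == pytest.approx(-0.5)

    def test_affine_invariance(self, toy_table):
        scaled, _ = minmax_scale(toy_table)
        shifted = FeatureTable(toy_table.values * 3.7 + 11.0, toy_table.meta)
        scaled2, _ = minmax_scale(shifted)
        np.testing.assert_allclose(scaled.values, scaled2.values, atol=1e-12)


def brute_force_spearman_components(values, threshold=0.75):
    """Independent oracle: all-pairs Spearman + union-find components."""
    p = values.shape[1]
    parent = list(range(p))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for i in range(p):
        for j in range(i + 1, p):
            rho = stats.spearmanr(values.iloc[:, i], values.iloc[:, j]).statistic
            if abs(rho) > threshold:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(p):
        comps.setdefault(find(i), []).append(i)
    return sorted(sorted(c) for c in comps.values())


class TestSpearmanPrune:
    def test_duplicate_column_drops_one(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=12)
        t = make_table(np.column_stack([a, a, rng.normal(size=12)]))
        pruned, report = spearman_prune(t, seed=0)
        assert pruned.n_features == 2
        assert len(report.dropped) == 1
        kept, dropped, rho = report.dropped[0]
        assert {kept, dropped} == {"f0", "f1"} and rho == pytest.approx(1.0)

    def test_monotone_transform_counts_as_collinear(self):
        rng = np.random.default_rng(3)
        a = np.abs(rng.normal(size=15)) + 0.1
        t = make_table(np.column_stack([a, a ** 2, rng.normal(size=15)]))
        pruned, _ = spearman_prune(t, seed=0)
        assert pruned.n_features == 2

    def test_strong_negative_correlation_pruned(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=15)
        t = make_table(np.column_stack([a, -a, rng.normal(size=15)]))
        pruned, _ = spearman_prune(t, seed=0)
        assert pruned.n_features == 2

    def test_exact_threshold_tie_retained(self):
        # permutation of 1..9 with sum of squared rank differences 30
        # -> Spearman rho = 1 - 6*30/(9*80) = 0.75 exactly ("above 0.75"
        # is strict, so the pair survives)
        x = np.arange(1, 10, dtype=float)
        y = x.copy()
        for i, j in [(0, 1), (2, 3), (4, 6), (5, 8)]:
            y[i], y[j] = y[j], y[i]
        rho = stats.spearmanr(x, y).statistic
        assert rho == pytest.approx(0.75, abs=1e-12)
        pruned, report = spearman_prune(make_table(np.column_stack([x, y])), seed=0)
        assert pruned.n_features == 2 and not report.dropped

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(20, 4))
        cols = [base[:, 0], base[:, 0] + 0.05 * rng.normal(size=20),
                base[:, 1], -base[:, 1] + 0.05 * rng.normal(size=20),
                base[:, 2], base[:, 3]] + [rng.normal(size=20) for _ in range(4)]
        t = make_table(np.column_stack(cols))
        pruned, report = spearman_prune(t, seed=1)
        oracle = brute_force_spearman_components(t.values)
        # one survivor per oracle component
        names = list(t.feature_names)
        kept_idx = sorted(names.index(f) for f in pruned.feature_names)
        assert len(kept_idx) == len(oracle)
        for comp in oracle:
            assert len(set(comp) & set(kept_idx)) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=18)
        t = make_table(np.column_stack(
            [a, a + 0.01 * rng.normal(size=18), rng.normal(size=18),
             rng.normal(size=18)]))
        once, _ = spearman_prune(t, seed=2)
        twice, report = spearman_prune(once, seed=3)
        assert list(twice.feature_names) == list(once.feature_names)
        assert not report.dropped

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=10)
        t = make_table(np.column_stack([a, a, a, rng.normal(size=10)]))
        k1, _ = spearman_prune(t, seed=42)
        k2, _ = spearman_prune(t, seed=42)
        assert list(k1.feature_names) == list(k2.feature_names)


class TestAssembleDynamic:
    def test_sixtytwo_plus_seven_is_sixtynine(self, trial_cohort):
        fc = fold_change_features(trial_cohort.plasma)
        combined = assemble_dynamic(trial_cohort.features, fc)
        assert trial_cohort.features.n_features == 62
        assert fc.n_features == 7
        assert combined.n_features == 69

    def test_empty_dynamic_is_identity(self, trial_cohort):
        fc = fold_change_features(trial_cohort.plasma)
        empty = fc.select_features([])
        combined = assemble_dynamic(trial_cohort.features, empty)
        pd.testing.assert_frame_equal(combined.values,
                                      trial_cohort.features.values)

    def test_patient_mismatch_rejected(self, trial_cohort):
        fc = fold_change_features(trial_cohort.plasma)
        fc_short = fc.select_patients(list(fc.patient_ids[:-1]))
        with pytest.raises(ValidationError):
            assemble_dynamic(trial_cohort.features, fc_short)


class TestPreprocessModel:
    def test_heldout_row_transformed_with_training_statistics(self):
        rng = np.random.default_rng(8)
        arr = rng.normal(size=(15, 4))
        arr[2, 1] = np.nan
        table = make_table(arr)
        train = table.select_patients([f"P{i}" for i in range(14)])
        model = PreprocessModel(seed=0)
        fitted = model.fit_transform(train)
        held = model.transform(table.select_patients(["P14"]))
        assert list(held.feature_names) == list(fitted.feature_names)
        assert held.is_complete
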