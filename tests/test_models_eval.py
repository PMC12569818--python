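import numpy as np
import pytest

from pairddg.models_eval import (
    RegressorSpec,
    assign_distance_bin,
    classify_resistance,
    compute_metrics,
    grid_sweep,
    make_regressor,
    repeat_harness,
    stratify_by_location,
    threshold_from_fold_change,
    train_model,
)
from pairddg.records import MutationRecord


def brute_force_metrics(y, yhat):
    """Independent re-implementation of the four metrics from first
    principles (loops + rank formulae), used as the oracle."""
    n = len(y)
    mae = sum(abs(a - b) for a, b in zip(yhat, y)) / n
    rmse = (sum((a - b) ** 2 for a, b in zip(yhat, y)) / n) ** 0.5
    my, mh = sum(y) / n, sum(yhat) / n
    num = sum((a - my) * (b - mh) for a, b in zip(y, yhat))
    den = (sum((a - my) ** 2 for a in y) * sum((b - mh) ** 2 for b in yhat)) ** 0.5
    pearson = num / den

    def avg_ranks(v):
        order = sorted(range(n), key=lambda i: v[i])
        ranks = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    ry, rh = avg_ranks(list(y)), avg_ranks(list(yhat))
    mry, mrh = sum(ry) / n, sum(rh) / n
    num = sum((a - mry) * (b - mrh) for a, b in zip(ry, rh))
    den = (sum((a - mry) ** 2 for a in ry) * sum((b - mrh) ** 2 for b in rh)) ** 0.5
    spearman = num / den
    return mae, rmse, pearson, spearman


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.mae, m.rmse) == (0.0, 0.0)
        assert m.pearson == pytest.approx(1.0)
        assert m.spearman == pytest.approx(1.0)

    def test_spearman_rank_formula_example(self):
        # one swapped adjacent pair: sum d^2 = 2, rho = 1 - 12/60 = 0.8
        m = compute_metrics([1, 2, 3, 4], [1, 3, 2, 4])
        assert m.spearman == pytest.approx(0.8)

    def test_hand_evaluated_errors(self):
        m = compute_metrics([1.0, 2.0], [2.0, 4.0])
        assert m.mae == pytest.approx(1.5)
        assert m.rmse == pytest.approx(np.sqrt(2.5))

    def test_zero_variance_flagged_not_raised(self):
        m = compute_metrics([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert np.isnan(m.pearson) and np.isnan(m.spearman)
        assert "zero-variance" in m.flags
        assert m.mae > 0

    def test_oracle_equivalence_including_ties(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for i in range(200):
            n = int(rng.integers(3, 40))
            y = rng.normal(size=n)
            yhat = rng.normal(size=n)
            if i % 3 == 0:  # force ties on both sides
                y = np.round(y)
                yhat = np.round(yhat, 1)
            if np.std(y) == 0 or np.std(yhat) == 0:
                continue
            m = compute_metrics(y, yhat)
            ref = brute_force_metrics(y, yhat)
            worst = max(
                worst,
                abs(m.mae - ref[0]), abs(m.rmse - ref[1]),
                abs(m.pearson - ref[2]), abs(m.spearman - ref[3]),
            )
        assert worst <= 1e-12

    def test_pearson_affine_and_spearman_monotone_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        yhat = rng.normal(size=50)
        base = compute_metrics(y, yhat)
        affine = compute_metrics(y, 2.5 * yhat + 7.0)
        assert affine.pearson == pytest.approx(base.pearson, abs=1e-12)
        mono = compute_metrics(y, np.exp(yhat))  # strictly increasing
        assert mono.spearman == pytest.approx(base.spearman, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0, 2.0], [1.0])


class TestThreshold:
    def test_tenfold_at_298K_rounds_to_1_36(self):
        assert round(threshold_from_fold_change(10.0), 2) == 1.36

    def test_small_fold_limit(self):
        assert threshold_from_fold_change(1.0 + 1e-9) == pytest.approx(0.0, abs=1e-9)

    def test_log_identity_fold_100(self):
        assert threshold_from_fold_change(100.0) == pytest.approx(
            2 * threshold_from_fold_change(10.0)
        )

    def test_strictly_increasing_in_both_arguments(self):
        folds = [2.0, 5.0, 10.0, 50.0]
        vals = [threshold_from_fold_change(f) for f in folds]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        temps = [273.0, 298.0, 310.0]
        vals = [threshold_from_fold_change(10.0, t) for t in temps]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("fold,temp", [(1.0, 298.0), (0.5, 298.0), (10.0, -5.0)])
    def test_domain_errors(self, fold, temp):
        with pytest.raises(ValueError):
            threshold_from_fold_change(fold, temp)


class TestClassification:
    def test_perfect_predictions(self):
        truth = [2.0, 0.5, 1.5, -1.0]
        rep = classify_resistance(truth, truth)
        assert rep.accuracy == 1.0
        assert rep.fp == rep.fn == 0
        assert rep.auc == 1.0

    def test_separable_scores_auc_one(self):
        truth = [3.0, 2.0, 0.5, -1.0]
        rep = classify_resistance(truth, [0.9, 0.8, 0.2, 0.1])
        assert rep.auc == 1.0

    def test_enumerated_confusion(self):
        rep = classify_resistance([2.0, 1.0], [1.5, 1.4], threshold=1.36)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (1, 1, 0, 0)
        assert rep.accuracy == 0.5

    def test_single_class_auc_flagged(self):
        rep = classify_resistance([0.1, 0.2, 0.3], [0.1, 0.5, 2.0])
        assert np.isnan(rep.auc)
        assert "single-class" in rep.flags
        assert 0.0 <= rep.accuracy <= 1.0

    def test_boundary_flag_flips_label(self):
        at = classify_resistance([1.36], [1.36] * 1 + [], threshold=1.36)
        assert at.tp == 1
        above_only = classify_resistance([1.36], [1.36], threshold=1.36,
                                         resistant_at_threshold=False)
        assert above_only.tn == 1

    def test_confusion_sums_to_n(self):
        rng = np.random.default_rng(0)
        t, p = rng.normal(1, 1, 50), rng.normal(1, 1, 50)
        rep = classify_resistance(t, p)
        assert rep.confusion.sum() == 50 == rep.n


class TestTrainModel:
    def test_constant_target_constant_prediction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = np.full(30, 2.5)
        for name in ("rf", "linear"):
            model = train_model(RegressorSpec(name), X, y)
            np.testing.assert_allclose(model.predict(X), 2.5, atol=1e-8)

    def test_svr_fits_exact_linear_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        model = train_model(
            RegressorSpec.make("svr", kernel="linear", epsilon=1e-4, C=100.0), X, y
        )
        r = compute_metrics(y, model.predict(X))
        assert r.pearson > 0.99

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 8))
        y = rng.normal(size=60)
        spec = RegressorSpec.make("rf", seed=7, n_estimators=20)
        p1 = train_model(spec, X, y).predict(X)
        p2 = train_model(spec, X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_name_lists_registry(self):
        with pytest.raises(KeyError, match="rf"):
            train_model(RegressorSpec("no-such-model"), np.zeros((3, 2)), np.zeros(3))

    def test_nan_rejected(self):
        X = np.zeros((3, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train_model(RegressorSpec("rf"), X, np.zeros(3))

    def test_deep_stubs_raise(self):
        with pytest.raises(NotImplementedError):
            make_regressor(RegressorSpec("transformer"))


class TestRepeatHarness:
    def test_oracle_experiment_sd_zero(self):
        def run(seed):
            y = np.arange(10.0)
            return compute_metrics(y, y)

        agg = repeat_harness(run, n_repeats=5, base_seed=0)
        assert agg.mean("pearson") == pytest.approx(1.0)
        assert agg.sd("pearson") == 0.0

    def test_seed_insensitive_experiment_sd_zero(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.normal(size=20), rng.normal(size=20)

        agg = repeat_harness(lambda seed: compute_metrics(y, yhat), n_repeats=3)
        assert agg.sd("mae") == 0.0

    def test_failures_disclosed(self):
        def run(seed):
            if seed == 1:
                raise RuntimeError("boom")
            y = np.arange(5.0)
            return compute_metrics(y, y)

        agg = repeat_harness(run, n_repeats=3, base_seed=0)
        assert agg.n_completed == 2
        assert agg.n_failed == 1
        assert "seed 1" in agg.failures[0]

    def test_minimum_repeats(self):
        with pytest.raises(ValueError):
            repeat_harness(lambda s: None, n_repeats=1)


class TestStratification:
    def make_records(self, distances):
        return [
            MutationRecord(
                record_id=f"r{i}", uniprot_id="P", wild_seq="ACDT",
                mutation_spec="A1C", smiles="CCO", ddg=0.0, distance=d,
            )
            for i, d in enumerate(distances)
        ]

    def test_bin_assignment_examples(self):
        assert assign_distance_bin(3.0) == "pocket"
        assert assign_distance_bin(8.0) == "intermediate"
        assert assign_distance_bin(20.0) == "distal"

    def test_boundary_15(self):
        assert assign_distance_bin(15.0) == "intermediate"
        assert assign_distance_bin(15.0001) == "distal"

    def test_all_distal(self):
        recs = self.make_records([50.0] * 6)
        rep = stratify_by_location(recs, np.arange(6.0), np.arange(6.0))
        assert rep.counts == {"pocket": 0, "intermediate": 0, "distal": 6}
        assert rep.per_bin["distal"].pearson == pytest.approx(1.0)
        assert rep.per_bin["pocket"] is None

    def test_missing_distance_excluded_and_counted(self):
        recs = self.make_records([3.0, None, 20.0, 9.0])
        rep = stratify_by_location(recs, np.zeros(4), np.zeros(4))
        assert rep.n_excluded == 1
        assert sum(rep.counts.values()) == 3


class TestGridSweep:
    def setup_linear(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 6))
        w = rng.normal(size=6)
        y = X @ w + rng.normal(0, 0.05, size=120)
        return X[:80], y[:80], X[80:], y[80:]

    def test_single_spec_single_row(self):
        Xtr, ytr, Xva, yva = self.setup_linear()
        table, best = grid_sweep([RegressorSpec("linear")], Xtr, ytr, Xva, yva)
        assert len(table) == 1
        assert best.name == "linear"

    def test_exhaustive_and_selects_better_model(self):
        Xtr, ytr, Xva, yva = self.setup_linear()
        specs = [
            RegressorSpec.make("lasso", alpha=50.0),   # over-shrunk
            RegressorSpec.make("lasso", alpha=0.001),  # near-OLS, favored
        ]
        table, best = grid_sweep(specs, Xtr, ytr, Xva, yva, n_repeats=2)
        assert len(table) == len(specs)
        assert best.params["alpha"] == 0.001

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            grid_sweep([], *self.setup_linear())
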