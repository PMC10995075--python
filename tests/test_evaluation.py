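"""Metrics, decision function, cross-validation harness, model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kidneystrip import evaluation as ev
from kidneystrip import spr
from kidneystrip.errors import ConfigurationError, DomainError, StratificationError
from kidneystrip.synthdata import sample_subject
from kidneystrip.egfr import evaluate_subject


class TestRMSE:
    def test_identical_vectors_zero(self):
        assert ev.rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_single_deviation(self):
        assert ev.rmse([0.0], [2.0]) == 2.0

    def test_matches_elementwise_loop_oracle(self, rng):
        y = rng.uniform(0, 60, 100)
        yhat = rng.uniform(0, 60, 100)
        acc = 0.0
        for a, b in zip(y, yhat):
            acc += (a - b) ** 2
        assert ev.rmse(y, yhat) == pytest.approx(np.sqrt(acc / 100), rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            ev.rmse([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            ev.rmse([1.0], [1.0, 2.0])


class TestF1:
    def test_perfect_predictions(self):
        y = ["healthy", "critical", "intermediate", "healthy"]
        assert ev.f1_score(y, list(y)) == 1.0

    def test_printed_formula_tp1_fp1_fn1(self):
        # each class has TP=1, FP=1, FN=1 -> TP / (TP + (FP+FN)/2) = 0.5
        true = ["healthy", "healthy", "critical", "critical"]
        pred = ["healthy", "critical", "critical", "healthy"]
        for avg in ("weighted", "macro", "micro"):
            assert ev.f1_score(true, pred, avg) == pytest.approx(0.5)

    def test_three_class_matches_confusion_matrix_oracle(self, rng):
        classes = np.array(ev.SEVERITY_CLASSES)
        true = classes[rng.integers(0, 3, 200)]
        pred = classes[rng.integers(0, 3, 200)]
        # independent oracle: per-class F1 from a hand-built confusion matrix
        f1s, weights = [], []
        for c in classes:
            tp = np.sum((true == c) & (pred == c))
            fp = np.sum((true != c) & (pred == c))
            fn = np.sum((true == c) & (pred != c))
            f1s.append(tp / (tp + 0.5 * (fp + fn)) if tp + fp + fn else 0.0)
            weights.append(np.sum(true == c))
        expected = np.average(f1s, weights=weights)
        assert ev.f1_score(true, pred, "weighted") == pytest.approx(expected, rel=1e-12)
        assert ev.f1_score(true, pred, "macro") == pytest.approx(np.mean(f1s), rel=1e-12)

    def test_absent_class_excluded_with_warning(self):
        true = ["healthy", "healthy", "intermediate"]
        pred = ["healthy", "intermediate", "intermediate"]
        with pytest.warns(UserWarning, match="critical"):
            score = ev.f1_score(true, pred)
        assert 0 < score < 1

    def test_unknown_averaging_rejected(self):
        with pytest.raises(ConfigurationError):
            ev.f1_score(["healthy"], ["healthy"], "harmonic")


class TestDecisionScore:
    def test_alpha_one_returns_f1(self):
        assert ev.decision_score(1.0, 0.83, 5.0) == 0.83

    def test_alpha_zero_returns_inverse_rmse(self):
        assert ev.decision_score(0.0, 0.83, 5.0) == pytest.approx(0.2)

    def test_winning_configuration_arithmetic(self):
        # alpha=0.75 with F1=0.9422 and RMSE=2.19
        assert ev.decision_score(0.75, 0.9422, 2.19) == pytest.approx(0.8208, abs=5e-5)

    def test_zero_rmse_rejected_unless_alpha_one(self):
        with pytest.raises(DomainError):
            ev.decision_score(0.75, 0.9, 0.0)
        assert ev.decision_score(1.0, 0.9, 0.0) == 0.9

    def test_invalid_alpha_rejected(self):
        with pytest.raises(DomainError):
            ev.decision_score(1.5, 0.9, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        alpha=st.floats(0.01, 0.99),
        f1=st.floats(0, 1),
        r=st.floats(0.1, 100),
        df1=st.floats(0.001, 0.5),
        dr=st.floats(0.001, 10),
    )
    def test_strictly_monotone_in_f1_and_rmse(self, alpha, f1, r, df1, dr):
        base = ev.decision_score(alpha, f1, r)
        assert ev.decision_score(alpha, min(f1 + df1, 1.0), r) >= base
        if f1 + df1 <= 1.0:
            assert ev.decision_score(alpha, f1 + df1, r) > base
        assert ev.decision_score(alpha, f1, r + dr) < base


def _toy_dataset(rng, n_captures=60, tiles_per_capture=2):
    """EvalDataset whose first feature column IS the concentration (so an
    identity-reading oracle predicts perfectly) plus noise columns.

    Concentrations are drawn from three strata (low/mid/high) so that all
    three severity classes are well represented for any census population.
    """
    per = n_captures // 3
    concs = np.concatenate(
        [
            rng.uniform(0.3, 0.8, per),  # mostly healthy
            rng.uniform(2.5, 4.0, per),  # mostly intermediate
            rng.uniform(10.0, 60.0, n_captures - 2 * per),  # mostly critical
        ]
    )
    rows, caps = [], []
    for i, c in enumerate(concs):
        for _ in range(tiles_per_capture):
            rows.append([c, *rng.normal(size=3)])
            caps.append(f"cap{i:03d}")
    return ev.EvalDataset(
        X=np.array(rows), concentrations=np.repeat(concs, tiles_per_capture),
        capture_ids=np.array(caps),
    )


class _Oracle:
    """Reads the concentration straight out of feature column 0."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return X[:, 0]


class TestRunExperiment:
    def test_perfect_oracle_scores_f1_one_rmse_zero(self, rng):
        ds = _toy_dataset(rng)
        spec = ev.ModelSpec("oracle", factory=lambda rs: _Oracle())
        rep = ev.run_experiment(ds, spec, n_folds=3, n_experiments=2, seed=1)
        assert rep.mean_f1 == 1.0
        assert rep.mean_rmse == 0.0
        for e in rep.experiments:
            for f in e["folds"]:
                assert f["f1"] == 1.0 and f["rmse"] == 0.0

    def test_deterministic_given_master_seed(self, tiny_tiled_dataset):
        spec = ev.ModelSpec(
            "knn", spr.PartitionScheme((0, 4, 20, 60)), spr.SubEstimatorSpec("KNN")
        )
        r1 = ev.run_experiment(tiny_tiled_dataset, spec, n_folds=3, n_experiments=2, seed=9)
        r2 = ev.run_experiment(tiny_tiled_dataset, spec, n_folds=3, n_experiments=2, seed=9)
        assert r1.experiments == r2.experiments
        assert r1.confusion == r2.confusion

    def test_mean_recomputable_from_experiments(self, tiny_tiled_dataset):
        spec = ev.ModelSpec("knn-global", None, spr.SubEstimatorSpec("KNN"))
        rep = ev.run_experiment(tiny_tiled_dataset, spec, n_folds=3, n_experiments=3, seed=4)
        assert rep.mean_f1 == pytest.approx(
            np.mean([e["f1"] for e in rep.experiments]), abs=1e-12
        )
        assert rep.mean_rmse == pytest.approx(
            np.mean([e["rmse"] for e in rep.experiments]), abs=1e-12
        )
        # decision score recomputable from the stored per-experiment F1/RMSE
        for e in rep.experiments:
            assert e["decision"] == pytest.approx(
                ev.decision_score(rep.alpha, e["f1"], e["rmse"]), abs=1e-12
            )

    def test_stratification_error_when_class_too_rare(self, rng):
        # concentrations so low that nearly everyone is healthy
        concs = np.full(20, 0.2)
        concs[0] = 60.0  # a single capture can be non-healthy
        ds = ev.EvalDataset(
            X=np.column_stack([concs, rng.normal(size=20)]),
            concentrations=concs,
            capture_ids=np.array([f"c{i}" for i in range(20)]),
        )
        spec = ev.ModelSpec("oracle", factory=lambda rs: _Oracle())
        with pytest.raises(StratificationError):
            ev.run_experiment(ds, spec, n_folds=5, n_experiments=1, seed=0)


class TestStratifiedFolds:
    def _severity(self, ds, seed):
        rng = np.random.default_rng(seed)
        subjects = {c: sample_subject(rng) for c in np.unique(ds.capture_ids)}
        return np.array(
            [
                evaluate_subject(c, subjects[cid], floor=True).severity
                for c, cid in zip(ds.concentrations, ds.capture_ids)
            ]
        )

    def test_folds_partition_dataset(self, rng):
        ds = _toy_dataset(rng, n_captures=50, tiles_per_capture=4)
        sev = self._severity(ds, 0)
        folds = ev.stratified_folds(ds.X, sev, ds.capture_ids, 5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(len(ds)))  # exhaustive, disjoint
        for tr, te in folds:
            assert not set(tr) & set(te)

    def test_capture_tiles_never_split_across_folds(self, rng):
        ds = _toy_dataset(rng, n_captures=50, tiles_per_capture=4)
        sev = self._severity(ds, 0)
        for tr, te in ev.stratified_folds(ds.X, sev, ds.capture_ids, 5, seed=1):
            assert not set(ds.capture_ids[tr]) & set(ds.capture_ids[te])

    def test_fold_class_proportions_track_global(self, rng):
        ds = _toy_dataset(rng, n_captures=100, tiles_per_capture=4)
        sev = self._severity(ds, 3)
        classes, global_counts = np.unique(sev, return_counts=True)
        for _, te in ev.stratified_folds(ds.X, sev, ds.capture_ids, 5, seed=2):
            for cls, total in zip(classes, global_counts):
                got = np.sum(sev[te] == cls)
                # within one capture (4 tiles) of the proportional share
                assert abs(got - total / 5) <= 4 + 1e-9


class TestCompareModels:
    def test_single_bin_spr_ties_global_regressor(self, tiny_tiled_dataset):
        lo = tiny_tiled_dataset.concentrations.min()
        hi = tiny_tiled_dataset.concentrations.max()
        specs = [
            ev.ModelSpec(
                "spr-1bin", spr.PartitionScheme((lo, hi)), spr.SubEstimatorSpec("KNN")
            ),
            ev.ModelSpec("global", None, spr.SubEstimatorSpec("KNN")),
        ]
        table, reports = ev.compare_models(
            tiny_tiled_dataset, specs, seed=5, n_folds=3, n_experiments=2
        )
        assert reports["spr-1bin"].mean_f1 == reports["global"].mean_f1
        assert reports["spr-1bin"].mean_rmse == reports["global"].mean_rmse

    def test_ranking_sorted_descending(self, tiny_tiled_dataset, rng):
        specs = [
            ev.ModelSpec("oracle", factory=lambda rs: _Oracle()),
            ev.ModelSpec("knn-global", None, spr.SubEstimatorSpec("KNN")),
        ]
        ds = _toy_dataset(rng)
        table, _ = ev.compare_models(ds, specs, seed=5, n_folds=3, n_experiments=2)
        vals = table["mean_decision"].to_numpy()
        assert np.all(np.diff(vals) <= 0)
        assert table.iloc[0]["model"] == "oracle"  # RMSE 0 dominates

    def test_fewer_than_two_specs_rejected(self, tiny_tiled_dataset):
        with pytest.raises(ConfigurationError):
            ev.compare_models(
                tiny_tiled_dataset, [ev.ModelSpec("only", None)], seed=0
            )
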