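"""Metrics, repeated stratified cross-validation, and model comparison.

Model quality is judged jointly on CKD-severity classification (F1) and
creatinine regression (RMSE), combined by the decision function

    f_decision(alpha, F1, RMSE) = alpha * F1 + (1 - alpha) / RMSE,

with alpha = 0.75 by default. Evaluation uses 5-fold cross-validation
stratified by CKD severity, with all tiles of one capture kept in the same
fold (tiles of a capture are near-duplicates; splitting them would leak), and
the whole procedure is repeated N = 10 times with freshly drawn census
populations, since severity labels depend on the subject assigned to each
capture. Reported metrics are means across the N experiments.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedGroupKFold

from . import spr
from .egfr import SeverityThresholds, Subject, evaluate_subject
from .errors import ConfigurationError, DomainError, StratificationError
from .features import FeatureConfig, extract_features
from .imaging import MaskRanges, preprocess_capture
from .synthdata import CaptureRecord, CensusDistribution, sample_subject

__all__ = [
    "SEVERITY_CLASSES",
    "rmse",
    "f1_score",
    "decision_score",
    "EvalDataset",
    "ModelSpec",
    "EvalReport",
    "dataset_from_captures",
    "stratified_folds",
    "run_experiment",
    "compare_models",
]

SEVERITY_CLASSES = ("healthy", "intermediate", "critical")
DEFAULT_ALPHA = 0.75


def rmse(true: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean squared error sqrt(sum((y - yhat)^2) / n), in mg/dL."""
    y = np.asarray(true, dtype=np.float64)
    yhat = np.asarray(predicted, dtype=np.float64)
    if y.shape != yhat.shape:
        raise DomainError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise DomainError("RMSE of empty input is undefined")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def f1_score(
    true: Sequence[str], predicted: Sequence[str], averaging: str = "weighted"
) -> float:
    """Multi-class F1 with per-class F1 = TP / (TP + (FP + FN) / 2).

    Classes absent from both the true and predicted labels are excluded with
    a warning. ``averaging`` is one of weighted (default), macro, micro.
    """
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape:
        raise DomainError(f"length mismatch: {true.shape} vs {predicted.shape}")
    if averaging not in ("weighted", "macro", "micro"):
        raise ConfigurationError(f"unknown averaging {averaging!r}")
    present = [c for c in SEVERITY_CLASSES if c in true or c in predicted]
    if not present:
        present = sorted(set(true) | set(predicted))
    missing = set(SEVERITY_CLASSES) - set(present)
    if missing and set(true) <= set(SEVERITY_CLASSES):
        warnings.warn(
            f"classes absent from both true and predicted labels, excluded: {sorted(missing)}",
            stacklevel=2,
        )
    return float(
        skmetrics.f1_score(
            true, predicted, labels=present, average=averaging, zero_division=0.0
        )
    )


def decision_score(alpha: float, f1: float, rmse_value: float) -> float:
    """Joint ranking score alpha * F1 + (1 - alpha) / RMSE.

    Strictly increasing in F1 and decreasing in RMSE for alpha in (0, 1).
    """
    if not 0.0 <= alpha <= 1.0:
        raise DomainError(f"alpha must be in [0, 1], got {alpha}")
    if rmse_value < 0:
        raise DomainError(f"RMSE must be >= 0, got {rmse_value}")
    if rmse_value == 0:
        if alpha < 1.0:
            raise DomainError("decision score undefined for RMSE = 0 with alpha < 1")
        return float(f1)
    return float(alpha * f1 + (1.0 - alpha) / rmse_value)


def _safe_decision(alpha: float, f1: float, rmse_value: float) -> float:
    # internal: a perfect regressor (RMSE 0) dominates any ranking
    if rmse_value == 0 and alpha < 1.0:
        return float("inf")
    return decision_score(alpha, f1, rmse_value)


@dataclass
class EvalDataset:
    """Feature matrix plus ground truth and capture grouping, one row per tile."""

    X: np.ndarray
    concentrations: np.ndarray
    capture_ids: np.ndarray
    feature_config: FeatureConfig | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.concentrations = np.asarray(self.concentrations, dtype=np.float64)
        self.capture_ids = np.asarray(self.capture_ids)
        n = self.X.shape[0]
        if not (len(self.concentrations) == len(self.capture_ids) == n):
            raise DomainError("X, concentrations and capture_ids must align")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class ModelSpec:
    """Recipe for a model entering the comparison harness.

    ``partition=None`` denotes a single-phase global regressor baseline (the
    design used by prior test-strip studies); otherwise an SPR model with the
    given partition is fitted. ``factory``, when given, overrides everything:
    it must return an object with fit(X, y) / predict(X) and is used for
    injecting reference models (e.g. oracles) into the harness.
    """

    name: str
    partition: spr.PartitionScheme | None = None
    estimator: spr.SubEstimatorSpec = field(
        default_factory=lambda: spr.SubEstimatorSpec("HBT")
    )
    clamp: bool = False
    factory: Callable[[int | None], object] | None = None


class _FittedSpec:
    """Uniform predict interface over SPR models, global regressors and
    factory-injected estimators."""

    def __init__(self, spec: ModelSpec, X: np.ndarray, y: np.ndarray, rs: int | None):
        if spec.factory is not None:
            self._est = spec.factory(rs)
            self._est.fit(X, y)
            self._kind = "custom"
        elif spec.partition is None:
            self._est = spr.make_estimator(spec.estimator, "regressor", rs)
            self._est.fit(X, y)
            self._kind = "global"
        else:
            self._est = spr.fit(
                X, y, spec.partition, spec.estimator, clamp=spec.clamp, random_state=rs
            )
            self._kind = "spr"

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._kind == "spr":
            return np.atleast_1d(self._est.predict_concentration(X))
        return np.asarray(self._est.predict(X), dtype=np.float64)


@dataclass
class EvalReport:
    """Per-experiment and mean metrics for one model spec."""

    spec_name: str
    alpha: float
    n_folds: int
    experiments: list[dict]
    mean_f1: float
    mean_rmse: float
    mean_decision: float
    confusion: list[list[int]]  # summed over experiments and folds
    train_time_s: float
    inference_time_s: float

    def to_dict(self) -> dict:
        return {
            "spec_name": self.spec_name,
            "alpha": self.alpha,
            "n_folds": self.n_folds,
            "experiments": self.experiments,
            "mean_f1": self.mean_f1,
            "mean_rmse": self.mean_rmse,
            "mean_decision": self.mean_decision,
            "confusion": self.confusion,
            "classes": list(SEVERITY_CLASSES),
            "train_time_s": self.train_time_s,
            "inference_time_s": self.inference_time_s,
        }


def dataset_from_captures(
    records: list[CaptureRecord],
    feature_config: FeatureConfig | None = None,
    time_points: tuple[int, ...] = (22,),
    mask_ranges: MaskRanges | None = None,
    crop: tuple[int, int] = (128, 64),
) -> EvalDataset:
    """Preprocess captures (mask, crop, 4x tiling) at the selected time points
    and extract features; default is the 22-minute time point only, the most
    informative one."""
    feature_config = feature_config or FeatureConfig()
    tiles, concs, caps = [], [], []
    for rec in records:
        if rec.sample.time_point not in time_points:
            continue
        for t in preprocess_capture(rec.sample.image, mask_ranges, crop):
            tiles.append(t)
            concs.append(rec.sample.concentration)
            caps.append(rec.sample.capture_id)
    if not tiles:
        raise DomainError(f"no captures at time points {time_points}")
    X = extract_features(tiles, feature_config)
    return EvalDataset(
        X=X,
        concentrations=np.array(concs),
        capture_ids=np.array(caps),
        feature_config=feature_config,
    )


def _draw_population(
    capture_ids: np.ndarray,
    concentrations: np.ndarray,
    rng: np.random.Generator,
    dist: CensusDistribution | None,
    thresholds: SeverityThresholds | None,
) -> tuple[dict[str, Subject], np.ndarray]:
    """One subject per capture; per-row severity from (true conc, subject)."""
    subjects: dict[str, Subject] = {}
    for cid in pd.unique(capture_ids):
        subjects[cid] = sample_subject(rng, dist)
    severity = np.array(
        [
            evaluate_subject(c, subjects[cid], thresholds, floor=True).severity
            for c, cid in zip(concentrations, capture_ids)
        ]
    )
    return subjects, severity


def stratified_folds(
    X: np.ndarray,
    severity: np.ndarray,
    groups: np.ndarray,
    n_folds: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Severity-stratified folds with capture-level grouping.

    Folds partition the rows (disjoint and exhaustive) and never split a
    capture's tiles across folds; class proportions per fold track the global
    proportions up to group granularity.
    """
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(X, severity, groups=groups)]


def run_experiment(
    dataset: EvalDataset,
    spec: ModelSpec,
    n_folds: int = 5,
    n_experiments: int = 10,
    seed: int = 0,
    *,
    alpha: float = DEFAULT_ALPHA,
    dist: CensusDistribution | None = None,
    thresholds: SeverityThresholds | None = None,
    averaging: str = "weighted",
) -> EvalReport:
    """Repeated stratified grouped cross-validation of one model spec.

    For each of ``n_experiments``: draw a fresh census population (one subject
    per capture), recompute severity labels, split into ``n_folds`` folds
    stratified by severity with capture-level grouping, and fit/evaluate the
    model per fold. F1 is computed on severity classes derived from predicted
    concentrations via the MDRD equation; RMSE on the concentrations
    themselves.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_experiments)
    experiments = []
    confusion = np.zeros((3, 3), dtype=int)
    t_train = t_infer = 0.0
    for e in range(n_experiments):
        exp_ss = children[e]
        rng = np.random.default_rng(exp_ss)
        subjects, severity = _draw_population(
            dataset.capture_ids, dataset.concentrations, rng, dist, thresholds
        )
        cap_sev = pd.DataFrame(
            {"cid": dataset.capture_ids, "sev": severity}
        ).drop_duplicates("cid")
        counts = cap_sev["sev"].value_counts()
        if (counts < n_folds).any():
            worst = counts.idxmin()
            raise StratificationError(
                f"class {worst!r} has {counts.min()} captures, fewer than "
                f"{n_folds} folds"
            )
        fold_seed = int(rng.integers(2**31 - 1))
        folds = stratified_folds(
            dataset.X, severity, dataset.capture_ids, n_folds, fold_seed
        )
        fold_records = []
        for k, (tr, te) in enumerate(folds):
            fit_seed = int(np.random.default_rng(exp_ss.spawn(1)[0]).integers(2**31 - 1))
            t0 = time.perf_counter()
            model = _FittedSpec(
                spec, dataset.X[tr], dataset.concentrations[tr], fit_seed
            )
            t_train += time.perf_counter() - t0
            t0 = time.perf_counter()
            pred_conc = model.predict(dataset.X[te])
            t_infer += time.perf_counter() - t0
            pred_sev = np.array(
                [
                    evaluate_subject(
                        p, subjects[cid], thresholds, floor=True
                    ).severity
                    for p, cid in zip(pred_conc, dataset.capture_ids[te])
                ]
            )
            true_sev = severity[te]
            fold_f1 = f1_score(true_sev, pred_sev, averaging)
            fold_rmse = rmse(dataset.concentrations[te], pred_conc)
            confusion += skmetrics.confusion_matrix(
                true_sev, pred_sev, labels=list(SEVERITY_CLASSES)
            )
            fold_records.append(
                {
                    "fold": k,
                    "f1": fold_f1,
                    "rmse": fold_rmse,
                    "decision": _safe_decision(alpha, fold_f1, fold_rmse),
                }
            )
        exp_f1 = float(np.mean([f["f1"] for f in fold_records]))
        exp_rmse = float(np.mean([f["rmse"] for f in fold_records]))
        experiments.append(
            {
                "experiment": e,
                "folds": fold_records,
                "f1": exp_f1,
                "rmse": exp_rmse,
                "decision": _safe_decision(alpha, exp_f1, exp_rmse),
            }
        )
    return EvalReport(
        spec_name=spec.name,
        alpha=alpha,
        n_folds=n_folds,
        experiments=experiments,
        mean_f1=float(np.mean([x["f1"] for x in experiments])),
        mean_rmse=float(np.mean([x["rmse"] for x in experiments])),
        mean_decision=float(np.mean([x["decision"] for x in experiments])),
        confusion=confusion.tolist(),
        train_time_s=t_train,
        inference_time_s=t_infer,
    )


def compare_models(
    dataset: EvalDataset,
    specs: list[ModelSpec],
    seed: int = 0,
    *,
    n_folds: int = 5,
    n_experiments: int = 10,
    alpha: float = DEFAULT_ALPHA,
    dist: CensusDistribution | None = None,
    thresholds: SeverityThresholds | None = None,
) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    """Evaluate several model specs under identical conditions and rank them.

    Every spec sees the same seed, hence the same populations and folds.
    Returns the ranking table (descending mean decision score) and the full
    per-spec reports. Wall times are informational only.
    """
    if len(specs) < 2:
        raise ConfigurationError("compare_models needs at least 2 specs")
    reports: dict[str, EvalReport] = {}
    rows = []
    for spec in specs:
        rep = run_experiment(
            dataset,
            spec,
            n_folds=n_folds,
            n_experiments=n_experiments,
            seed=seed,
            alpha=alpha,
            dist=dist,
            thresholds=thresholds,
        )
        reports[spec.name] = rep
        rows.append(
            {
                "model": spec.name,
                "mean_decision": rep.mean_decision,
                "mean_f1": rep.mean_f1,
                "mean_rmse": rep.mean_rmse,
                "train_time_s": rep.train_time_s,
                "inference_time_s": rep.inference_time_s,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "mean_decision", ascending=False, ignore_index=True
    )
    return table, reports
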