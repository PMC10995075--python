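"""Selective Partitioned Regression (SPR).

SPR is a two-phase estimator for a regression target whose range is wide and
unevenly sampled. Phase 1 is a classifier that predicts which concentration
bin a sample falls into; phase 2 is a set of local regressors, one per bin,
each trained only on the samples whose true concentration lies in its bin. At
inference the phase-1 prediction selects the local regressor that produces the
final concentration estimate. With a single bin (chi = 1) SPR degenerates
exactly to the matched global regressor.

Six pluggable sub-estimator families are supported, each with classifier and
regressor variants: histogram gradient boosting (HBT), extreme gradient
boosting (XGB), random forest (RF), k-nearest neighbors (KNN), decision tree
(DT), and support vector machines (SVM). By default the same family is used
for both phases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from .errors import ConfigurationError, DomainError, FitError, SizeError

__all__ = [
    "PartitionScheme",
    "SubEstimatorSpec",
    "SPRModel",
    "FAMILIES",
    "assign_bin",
    "assign_bins",
    "make_estimator",
    "fit",
    "load_model",
]

FAMILIES = ("HBT", "XGB", "RF", "KNN", "DT", "SVM")

#: Default bin edges (mg/dL) for a 4-regressor model, following the
#: experimental concentration ranges of the assay design.
DEFAULT_EDGES_4BIN = (0.0, 4.0, 7.5, 19.0, 60.0)


@dataclass(frozen=True)
class PartitionScheme:
    """Concentration bin edges delta (mg/dL) defining chi = len(edges) - 1
    local regressors. Bins are [low, high) with the last bin right-closed."""

    edges: tuple[float, ...] = DEFAULT_EDGES_4BIN

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 2:
            raise ConfigurationError("need at least 2 edges (1 bin)")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigurationError(f"edges must be strictly increasing: {edges}")

    @property
    def chi(self) -> int:
        return len(self.edges) - 1

    def bin_range(self, index: int) -> tuple[float, float]:
        return self.edges[index], self.edges[index + 1]


@dataclass(frozen=True)
class SubEstimatorSpec:
    """A sub-estimator family plus hyperparameter overrides."""

    family: str = "HBT"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )


def assign_bin(concentration: float, partition: PartitionScheme) -> int:
    """Bin index i with delta_i <= c < delta_{i+1}; the last bin includes its
    upper edge. Concentrations outside [delta_0, delta_chi] are a domain
    error."""
    return int(assign_bins(np.asarray([concentration]), partition)[0])


def assign_bins(concentrations: np.ndarray, partition: PartitionScheme) -> np.ndarray:
    """Vectorized :func:`assign_bin`."""
    c = np.asarray(concentrations, dtype=np.float64)
    edges = np.asarray(partition.edges)
    if np.any(c < edges[0]) or np.any(c > edges[-1]):
        bad = c[(c < edges[0]) | (c > edges[-1])][0]
        raise DomainError(
            f"concentration {bad} outside partition span [{edges[0]}, {edges[-1]}]"
        )
    idx = np.searchsorted(edges, c, side="right") - 1
    return np.minimum(idx, partition.chi - 1).astype(int)


def make_estimator(spec: SubEstimatorSpec, task: str, random_state: int | None = 0):
    """Instantiate the classifier or regressor variant of a family.

    Stochastic families receive ``random_state`` so that repeated fits with
    equal seeds are reproducible; tree ensembles are pinned to one thread for
    determinism.
    """
    if task not in ("classifier", "regressor"):
        raise ConfigurationError(f"task must be classifier or regressor, got {task!r}")
    params = dict(spec.hyperparameters)
    fam, clf = spec.family, task == "classifier"
    if fam == "HBT":
        from sklearn.ensemble import (
            HistGradientBoostingClassifier,
            HistGradientBoostingRegressor,
        )

        cls = HistGradientBoostingClassifier if clf else HistGradientBoostingRegressor
        return cls(random_state=random_state, **params)
    if fam == "XGB":
        from xgboost import XGBClassifier, XGBRegressor

        cls = XGBClassifier if clf else XGBRegressor
        return cls(random_state=random_state, n_jobs=1, verbosity=0, **params)
    if fam == "RF":
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

        cls = RandomForestClassifier if clf else RandomForestRegressor
        return cls(random_state=random_state, n_jobs=1, **params)
    if fam == "KNN":
        from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor

        cls = KNeighborsClassifier if clf else KNeighborsRegressor
        return cls(**params)
    if fam == "DT":
        from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

        cls = DecisionTreeClassifier if clf else DecisionTreeRegressor
        return cls(random_state=random_state, **params)
    # SVM
    from sklearn.svm import SVC, SVR

    return SVC(random_state=random_state, **params) if clf else SVR(**params)


@dataclass
class SPRModel:
    """A fitted selective partitioned regressor.

    Holds the partition, the fitted phase-1 bin classifier (None when
    chi = 1), one fitted local regressor per bin, and the frozen
    configuration. Construct via :func:`fit` or :func:`load_model`.
    """

    partition: PartitionScheme
    phase1: object | None
    phase2: list
    classifier_spec: SubEstimatorSpec
    regressor_spec: SubEstimatorSpec
    clamp: bool = False
    random_state: int | None = 0
    feature_config: dict | None = None

    def _check_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise SizeError(
                f"expected feature dimension {self.n_features_}, got shape {X.shape}"
            )
        return X

    @property
    def n_features_(self) -> int:
        return self._n_features

    def predict_bin(self, X: np.ndarray) -> np.ndarray | int:
        """Phase-1 bin prediction (always 0 for a single-bin model)."""
        single = np.asarray(X).ndim == 1
        X2 = self._check_features(X)
        if self.partition.chi == 1:
            bins = np.zeros(X2.shape[0], dtype=int)
        else:
            bins = np.asarray(self.phase1.predict(X2), dtype=int)
        return int(bins[0]) if single else bins

    def predict_concentration(self, X: np.ndarray) -> np.ndarray | float:
        """Two-phase prediction: the regressor selected by the predicted bin
        estimates the concentration; optionally clamped to the bin's range."""
        single = np.asarray(X).ndim == 1
        X2 = self._check_features(X)
        bins = np.atleast_1d(self.predict_bin(X2))
        preds = np.empty(X2.shape[0], dtype=np.float64)
        for b in np.unique(bins):
            sel = bins == b
            preds[sel] = self.phase2[b].predict(X2[sel])
            if self.clamp:
                lo, hi = self.partition.bin_range(int(b))
                preds[sel] = np.clip(preds[sel], lo, hi)
        return float(preds[0]) if single else preds

    def save(self, directory: str | Path) -> None:
        """Serialize to a directory: JSON metadata plus per-estimator blobs.

        ``load_model`` of a saved bundle is prediction-exact.
        """
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "edges": list(self.partition.edges),
            "classifier_spec": {
                "family": self.classifier_spec.family,
                "hyperparameters": self.classifier_spec.hyperparameters,
            },
            "regressor_spec": {
                "family": self.regressor_spec.family,
                "hyperparameters": self.regressor_spec.hyperparameters,
            },
            "clamp": self.clamp,
            "random_state": self.random_state,
            "n_features": self._n_features,
            "feature_config": self.feature_config,
            "global_equivalent": self.partition.chi == 1,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2))
        if self.phase1 is not None:
            joblib.dump(self.phase1, d / "phase1.joblib")
        for i, reg in enumerate(self.phase2):
            joblib.dump(reg, d / f"phase2_{i}.joblib")


def fit(
    X: np.ndarray,
    concentrations: np.ndarray,
    partition: PartitionScheme | None = None,
    classifier_spec: SubEstimatorSpec | None = None,
    regressor_spec: SubEstimatorSpec | None = None,
    *,
    clamp: bool = False,
    random_state: int | None = 0,
    feature_config: dict | None = None,
) -> SPRModel:
    """Fit an SPR model.

    Phase 1 is trained on (X, true bin index); each local regressor i is
    trained only on the rows whose true concentration lies in bin i. When
    ``regressor_spec`` is omitted the classifier family is matched. An empty
    bin is a hard error (choose fewer bins or different edges).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(concentrations, dtype=np.float64)
    if X.ndim != 2:
        raise SizeError(f"X must be 2-D, got shape {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise SizeError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    partition = partition or PartitionScheme()
    classifier_spec = classifier_spec or SubEstimatorSpec("HBT")
    regressor_spec = regressor_spec or SubEstimatorSpec(
        classifier_spec.family, dict(classifier_spec.hyperparameters)
    )
    bins = assign_bins(y, partition)
    for i in range(partition.chi):
        if not np.any(bins == i):
            lo, hi = partition.bin_range(i)
            raise FitError(f"bin {i} [{lo}, {hi}) has no training samples")
    phase1 = None
    if partition.chi > 1:
        phase1 = make_estimator(classifier_spec, "classifier", random_state)
        phase1.fit(X, bins)
    phase2 = []
    for i in range(partition.chi):
        reg = make_estimator(regressor_spec, "regressor", random_state)
        sel = bins == i
        reg.fit(X[sel], y[sel])
        phase2.append(reg)
    model = SPRModel(
        partition=partition,
        phase1=phase1,
        phase2=phase2,
        classifier_spec=classifier_spec,
        regressor_spec=regressor_spec,
        clamp=clamp,
        random_state=random_state,
        feature_config=feature_config,
    )
    model._n_features = X.shape[1]
    return model


def load_model(directory: str | Path) -> SPRModel:
    """Load a model bundle written by :meth:`SPRModel.save`."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    partition = PartitionScheme(tuple(meta["edges"]))
    phase1 = None
    if (d / "phase1.joblib").exists():
        phase1 = joblib.load(d / "phase1.joblib")
    phase2 = [joblib.load(d / f"phase2_{i}.joblib") for i in range(partition.chi)]
    model = SPRModel(
        partition=partition,
        phase1=phase1,
        phase2=phase2,
        classifier_spec=SubEstimatorSpec(**meta["classifier_spec"]),
        regressor_spec=SubEstimatorSpec(**meta["regressor_spec"]),
        clamp=meta["clamp"],
        random_state=meta["random_state"],
        feature_config=meta.get("feature_config"),
    )
    model._n_features = meta["n_features"]
    return model
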