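"""Shallow structure-activity models, statsmodels-style.

:class:`StructureActivityModel` holds a labeled feature dataset (the 58
conserved-feature vectors with activation state and activity level per
structure) together with a model family and hyperparameters;
:meth:`~StructureActivityModel.fit` returns an :class:`ActivityResults`
object carrying the fitted classifier (inactive / intermediate / active)
and regressor (activity 0-100 %), feature importances, and a
``summary()`` table.  :meth:`~StructureActivityModel.cross_validate`
produces a stratified k-fold :class:`CVReport` (accuracy, MAE, pooled
R-squared), the headline benchmark of the approach.

Three shallow families are supported: gradient-boosted trees (xgboost),
random forest, and a single decision tree.  Tree models are used
deliberately: the datasets are a few hundred structures wide and 58
features deep, and tree importances give per-feature attribution.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np

from .errors import (
    DegenerateDataError,
    OutOfRangeError,
    SchemaMismatchError,
)
from .features import FeatureSchema, FeatureVector
from .structure_io import ACTIVATION_STATES

__all__ = [
    "MODEL_TYPES",
    "LabeledDataset",
    "StructureActivityModel",
    "ActivityResults",
    "CVReport",
]

MODEL_TYPES = ("xgboost", "random_forest", "decision_tree")

#: Default hyperparameters per family.  The boosted-tree settings
#: (300 estimators, depth 6, learning rate 0.1) are standard shallow-model
#: defaults; everything is overridable through ``StructureActivityModel``.
DEFAULT_HYPERPARAMS = {
    "xgboost": {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1},
    "random_forest": {"n_estimators": 300},
    "decision_tree": {},
}


@dataclass
class LabeledDataset:
    """Feature matrix with per-row activation state and activity level.

    Invariants: one schema for all rows; states from the three-class
    vocabulary; activities in [0, 100].
    """

    X: np.ndarray
    states: np.ndarray
    activities: np.ndarray
    schema: FeatureSchema | None = None
    feature_names: tuple[str, ...] | None = None
    structure_ids: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.states = np.asarray(self.states, dtype=object)
        self.activities = np.asarray(self.activities, dtype=float)
        n = self.X.shape[0]
        if self.states.shape != (n,) or self.activities.shape != (n,):
            raise DegenerateDataError("X, states and activities must have matching length")
        bad_states = set(self.states) - set(ACTIVATION_STATES)
        if bad_states:
            raise DegenerateDataError(f"unknown states {sorted(bad_states)}")
        if np.any(self.activities < 0) or np.any(self.activities > 100):
            raise OutOfRangeError("activities must lie in [0, 100]")
        if self.schema is not None and self.X.shape[1] != len(self.schema):
            raise SchemaMismatchError(
                f"X has {self.X.shape[1]} columns but schema defines {len(self.schema)}"
            )
        if self.feature_names is None and self.schema is not None:
            self.feature_names = self.schema.feature_names
        if self.feature_names is None:
            self.feature_names = tuple(f"f{i}" for i in range(self.X.shape[1]))

    @classmethod
    def from_vectors(cls, vectors: Sequence[FeatureVector], states, activities):
        schemas = {v.schema.fingerprint for v in vectors}
        if len(schemas) > 1:
            raise SchemaMismatchError("feature vectors built from different schemas")
        X = np.vstack([v.values for v in vectors])
        ids = np.array([v.frame_id for v in vectors], dtype=object)
        return cls(X, np.asarray(states), np.asarray(activities),
                   schema=vectors[0].schema, structure_ids=ids)

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class CVReport:
    """Stratified k-fold cross-validation metrics.

    ``accuracies`` and ``maes`` are per-fold (accuracy in %, MAE in
    activity percentage points); ``r2`` is computed on the pooled
    out-of-fold regression predictions.
    """

    k: int
    model_type: str
    accuracies: np.ndarray
    maes: np.ndarray
    r2: float
    seed: int

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    @property
    def mae_mean(self) -> float:
        return float(np.mean(self.maes))

    @property
    def mae_sd(self) -> float:
        return float(np.std(self.maes, ddof=1))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "model_type": self.model_type,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "mae_mean": self.mae_mean,
            "mae_sd": self.mae_sd,
            "r2": self.r2,
            "per_fold_accuracy": [float(a) for a in self.accuracies],
            "per_fold_mae": [float(m) for m in self.maes],
            "seed": self.seed,
        }

    def summary(self) -> str:
        return (
            f"{self.k}-fold CV, {self.model_type}\n"
            f"  state accuracy : {self.accuracy_mean:6.2f} % (SD {self.accuracy_sd:.2f})\n"
            f"  activity MAE   : {self.mae_mean:6.2f} %  (SD {self.mae_sd:.2f})\n"
            f"  pooled R^2     : {self.r2:6.3f}"
        )


def _make_estimators(model_type: str, seed: int, hyperparams: dict):
    params = dict(DEFAULT_HYPERPARAMS[model_type])
    params.update(hyperparams)
    if model_type == "xgboost":
        from xgboost import XGBClassifier, XGBRegressor

        clf = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **params)
        reg = XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **params)
    elif model_type == "random_forest":
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

        clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        reg = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    elif model_type == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

        clf = DecisionTreeClassifier(random_state=seed, **params)
        reg = DecisionTreeRegressor(random_state=seed, **params)
    else:
        raise ValueError(f"model_type must be one of {MODEL_TYPES}, got {model_type!r}")
    return clf, reg


class StructureActivityModel:
    """A structure-activity model specification bound to a dataset.

    Parameters
    ----------
    dataset
        A :class:`LabeledDataset` (or anything accepted by its
        constructor through :meth:`from_arrays`).
    model_type
        One of ``xgboost`` (gradient-boosted trees), ``random_forest``,
        ``decision_tree``.
    seed
        Seed used for estimator randomness and CV shuffling.
    **hyperparams
        Override the family defaults (``n_estimators``, ``max_depth``...).
    """

    def __init__(self, dataset: LabeledDataset, model_type: str = "xgboost",
                 seed: int = 0, **hyperparams):
        if model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}, got {model_type!r}")
        self.dataset = dataset
        self.model_type = model_type
        self.seed = int(seed)
        self.hyperparams = dict(hyperparams)

    @classmethod
    def from_arrays(cls, X, states, activities, schema=None, **kwargs):
        return cls(LabeledDataset(X, states, activities, schema=schema), **kwargs)

    @classmethod
    def from_dataframe(cls, df, feature_columns=None, state_column="state",
                       activity_column="activity", schema=None, **kwargs):
        """Build from a tidy table with one row per structure/frame."""
        if feature_columns is None:
            feature_columns = [
                c for c in df.columns
                if c not in (state_column, activity_column, "structure_id", "frame_id")
            ]
        ds = LabeledDataset(
            df[feature_columns].to_numpy(dtype=float),
            df[state_column].to_numpy(),
            df[activity_column].to_numpy(dtype=float),
            schema=schema,
            feature_names=tuple(feature_columns),
        )
        return cls(ds, **kwargs)

    # -- fitting ------------------------------------------------------

    def _check_trainable(self, states):
        if len(self.dataset) < 10:
            raise DegenerateDataError(
                f"need at least 10 rows to train, got {len(self.dataset)}"
            )
        if len(set(states)) < 2:
            raise DegenerateDataError("classification needs at least 2 states present")

    def fit(self, cv: int | None = None) -> "ActivityResults":
        """Fit classifier and regressor on the full dataset.

        ``cv=k`` additionally runs k-fold cross-validation and attaches
        the report to the results (shown by ``summary()``).
        """
        ds = self.dataset
        self._check_trainable(ds.states)
        clf, reg = _make_estimators(self.model_type, self.seed, self.hyperparams)
        codes, classes = _encode_states(ds.states)
        clf.fit(ds.X, codes)
        reg.fit(ds.X, ds.activities)
        results = ActivityResults(
            model=self,
            classifier=clf,
            regressor=reg,
            classes=classes,
            feature_names=tuple(ds.feature_names),
            schema_fingerprint=ds.schema.fingerprint if ds.schema is not None else None,
        )
        if cv is not None:
            results._cv = self.cross_validate(k=cv)
        return results

    def cross_validate(self, k: int = 5, seed: int | None = None) -> CVReport:
        """Stratified k-fold CV of both tasks; folds stratified by state."""
        from sklearn.metrics import r2_score
        from sklearn.model_selection import StratifiedKFold

        ds = self.dataset
        self._check_trainable(ds.states)
        if k < 2:
            raise OutOfRangeError(f"k must be >= 2, got {k}")
        if k > len(ds):
            raise OutOfRangeError(f"k={k} exceeds dataset size {len(ds)}")
        seed = self.seed if seed is None else int(seed)

        codes, classes = _encode_states(ds.states)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        accuracies, maes = [], []
        pooled_pred = np.empty(len(ds))
        for train, test in skf.split(ds.X, codes):
            clf, reg = _make_estimators(self.model_type, seed, self.hyperparams)
            fold_codes, _ = _encode_states(ds.states[train])
            clf.fit(ds.X[train], fold_codes)
            reg.fit(ds.X[train], ds.activities[train])
            present = np.array(sorted(set(ds.states[train]), key=ACTIVATION_STATES.index))
            pred_states = present[clf.predict(ds.X[test])]
            accuracies.append(100.0 * np.mean(pred_states == ds.states[test]))
            pred_act = np.clip(reg.predict(ds.X[test]), 0.0, 100.0)
            maes.append(float(np.mean(np.abs(pred_act - ds.activities[test]))))
            pooled_pred[test] = pred_act
        r2 = float(r2_score(ds.activities, pooled_pred))
        return CVReport(k=k, model_type=self.model_type,
                        accuracies=np.asarray(accuracies), maes=np.asarray(maes),
                        r2=r2, seed=seed)


def _encode_states(states) -> tuple[np.ndarray, np.ndarray]:
    """Map state strings to contiguous integer codes, activation-ordered."""
    present = sorted(set(states), key=ACTIVATION_STATES.index)
    lookup = {s: i for i, s in enumerate(present)}
    return np.array([lookup[s] for s in states]), np.array(present, dtype=object)


@dataclass
class ActivityResults:
    """Fitted structure-activity model.

    Carries the trained classifier and regressor, the activation-state
    vocabulary seen in training, the feature-name order and the schema
    fingerprint; prediction refuses inputs built from a different schema.
    """

    model: StructureActivityModel
    classifier: object
    regressor: object
    classes: np.ndarray
    feature_names: tuple[str, ...]
    schema_fingerprint: str | None = None
    _cv: CVReport | None = field(default=None, repr=False)

    @property
    def cv(self) -> CVReport | None:
        """The cross-validation report, if ``fit(cv=k)`` was used."""
        return self._cv

    # -- prediction ---------------------------------------------------

    def _as_matrix(self, x) -> np.ndarray:
        if isinstance(x, FeatureVector):
            if (self.schema_fingerprint is not None
                    and x.schema.fingerprint != self.schema_fingerprint):
                raise SchemaMismatchError(
                    "feature vector schema does not match the training schema"
                )
            arr = x.values[None, :]
        else:
            arr = np.atleast_2d(np.asarray(x, dtype=float))
        if arr.shape[1] != len(self.feature_names):
            raise SchemaMismatchError(
                f"expected {len(self.feature_names)} features, got {arr.shape[1]}"
            )
        return arr

    def predict_state(self, x):
        """Predict activation state(s): scalar for one vector, array for a matrix."""
        arr = self._as_matrix(x)
        labels = self.classes[self.classifier.predict(arr)]
        scalar = isinstance(x, FeatureVector) or np.asarray(x).ndim == 1
        return str(labels[0]) if scalar else labels

    def predict_activity(self, x):
        """Predict activity level(s) in percent, clamped to [0, 100]."""
        arr = self._as_matrix(x)
        pred = np.clip(np.asarray(self.regressor.predict(arr), dtype=float), 0.0, 100.0)
        scalar = isinstance(x, FeatureVector) or np.asarray(x).ndim == 1
        return float(pred[0]) if scalar else pred

    # -- attribution --------------------------------------------------

    def feature_importance(self, top_k: int | None = None):
        """Ranked (feature name, importance) from the regressor.

        Importances are total-gain based for boosted trees and
        impurity-decrease based for the sklearn forests/trees, normalised
        to sum to one over all features, sorted descending with ties
        broken by canonical feature order.
        """
        if self.model.model_type == "xgboost":
            booster = self.regressor.get_booster()
            gains = booster.get_score(importance_type="total_gain")
            raw = np.array(
                [gains.get(f"f{i}", 0.0) for i in range(len(self.feature_names))]
            )
        else:
            raw = np.asarray(self.regressor.feature_importances_, dtype=float)
        total = raw.sum()
        imp = raw / total if total > 0 else raw
        order = sorted(range(len(imp)), key=lambda i: (-imp[i], i))
        if top_k is None:
            top_k = len(imp)
        top_k = min(max(int(top_k), 0), len(imp))
        return [(self.feature_names[i], float(imp[i])) for i in order[:top_k]]

    # -- reporting ----------------------------------------------------

    def summary(self, top_k: int = 10) -> str:
        lines = [
            "Structure-activity model",
            "=" * 48,
            f"model family   : {self.model.model_type}",
            f"features       : {len(self.feature_names)}",
            f"training rows  : "
            f"{len(self.model.dataset) if self.model.dataset is not None else 'n/a (loaded)'}",
            f"states seen    : {', '.join(self.classes)}",
            f"seed           : {self.model.seed}",
        ]
        if self._cv is not None:
            lines += ["", self._cv.summary()]
        lines += ["", f"top {top_k} features (regressor importance):"]
        for name, imp in self.feature_importance(top_k):
            lines.append(f"  {name:<16s} {imp:8.4f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------

    def save(self, path) -> None:
        """Serialise the full results object (joblib archive)."""
        payload = {
            "model_type": self.model.model_type,
            "seed": self.model.seed,
            "hyperparams": self.model.hyperparams,
            "classifier": self.classifier,
            "regressor": self.regressor,
            "classes": self.classes,
            "feature_names": self.feature_names,
            "schema_fingerprint": self.schema_fingerprint,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "ActivityResults":
        payload = joblib.load(path)
        # rebuild a spec-only model (no training data needed for prediction)
        dummy = StructureActivityModel.__new__(StructureActivityModel)
        dummy.model_type = payload["model_type"]
        dummy.seed = payload["seed"]
        dummy.hyperparams = payload["hyperparams"]
        dummy.dataset = None
        return cls(
            model=dummy,
            classifier=payload["classifier"],
            regressor=payload["regressor"],
            classes=payload["classes"],
            feature_names=tuple(payload["feature_names"]),
            schema_fingerprint=payload["schema_fingerprint"],
        )

    def roundtrips(self, X: np.ndarray) -> bool:
        """True if save->load reproduces predictions bit-identically on X."""
        buf = io.BytesIO()
        joblib.dump(self, buf)
        buf.seek(0)
        other = joblib.load(buf)
        return bool(
            np.array_equal(self.predict_activity(X), other.predict_activity(X))
            and np.array_equal(self.predict_state(X), other.predict_state(X))
        )
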