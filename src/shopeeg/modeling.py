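"""Classifier benchmark: five model families, two cross-validation
designs, balanced accuracy and random-forest channel importance.

The central object is :class:`PurchaseDecoder`, a model built from a
feature table (one row per snippet, ``ch_*`` feature columns plus
``label``/``subject_id``/``episode_id`` bookkeeping). ``fit()`` returns
a :class:`DecoderResults`; ``cross_validate()`` returns a
:class:`CVResults` carrying per-fold balanced accuracies, confusion
matrices and convergence flags. Module-level functions
(:func:`fit_predict`, :func:`cross_validate`, :func:`balanced_accuracy`,
:func:`channel_importance`) are thin wrappers over the same machinery.

Cross-validation designs:

* ``kfold5`` — stratified 5-fold over snippets (each fold an 80/20
  split). Augmented variants of the same page view can straddle the
  split, so scores are optimistic when features leak episode or subject
  identity.
* ``loso`` — leave-one-subject-out: all snippets of one subject held
  out together; the unweighted mean over subjects is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "PurchaseDecoder",
    "DecoderResults",
    "CVResults",
    "ImportanceMap",
    "fit_predict",
    "balanced_accuracy",
    "cross_validate",
    "channel_importance",
]

MODEL_FAMILIES = ("lda", "logistic", "knn", "svm", "random_forest")


@dataclass(frozen=True)
class ModelSpec:
    """Pinned hyperparameters for one classifier family.

    Values the source toolbox leaves at its defaults are pinned here
    explicitly so behavior is reproducible across library versions.
    """

    family: str = "random_forest"
    knn_k: int = 5
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    svm_max_iter: int = -1
    logistic_max_iter: int = 200
    rf_n_trees: int = 100
    class_policy: str = "none"  # or "balanced-weights"
    seed: int = 0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {MODEL_FAMILIES}")
        if self.knn_k < 1 or self.rf_n_trees < 1:
            raise ValueError("knn_k and rf_n_trees must be >= 1")
        if self.class_policy not in ("none", "balanced-weights"):
            raise ValueError("class_policy must be 'none' or 'balanced-weights'")

    def build(self):
        """Instantiate the scikit-learn estimator."""
        weight = "balanced" if self.class_policy == "balanced-weights" else None
        if self.family == "lda":
            return LinearDiscriminantAnalysis()
        if self.family == "logistic":
            return LogisticRegression(max_iter=self.logistic_max_iter, class_weight=weight)
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k)
        if self.family == "svm":
            return SVC(
                kernel=self.svm_kernel, C=self.svm_c, gamma="scale",
                max_iter=self.svm_max_iter, class_weight=weight,
                random_state=self.seed,
            )
        return RandomForestClassifier(
            n_estimators=self.rf_n_trees, class_weight=weight, random_state=self.seed,
        )


def split_features(table: pd.DataFrame):
    """(X, y, feature column names) from a feature table."""
    ch_cols = [c for c in table.columns if c.startswith("ch_")]
    if not ch_cols:
        raise ValueError("feature table has no ch_* columns")
    return table[ch_cols].to_numpy(dtype=float), table["label"].to_numpy(), ch_cols


def _fit_flagged(estimator, X, y):
    """Fit, capturing convergence failures instead of discarding them."""
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        estimator.fit(X, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
    return estimator, converged


def fit_predict(spec: ModelSpec, train: pd.DataFrame, test: pd.DataFrame):
    """Train on one table, predict another; returns (predictions, converged)."""
    X_tr, y_tr, cols = split_features(train)
    X_te, _, cols_te = split_features(test)
    if cols != cols_te:
        raise ValueError("train and test feature columns differ")
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set has a single class")
    est, converged = _fit_flagged(spec.build(), X_tr, y_tr)
    return est.predict(X_te), converged


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recall (macro recall)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if len(y_true) == 0:
        raise ValueError("empty label arrays")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return float(balanced_accuracy_score(y_true, y_pred))


@dataclass
class FoldResult:
    name: str
    score: float
    confusion: np.ndarray
    converged: bool
    n_test: int


@dataclass
class CVResults:
    """Per-fold balanced accuracies under one cross-validation design."""

    scheme: str
    spec: ModelSpec
    folds: list[FoldResult]
    classes: tuple[str, ...]

    @property
    def fold_scores(self) -> np.ndarray:
        return np.array([f.score for f in self.folds])

    @property
    def mean(self) -> float:
        return float(self.fold_scores.mean())

    @property
    def sd(self) -> float:
        return float(self.fold_scores.std(ddof=0))

    @property
    def convergence_flags(self) -> list[bool]:
        return [f.converged for f in self.folds]

    @property
    def confusion(self) -> np.ndarray:
        """Pooled confusion matrix over folds (rows = true classes)."""
        return np.sum([f.confusion for f in self.folds], axis=0)

    @property
    def pooled(self) -> float:
        """Balanced accuracy of the pooled out-of-fold predictions.

        The unweighted subject mean is biased upward whenever a held-out
        subject's few test views miss some classes (a subject with only
        no-buy views scores 1.0 against a majority-class predictor), so
        the pooled macro recall — every snippet predicted exactly once,
        always out-of-fold — is the calibrated headline statistic.
        """
        cm = self.confusion
        row_sums = cm.sum(axis=1)
        present = row_sums > 0
        recalls = np.diag(cm)[present] / row_sums[present]
        return float(recalls.mean())

    def summary(self) -> str:
        lines = [
            f"Cross-validation: {self.scheme}   model: {self.spec.family}",
            f"balanced accuracy: pooled={self.pooled:.3f}  fold mean={self.mean:.3f}  "
            f"sd={self.sd:.3f}  folds={len(self.folds)}  converged={all(self.convergence_flags)}",
            "per fold:",
        ]
        for f in self.folds:
            lines.append(
                f"  {f.name:>10s}  {f.score:.3f}  (n={f.n_test}"
                + ("" if f.converged else ", NOT CONVERGED") + ")"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "family": self.spec.family,
            "seed": self.spec.seed,
            "mean": self.mean,
            "sd": self.sd,
            "pooled": self.pooled,
            "classes": list(self.classes),
            "folds": [
                {"name": f.name, "score": f.score, "n_test": f.n_test,
                 "converged": f.converged}
                for f in self.folds
            ],
        }


@dataclass
class DecoderResults:
    """A fitted classifier plus training diagnostics."""

    spec: ModelSpec
    estimator: object
    converged: bool
    classes: tuple[str, ...]
    feature_names: list[str]
    train_score: float

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict(X)

    def score(self, table: pd.DataFrame) -> float:
        return balanced_accuracy(table["label"].to_numpy(), self.predict(table))

    def channel_importance(self, method: str = "impurity",
                           table: pd.DataFrame | None = None,
                           n_repeats: int = 10) -> "ImportanceMap":
        return channel_importance(self, method=method, table=table, n_repeats=n_repeats)

    def summary(self) -> str:
        return (
            f"PurchaseDecoder results — family={self.spec.family}\n"
            f"classes: {', '.join(self.classes)}\n"
            f"features: {len(self.feature_names)} channels\n"
            f"train balanced accuracy: {self.train_score:.3f}\n"
            f"converged: {self.converged}"
        )


class PurchaseDecoder:
    """Decode buy/cart/no-buy labels from per-channel feature vectors.

    Parameters
    ----------
    table:
        Feature table with ``ch_*`` columns plus ``label`` and (for
        LOSO) ``subject_id``.
    spec:
        Hyperparameter bundle; defaults to a 100-tree random forest.
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec = ModelSpec()):
        if "label" not in table.columns:
            raise ValueError("feature table needs a 'label' column")
        self.table = table.reset_index(drop=True)
        self.spec = spec
        self.X, self.y, self.feature_names = split_features(self.table)
        self.classes = tuple(sorted(np.unique(self.y)))
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, spec: ModelSpec = ModelSpec()):
        return cls(table, spec)

    def fit(self) -> DecoderResults:
        est, converged = _fit_flagged(self.spec.build(), self.X, self.y)
        train_score = balanced_accuracy(self.y, est.predict(self.X))
        return DecoderResults(
            spec=self.spec, estimator=est, converged=converged,
            classes=self.classes, feature_names=self.feature_names,
            train_score=train_score,
        )

    # -- cross-validation ------------------------------------------------

    def _folds(self, scheme: str):
        if scheme == "kfold5":
            skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=self.spec.seed)
            for i, (tr, te) in enumerate(skf.split(self.X, self.y)):
                yield f"fold{i + 1}", tr, te
        elif scheme == "loso":
            if "subject_id" not in self.table.columns:
                raise ValueError("LOSO needs a 'subject_id' column")
            subjects = self.table["subject_id"].to_numpy()
            unique = pd.unique(subjects)
            if len(unique) < 2:
                raise ValueError("LOSO needs at least 2 subjects")
            for subject in unique:
                te = np.flatnonzero(subjects == subject)
                tr = np.flatnonzero(subjects != subject)
                yield str(subject), tr, te
        else:
            raise ValueError(f"unknown CV scheme {scheme!r}")

    def cross_validate(self, scheme: str = "kfold5") -> CVResults:
        folds = []
        for name, tr, te in self._folds(scheme):
            if len(np.unique(self.y[tr])) < 2:
                raise ValueError(f"fold {name}: single-class training set")
            est, converged = _fit_flagged(clone(self.spec.build()), self.X[tr], self.y[tr])
            pred = est.predict(self.X[te])
            score = balanced_accuracy(self.y[te], pred)
            cm = confusion_matrix(self.y[te], pred, labels=list(self.classes))
            folds.append(FoldResult(name, score, cm, converged, len(te)))
        return CVResults(scheme=scheme, spec=self.spec, folds=folds, classes=self.classes)


def cross_validate(spec: ModelSpec, table: pd.DataFrame, scheme: str = "kfold5") -> CVResults:
    """Functional form of :meth:`PurchaseDecoder.cross_validate`."""
    return PurchaseDecoder(table, spec).cross_validate(scheme)


@dataclass
class ImportanceMap:
    """Per-channel importance scores with spread across trees/repeats."""

    method: str  # "impurity" or "permutation"
    channels: list[str]
    scores: np.ndarray
    sd: np.ndarray

    def ranking(self) -> list[str]:
        order = np.argsort(self.scores)[::-1]
        return [self.channels[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"channel": self.channels, "score": self.scores, "sd": self.sd}
        ).sort_values("score", ascending=False, ignore_index=True)


def channel_importance(
    results: DecoderResults,
    method: str = "impurity",
    table: pd.DataFrame | None = None,
    n_repeats: int = 10,
) -> ImportanceMap:
    """Channel importance of a fitted random forest.

    ``impurity``: mean decrease in impurity, mean and sd across trees
    (normalized scores sum to 1). ``permutation``: balanced-accuracy
    drop under per-channel shuffling on a held-out table, mean and sd
    over ``n_repeats`` repeats. Both are offered because they answer
    slightly different questions; impurity is the default.
    """
    est = results.estimator
    if not isinstance(est, RandomForestClassifier):
        raise ValueError("channel importance requires a fitted random forest")
    names = [c.removeprefix("ch_") for c in results.feature_names]
    if method == "impurity":
        per_tree = np.array([t.feature_importances_ for t in est.estimators_])
        return ImportanceMap("impurity", names, est.feature_importances_, per_tree.std(axis=0))
    if method == "permutation":
        if table is None:
            raise ValueError("permutation importance needs a held-out table")
        from sklearn.inspection import permutation_importance

        X = table[results.feature_names].to_numpy(dtype=float)
        y = table["label"].to_numpy()
        res = permutation_importance(
            est, X, y, scoring="balanced_accuracy",
            n_repeats=n_repeats, random_state=results.spec.seed,
        )
        return ImportanceMap("permutation", names, res.importances_mean, res.importances_std)
    raise ValueError(f"unknown importance method {method!r}")


def default_model_grid(seed: int = 0) -> list[ModelSpec]:
    """The five benchmark families with pinned hyperparameters."""
    return [replace(ModelSpec(family=f), seed=seed) for f in MODEL_FAMILIES]
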