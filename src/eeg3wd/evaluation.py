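"""Cross-validated evaluation with abstention-aware confusion metrics.

A three-way classifier splits the SI evaluated instances into CCI
(correctly classified), ECI (erroneously classified), and BI (abstained
/ boundary); the three report metrics are the ratios

    Acc = CCI/SI,  Err = ECI/SI,  Bnd = BI/SI,

which always sum to 1. Binary classifiers never abstain, so for them
BI = 0 and Acc + Err = 1.

Any object exposing ``train(X, y)`` and ``predict(x) -> 0 | 1 |
"boundary"`` plugs into :func:`evaluate_cv`; the module ships the O_CCA
classifier, dummy classifiers for bookkeeping checks, and thin
comparison-only adapters over scikit-learn baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import StratifiedKFold

from eeg3wd.entropy import BOUNDARY
from eeg3wd import occa

_VALID_PREDICTIONS = (0, 1, BOUNDARY)


@dataclass
class EvalReport:
    """Confusion counts of a three-way evaluation and their ratios."""

    SI: int
    CCI: int
    ECI: int
    BI: int

    def __post_init__(self) -> None:
        for name in ("SI", "CCI", "ECI", "BI"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.SI == 0:
            raise ValueError("SI must be positive")
        if self.CCI + self.ECI + self.BI != self.SI:
            raise ValueError(
                f"inconsistent counts: CCI+ECI+BI = "
                f"{self.CCI + self.ECI + self.BI} != SI = {self.SI}"
            )

    @property
    def acc(self) -> float:
        return self.CCI / self.SI

    @property
    def err(self) -> float:
        return self.ECI / self.SI

    @property
    def bnd(self) -> float:
        return self.BI / self.SI

    def as_percent(self) -> dict[str, float]:
        """Ratios as percentages rounded half-up to 2 decimals."""
        def pct(x: float) -> float:
            return float(
                Decimal(repr(x * 100)).quantize(
                    Decimal("0.01"), rounding=ROUND_HALF_UP
                )
            )
        return {"acc": pct(self.acc), "err": pct(self.err), "bnd": pct(self.bnd)}

    def to_dict(self) -> dict:
        return {
            "SI": self.SI,
            "CCI": self.CCI,
            "ECI": self.ECI,
            "BI": self.BI,
            "acc": self.acc,
            "err": self.err,
            "bnd": self.bnd,
            "percent": self.as_percent(),
        }


def metrics_from_counts(SI: int, CCI: int, ECI: int, BI: int) -> EvalReport:
    """Build an :class:`EvalReport` from confusion counts, validating them."""
    return EvalReport(SI=SI, CCI=CCI, ECI=ECI, BI=BI)


def kfold_split(n: int, k: int, labels, seed: int) -> list[np.ndarray]:
    """Stratified k-fold partition of indices 0..n-1.

    Folds are pairwise disjoint, cover all indices, keep per-fold class
    counts within 1 of proportionality, and are deterministic given the
    seed.
    """
    labels = np.asarray(labels)
    if labels.size != n:
        raise ValueError("labels length must equal n")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros((n, 1)), labels)]


class OCCAClassifier:
    """Classifier-contract wrapper around the O_CCA cover model."""

    def __init__(self, radius_mode: str = "midpoint") -> None:
        self.radius_mode = radius_mode
        self.model: occa.CoverModel | None = None

    def train(self, X, y) -> "OCCAClassifier":
        self.model = occa.train(X, y, radius_mode=self.radius_mode)
        return self

    def predict(self, x):
        if self.model is None:
            raise RuntimeError("classifier is not trained")
        return occa.decide(self.model, x).predicted_label


class DummyClassifier:
    """Diagnostic classifier for metric bookkeeping.

    behavior="abstain" always returns the boundary token;
    behavior="constant" always predicts ``constant_label``.
    """

    def __init__(self, behavior: str = "abstain", constant_label: int = 0) -> None:
        if behavior not in ("abstain", "constant"):
            raise ValueError("behavior must be 'abstain' or 'constant'")
        self.behavior = behavior
        self.constant_label = constant_label

    def train(self, X, y) -> "DummyClassifier":
        return self

    def predict(self, x):
        if self.behavior == "abstain":
            return BOUNDARY
        return self.constant_label


class LabelFlipClassifier:
    """Nearest-neighbor memorizer that reports the wrong class on purpose.

    Used to verify that Err bookkeeping counts misclassifications: on
    training data it predicts the complement of the true label of the
    nearest memorized sample.
    """

    def __init__(self) -> None:
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def train(self, X, y) -> "LabelFlipClassifier":
        self._X = np.atleast_2d(np.asarray(X, dtype=float))
        self._y = np.asarray(y).astype(int)
        return self

    def predict(self, x):
        d = np.linalg.norm(self._X - np.asarray(x, dtype=float), axis=1)
        return 1 - int(self._y[int(np.argmin(d))])


class SklearnAdapter:
    """Comparison-only adapter fitting a scikit-learn binary estimator.

    The baselines (SVM, k-NN, naive Bayes, random forest) are not part
    of the three-way model; they exist to reproduce the structure of a
    binary-classifier comparison (BI always 0). Estimator internals are
    entirely scikit-learn's.
    """

    #: Factory names accepted by :meth:`by_name`.
    KNOWN = ("svm", "knn", "nb", "rf")

    def __init__(self, estimator) -> None:
        self.estimator = estimator

    @classmethod
    def by_name(cls, name: str, seed: int = 0) -> "SklearnAdapter":
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.naive_bayes import GaussianNB
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.svm import SVC

        factories = {
            "svm": lambda: SVC(kernel="rbf"),
            "knn": lambda: KNeighborsClassifier(n_neighbors=3),
            "nb": lambda: GaussianNB(),
            "rf": lambda: RandomForestClassifier(
                n_estimators=100, random_state=seed
            ),
        }
        if name not in factories:
            raise ValueError(f"unknown baseline {name!r}; choose from {cls.KNOWN}")
        return cls(factories[name]())

    def train(self, X, y) -> "SklearnAdapter":
        self.estimator.fit(np.atleast_2d(X), np.asarray(y).astype(int))
        return self

    def predict(self, x):
        return int(self.estimator.predict(np.atleast_2d(x))[0])


def evaluate_cv(features, labels, classifier, k: int = 10,
                seed: int = 0) -> EvalReport:
    """k-fold cross-validated three-way evaluation.

    Per fold the classifier is retrained on the other k-1 folds and
    decides each held-out row; predictions are pooled over folds into
    the CCI/ECI/BI counts.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).astype(int)
    folds = kfold_split(X.shape[0], k, y, seed)
    cci = eci = bi = 0
    for test_idx in folds:
        mask = np.ones(X.shape[0], dtype=bool)
        mask[test_idx] = False
        classifier.train(X[mask], y[mask])
        for i in test_idx:
            pred = classifier.predict(X[i])
            if pred not in _VALID_PREDICTIONS:
                raise ValueError(
                    f"classifier emitted invalid prediction {pred!r}; "
                    f"allowed: {_VALID_PREDICTIONS}"
                )
            if pred == BOUNDARY:
                bi += 1
            elif pred == y[i]:
                cci += 1
            else:
                eci += 1
    return metrics_from_counts(SI=X.shape[0], CCI=cci, ECI=eci, BI=bi)
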