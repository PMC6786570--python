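"""The four base binary classifiers and their probability outputs.

Each subset is learned by four families — a degree-3 polynomial-kernel
support vector machine, a random forest, logistic regression and linear
discriminant analysis — and each fitted model reports, for a questionnaire,
a coded diagnosis (0 = class 1, the rare-disease side; 1 = class 2) together
with the probability of that diagnosis.

Hyperparameters are pinned explicitly in :class:`TrainingConfig` rather
than left to library defaults so runs are reproducible across library
versions.  The SVM's probabilities come from Platt-style sigmoid
calibration fitted within the training split (margin methods have no native
probability).  Feature standardization is applied before the SVM, logistic
and LDA fits by default — raw age (0-120 years) would otherwise dominate
kernel distances against the 1-4 answer scale — and the fitted scaler is
stored in the bundle so train and predict transforms are identical.  The
random forest sees raw features; trees are scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_model import FEATURE_LENGTH

#: Fixed family order; fusion features depend on it.
FAMILIES = ("SVM_POLY3", "RANDOM_FOREST", "LOGISTIC_REGRESSION", "LDA")

#: Families whose fit consumes standardized features.
SCALED_FAMILIES = frozenset({"SVM_POLY3", "LOGISTIC_REGRESSION", "LDA"})


class TrainingError(ValueError):
    """Dataset unsuitable for training (e.g. a single class present)."""


class ContractError(ValueError):
    """An input violates a structural contract (shape, family order, ids)."""


@dataclass(frozen=True)
class TrainingConfig:
    """Pinned hyperparameters for the four families.

    svm_c / svm_degree / svm_coef0: polynomial-kernel SVM (degree 3 with an
    inhomogeneous term so lower-order interactions are represented).
    n_trees: forest size; 100 trees, the library-convention default, is
    ample for these small tabular problems.
    calibration_folds: internal folds for the SVM's Platt sigmoid
    calibration, fitted within the training split.
    logreg_c: inverse L2 regularization strength.
    lda_shrinkage: ridge mixing weight on the pooled covariance; "auto"
    selects it by Ledoit-Wolf, the right regime when the feature count
    (55) is comparable to the per-class sample size, and also guards
    against singular covariance when an item is constant within a class.
    standardize: z-score features for the scale-sensitive families.
    """

    svm_c: float = 1.0
    svm_degree: int = 3
    svm_coef0: float = 1.0
    n_trees: int = 100
    calibration_folds: int = 5
    logreg_c: float = 1.0
    logreg_max_iter: int = 2000
    lda_shrinkage: float | str = "auto"
    standardize: bool = True


@dataclass(frozen=True)
class BaseClassifierResult:
    """One family's verdict: coded diagnosis and its probability."""

    family: str
    predicted_index: int  # 0 = class1 (RD side), 1 = class2
    probability: float  # probability of the predicted class, in [0, 1]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ContractError(f"unknown family {self.family!r}")
        if self.predicted_index not in (0, 1):
            raise ContractError("predicted_index must be 0 or 1")
        if not (0.0 <= self.probability <= 1.0):
            raise ContractError(f"probability {self.probability} outside [0, 1]")


@dataclass
class BaseModelBundle:
    """The four fitted models for one subset plus preprocessing state."""

    subset_id: int
    models: dict
    scaler: StandardScaler | None
    config: TrainingConfig
    seed: int
    n_features: int = FEATURE_LENGTH

    def __post_init__(self) -> None:
        if set(self.models) != set(FAMILIES):
            raise ContractError(f"bundle must contain exactly the families {FAMILIES}")


def make_poly_svm(config: TrainingConfig, seed: int) -> CalibratedClassifierCV:
    """Degree-3 polynomial-kernel SVM with Platt sigmoid calibration.

    Calibration folds are internal to whatever data the estimator is fitted
    on, so calibration never sees held-out rows.
    """
    svc = SVC(
        kernel="poly",
        degree=config.svm_degree,
        coef0=config.svm_coef0,
        C=config.svm_c,
        gamma="scale",
        random_state=seed,
    )
    return CalibratedClassifierCV(
        svc, method="sigmoid", cv=config.calibration_folds, ensemble=False
    )


def _build_estimators(config: TrainingConfig, seed: int) -> dict:
    return {
        "SVM_POLY3": make_poly_svm(config, seed),
        "RANDOM_FOREST": RandomForestClassifier(
            n_estimators=config.n_trees, random_state=seed
        ),
        "LOGISTIC_REGRESSION": LogisticRegression(
            C=config.logreg_c, max_iter=config.logreg_max_iter
        ),
        "LDA": LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=config.lda_shrinkage
        ),
    }


def train_base(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | None = None,
    seed: int = 0,
    subset_id: int = 0,
) -> BaseModelBundle:
    """Fit the four base models on a labeled design matrix.

    ``y`` uses the 0/1 diagnosis-index coding (0 = rare-disease side).
    Stochastic fits (forest, SVM calibration folds) consume ``seed``.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise TrainingError("X must be 2-D with one label per row")
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")
    scaler = None
    Xs = X
    if config.standardize:
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
    models = {}
    for family, est in _build_estimators(config, seed).items():
        models[family] = est.fit(Xs if family in SCALED_FAMILIES else X, y)
    return BaseModelBundle(
        subset_id=subset_id,
        models=models,
        scaler=scaler,
        config=config,
        seed=seed,
        n_features=X.shape[1],
    )


def _proba_matrix(bundle: BaseModelBundle, X: np.ndarray) -> dict:
    """Per family, the (n, 2) matrix of [P(class1), P(class2)]."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != bundle.n_features:
        raise ContractError(
            f"feature vectors must have length {bundle.n_features}, got {X.shape[1]}"
        )
    Xs = bundle.scaler.transform(X) if bundle.scaler is not None else X
    out = {}
    for family in FAMILIES:
        model = bundle.models[family]
        proba = model.predict_proba(Xs if family in SCALED_FAMILIES else X)
        # column order follows model.classes_; normalize to [P(0), P(1)]
        cols = {int(c): j for j, c in enumerate(model.classes_)}
        out[family] = proba[:, [cols[0], cols[1]]]
    return out


def predict_base(bundle: BaseModelBundle, vector: np.ndarray) -> list[BaseClassifierResult]:
    """The four (diagnosis index, probability) verdicts for one questionnaire.

    Results come in the fixed family order; each probability is the model's
    calibrated probability of its own predicted class, hence >= 0.5.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1:
        raise ContractError("predict_base takes a single feature vector")
    probas = _proba_matrix(bundle, vector[None, :])
    results = []
    for family in FAMILIES:
        p0, p1 = probas[family][0]
        idx = 0 if p0 >= p1 else 1
        results.append(
            BaseClassifierResult(
                family=family,
                predicted_index=idx,
                probability=float(max(p0, p1)),
            )
        )
    return results


def save_bundle(bundle: BaseModelBundle, path) -> None:
    joblib.dump({"format_version": 1, "bundle": bundle}, path)


def load_bundle(path) -> BaseModelBundle:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ContractError("unrecognized bundle format version")
    return payload["bundle"]
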