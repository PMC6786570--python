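"""Classifier fusion: the 8-element meta-feature and the fusion SVM.

The four base families sometimes split 2-2 on a questionnaire ("diagnostic
parity").  A meta-classifier resolves this: its input is the concatenation,
in fixed family order, of each family's coded diagnosis and probability —
4 x 2 = 8 elements — and its output is the final diagnosis index with a
calibrated probability.  The meta-learner is itself a degree-3
polynomial-kernel SVM.

Training is leakage-safe stacking: the subset is split into ``k_inner``
stratified folds, base bundles fitted on k-1 folds predict the held-out
fold, and only those out-of-fold predictions form the fusion training
features.  The base bundle shipped alongside the fusion model is then refit
on the full subset.  Fold provenance (which indices trained which bundle)
is recorded so the no-leakage property can be asserted after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .base_classifiers import (
    FAMILIES,
    BaseClassifierResult,
    BaseModelBundle,
    ContractError,
    TrainingConfig,
    _proba_matrix,
    make_poly_svm,
    train_base,
)

FUSION_LENGTH = 8


class ConfigError(ValueError):
    """Invalid fusion training configuration."""


def make_fusion_feature(results: Sequence[BaseClassifierResult]) -> np.ndarray:
    """Concatenate four (index, probability) pairs into the 8-element feature.

    Exactly one result per family, in the fixed family order; no
    renormalization is applied.
    """
    if len(results) != len(FAMILIES):
        raise ContractError(f"expected {len(FAMILIES)} base results, got {len(results)}")
    for res, family in zip(results, FAMILIES):
        if res.family != family:
            raise ContractError(
                f"base results out of order: expected {family}, got {res.family}"
            )
    out = np.empty(FUSION_LENGTH, dtype=float)
    for j, res in enumerate(results):
        out[2 * j] = float(res.predicted_index)
        out[2 * j + 1] = res.probability
    return out


def _fusion_rows(bundle: BaseModelBundle, X: np.ndarray) -> np.ndarray:
    """Vectorized fusion features for every row of X under one bundle."""
    probas = _proba_matrix(bundle, X)
    n = np.atleast_2d(X).shape[0]
    rows = np.empty((n, FUSION_LENGTH), dtype=float)
    for j, family in enumerate(FAMILIES):
        p = probas[family]
        idx = (p[:, 1] > p[:, 0]).astype(float)
        rows[:, 2 * j] = idx
        rows[:, 2 * j + 1] = np.max(p, axis=1)
    return rows


@dataclass
class FusionModel:
    """The fitted meta-SVM for one subset, with its feature scaler."""

    subset_id: int
    model: object  # calibrated degree-3 polynomial-kernel SVM
    scaler: StandardScaler | None
    seed: int

    def predict_p_class1(self, fusion_features: np.ndarray) -> np.ndarray:
        F = np.atleast_2d(np.asarray(fusion_features, dtype=float))
        if F.shape[1] != FUSION_LENGTH:
            raise ContractError(f"fusion features must have length {FUSION_LENGTH}")
        Fs = self.scaler.transform(F) if self.scaler is not None else F
        proba = self.model.predict_proba(Fs)
        cols = {int(c): j for j, c in enumerate(self.model.classes_)}
        return proba[:, cols[0]]


@dataclass
class StackingProvenance:
    """Bookkeeping of the inner stacking split, for leakage audits.

    ``folds`` maps each inner fold to (train_indices, heldout_indices)
    into the canonically ordered rows: the bundle fitted on
    ``train_indices`` produced the fusion training rows for
    ``heldout_indices``.  ``order`` maps canonical positions back to the
    caller's row order.
    """

    subset_id: int
    k_inner: int
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    order: np.ndarray | None = None

    def assert_no_leakage(self, n: int) -> None:
        covered = np.zeros(n, dtype=int)
        for train_idx, held_idx in self.folds:
            if np.intersect1d(train_idx, held_idx).size:
                raise AssertionError("stacking leakage: fold trains on its own held-out rows")
            covered[held_idx] += 1
        if not np.all(covered == 1):
            raise AssertionError("stacking incomplete: each row must be predicted exactly once")


def train_fusion(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | None = None,
    k_inner: int = 5,
    seed: int = 0,
    subset_id: int = 0,
) -> tuple[BaseModelBundle, FusionModel, StackingProvenance]:
    """Train base bundle + fusion meta-SVM with out-of-fold stacking.

    Returns the final base bundle (refit on all rows), the fusion model
    (fit on out-of-fold base predictions only), and the stacking
    provenance.
    """
    if k_inner < 2:
        raise ConfigError("k_inner must be >= 2")
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    # Canonical row order (lexicographic on features, then label) makes the
    # fold split — and hence the fitted models — invariant to the order in
    # which the caller supplies the training records.
    order = np.lexsort((y,) + tuple(X.T[::-1]))
    X, y = X[order], y[order]
    n = len(y)
    meta_X = np.empty((n, FUSION_LENGTH), dtype=float)
    provenance = StackingProvenance(
        subset_id=subset_id, k_inner=k_inner, seed=seed, order=order
    )
    skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    for train_idx, held_idx in skf.split(X, y):
        fold_bundle = train_base(
            X[train_idx], y[train_idx], config=config, seed=seed, subset_id=subset_id
        )
        meta_X[held_idx] = _fusion_rows(fold_bundle, X[held_idx])
        provenance.folds.append((train_idx, held_idx))

    # The 8 meta-features are already on a common bounded scale (indices in
    # {0,1}, probabilities in [0,1]); z-scoring near-constant probability
    # columns would amplify noise directions, so no scaler is fitted here.
    meta_svm = make_poly_svm(config, seed).fit(meta_X, y)
    fusion_model = FusionModel(subset_id=subset_id, model=meta_svm, scaler=None, seed=seed)

    final_bundle = train_base(X, y, config=config, seed=seed, subset_id=subset_id)
    return final_bundle, fusion_model, provenance


def predict_fusion(
    bundle: BaseModelBundle,
    fusion_model: FusionModel,
    vector: np.ndarray,
) -> tuple[int, float]:
    """Final diagnosis for one questionnaire: (index, P(class 1)).

    The probability refers to the class-1 (rare-disease) side; the final
    index is 1 only when that probability falls below 0.5 — a tie goes to
    the rare-disease side, erring toward sensitivity because the tool is an
    alarm for considering a rare disease.
    """
    if bundle.subset_id != fusion_model.subset_id:
        raise ContractError(
            f"subset mismatch: bundle {bundle.subset_id} vs fusion {fusion_model.subset_id}"
        )
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1:
        raise ContractError("predict_fusion takes a single feature vector")
    rows = _fusion_rows(bundle, vector[None, :])
    p1 = float(fusion_model.predict_p_class1(rows)[0])
    return (0 if p1 >= 0.5 else 1), p1


def predict_fusion_batch(
    bundle: BaseModelBundle,
    fusion_model: FusionModel,
    X: np.ndarray,
) -> np.ndarray:
    """P(class 1) for every row of a design matrix."""
    if bundle.subset_id != fusion_model.subset_id:
        raise ContractError("subset mismatch between bundle and fusion model")
    return fusion_model.predict_p_class1(_fusion_rows(bundle, X))
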