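"""Cross-validated evaluation: confusion matrices, sensitivity/specificity,
ROC/AUC, cross-subset aggregation and per-patient probability triples.

Evaluation convention: the rare-disease side of each subset is the positive
class, so TP counts rare-disease questionnaires recognized as such and TN
counts the alternative group (NRO/CD/PSY) recognized as such.  Sensitivity
is TP/(TP+FN) and specificity TN/(TN+FP), reported as percentages truncated
(not rounded) to one decimal — the reporting convention the confusion-matrix
arithmetic implies (79/90 = 87.78 is reported as 87.7).  Raw double
precision is kept internally.

Cross-validation pools the per-fold counts into one confusion matrix per
classifier (per-fold sensitivities are stored too).  The headline
rare-disease sensitivity is the arithmetic mean of the three subsets'
fusion sensitivities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .base_classifiers import (
    FAMILIES,
    ContractError,
    TrainingConfig,
)
from .data_model import RespondentRecord, encode
from .fusion import predict_fusion_batch, train_fusion
from .subset_design import SubsetDataset

CLASSIFIERS = FAMILIES + ("FUSION",)


class MetricError(ValueError):
    """A metric is undefined for the given counts (empty denominator)."""


class StratificationError(ValueError):
    """Fold request incompatible with the class counts."""


def truncate_percent(x: float, decimals: int = 1) -> float:
    """Truncate toward zero to the given number of decimals (87.78 -> 87.7)."""
    scale = 10**decimals
    return math.floor(x * scale + 1e-9) / scale


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts with the rare-disease side as positive."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.TP + other.TP, self.FN + other.FN, self.FP + other.FP, self.TN + other.TN
        )


def sensitivity(cm: ConfusionMatrix) -> float:
    """100 * TP / (TP + FN), truncated to one decimal."""
    if cm.TP + cm.FN == 0:
        raise MetricError("sensitivity undefined: no positive samples (TP+FN = 0)")
    return truncate_percent(100.0 * cm.TP / (cm.TP + cm.FN))


def specificity(cm: ConfusionMatrix) -> float:
    """100 * TN / (TN + FP), truncated to one decimal."""
    if cm.TN + cm.FP == 0:
        raise MetricError("specificity undefined: no negative samples (TN+FP = 0)")
    return truncate_percent(100.0 * cm.TN / (cm.TN + cm.FP))


def aggregate_sensitivity(values: Sequence[float]) -> float:
    """Headline rare-disease sensitivity: arithmetic mean of the three
    subset sensitivities, to one decimal."""
    if len(values) != 3:
        raise ContractError(f"expected exactly 3 subset sensitivities, got {len(values)}")
    return truncate_percent(float(np.mean(values)))


# ---------------------------------------------------------------------------
# folds and ROC

def stratified_folds(labels: Sequence[int], k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (list of held-out index arrays).

    Per-class counts differ by at most one across folds; every class must
    have at least ``k`` members.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise StratificationError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = [str(c) for c, n in zip(classes, counts) if n < k]
    if small:
        raise StratificationError(f"class(es) {small} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [held for _, held in skf.split(np.zeros(len(labels)), labels)]


def roc_auc(scores: Sequence[tuple[int, float]]) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC from (true label, P(class 1)) pairs.

    Labels use the 0/1 diagnosis-index coding with 0 the positive
    (rare-disease) side.  The AUC equals the Mann-Whitney concordance
    probability with ties counted half; the curve is the threshold sweep
    over unique scores.
    """
    y = np.array([lab for lab, _ in scores], dtype=int)
    p = np.array([s for _, s in scores], dtype=float)
    if len(np.unique(y)) < 2:
        raise MetricError("ROC/AUC undefined: only one class present")
    y_pos = (y == 0).astype(int)  # positive = class 1 (RD side)
    fpr, tpr, _ = roc_curve(y_pos, p)
    auc = float(roc_auc_score(y_pos, p))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class EvaluationReport:
    """Pooled cross-validation results for one subset.

    Per classifier (four base families + fusion): a pooled confusion
    matrix with sensitivity/specificity percentages; for the fusion, also
    the per-record scores, ROC points and AUC.  Fold provenance and the
    seed make the run reproducible.
    """

    subset_id: int
    k: int
    seed: int
    confusions: dict[str, ConfusionMatrix]
    sensitivities: dict[str, float]
    specificities: dict[str, float]
    per_fold_sensitivity: dict[str, list[float]]
    fusion_scores: list[tuple[int, float]]
    roc_points: list[tuple[float, float]]
    auc: float
    fold_record_ids: list[list[str]]

    def to_json(self) -> str:
        payload = {
            "subset_id": self.subset_id,
            "k": self.k,
            "seed": self.seed,
            "confusions": {c: asdict(cm) for c, cm in self.confusions.items()},
            "sensitivities": self.sensitivities,
            "specificities": self.specificities,
            "per_fold_sensitivity": self.per_fold_sensitivity,
            "auc": self.auc,
            "roc_points": self.roc_points,
            "fold_record_ids": self.fold_record_ids,
        }
        return json.dumps(payload, indent=2)


def _counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    # positive class = index 0 (rare-disease side)
    return ConfusionMatrix(
        TP=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 0) & (y_pred == 1))),
        FP=int(np.sum((y_true == 1) & (y_pred == 0))),
        TN=int(np.sum((y_true == 1) & (y_pred == 1))),
    )


def cross_validate(
    dataset: SubsetDataset,
    k: int = 10,
    k_inner: int = 5,
    seed: int = 0,
    config: TrainingConfig | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of base families and fusion.

    Per fold, the base bundle and the fusion model are trained on the k-1
    training folds (the fusion via inner out-of-fold stacking) and applied
    to the held-out fold; counts are pooled across folds into one
    confusion matrix per classifier.
    """
    from .base_classifiers import train_base, _proba_matrix  # local to avoid cycle at import

    config = config or TrainingConfig()
    X = np.vstack([encode(r) for r in dataset.records])
    y = np.asarray(dataset.labels, dtype=int)
    folds = stratified_folds(y, k=k, seed=seed)

    cms = {c: ConfusionMatrix(0, 0, 0, 0) for c in CLASSIFIERS}
    per_fold_sens: dict[str, list[float]] = {c: [] for c in CLASSIFIERS}
    fusion_scores: list[tuple[int, float]] = []
    fold_ids: list[list[str]] = []

    all_idx = np.arange(len(y))
    for fold_no, held in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, held)
        try:
            bundle, fus, _ = train_fusion(
                X[train_idx],
                y[train_idx],
                config=config,
                k_inner=k_inner,
                seed=seed + fold_no,
                subset_id=dataset.subset_id,
            )
        except Exception as err:
            raise RuntimeError(f"training failed in CV fold {fold_no}") from err

        y_true = y[held]
        # base families
        probas = _proba_matrix(bundle, X[held])
        for family in FAMILIES:
            pred = (probas[family][:, 1] > probas[family][:, 0]).astype(int)
            cm = _counts(y_true, pred)
            cms[family] = cms[family] + cm
            per_fold_sens[family].append(
                100.0 * cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN else float("nan")
            )
        # fusion
        p1 = predict_fusion_batch(bundle, fus, X[held])
        pred = (p1 < 0.5).astype(int)  # ties to the RD side
        cm = _counts(y_true, pred)
        cms["FUSION"] = cms["FUSION"] + cm
        per_fold_sens["FUSION"].append(
            100.0 * cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN else float("nan")
        )
        fusion_scores.extend(zip(y_true.tolist(), p1.tolist()))
        fold_ids.append([dataset.records[i].record_id for i in held])

    roc_points, auc = roc_auc(fusion_scores)
    return EvaluationReport(
        subset_id=dataset.subset_id,
        k=k,
        seed=seed,
        confusions=cms,
        sensitivities={c: sensitivity(cm) for c, cm in cms.items()},
        specificities={c: specificity(cm) for c, cm in cms.items()},
        per_fold_sensitivity=per_fold_sens,
        fusion_scores=fusion_scores,
        roc_points=roc_points,
        auc=auc,
        fold_record_ids=fold_ids,
    )


# ---------------------------------------------------------------------------
# per-patient report

@dataclass(frozen=True)
class ProbabilityTriple:
    """The three rare-disease probabilities and the diagnostic suggestion.

    ``p_rd1..p_rd3`` are the fusion probabilities of the rare-disease side
    under subsets 1-3; the complements are the probabilities of NRO, CD and
    PSY respectively.  Suggestion rule: if any rare-disease probability
    reaches 0.5 the suggestion is the rare-disease composite of the argmax
    subset at that probability; otherwise the alternative group with the
    largest complement.  Ties at 0.5 go to the rare-disease side (the tool
    is an alarm for considering a rare disease).
    """

    p_rd1: float
    p_rd2: float
    p_rd3: float
    suggestion: str
    pointer_subset: int | None
    headline_probability: float

    @property
    def probabilities(self) -> tuple[float, float, float]:
        return (self.p_rd1, self.p_rd2, self.p_rd3)


ALTERNATIVE_GROUPS = {1: "NRO", 2: "CD", 3: "PSY"}


def suggest_from_probabilities(p_rd: Sequence[float]) -> ProbabilityTriple:
    """Apply the documented suggestion rule to a triple of RD probabilities."""
    if len(p_rd) != 3:
        raise ContractError("expected exactly three subset probabilities")
    p_rd = [float(p) for p in p_rd]
    for p in p_rd:
        if not (0.0 <= p <= 1.0):
            raise ContractError(f"probability {p} outside [0, 1]")
    best = int(np.argmax(p_rd))
    if p_rd[best] >= 0.5:
        return ProbabilityTriple(
            *p_rd,
            suggestion=f"RD (subset {best + 1})",
            pointer_subset=best + 1,
            headline_probability=p_rd[best],
        )
    complements = [1.0 - p for p in p_rd]
    alt = int(np.argmax(complements))
    return ProbabilityTriple(
        *p_rd,
        suggestion=ALTERNATIVE_GROUPS[alt + 1],
        pointer_subset=None,
        headline_probability=complements[alt],
    )


def evaluate_questionnaire(record: RespondentRecord, models) -> ProbabilityTriple:
    """Score one completed questionnaire against all three subset models.

    ``models`` maps subset id (1, 2, 3) to a trained (bundle, fusion
    model) pair.
    """
    for sid in (1, 2, 3):
        if sid not in models:
            raise ContractError(f"missing trained models for subset {sid}")
    x = encode(record)
    p_rd = [float(predict_fusion_batch(models[sid][0], models[sid][1], x[None, :])[0]) for sid in (1, 2, 3)]
    return suggest_from_probabilities(p_rd)
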