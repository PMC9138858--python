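"""Negative sampling, gradient-boosted classification, cross-validated
metrics, and per-disease candidate ranking.

The classifier contract is realized over XGBoost: logistic-loss
gradient boosting with L2 leaf regularization λ and split penalty γ.
Cross-validation shuffles once per seed into k near-equal (by default
stratified) folds; within each fold the autoencoder and the classifier
are fit on the training part only — a provenance log records the fit
scope so the no-leakage guarantee is checkable.

Metrics per fold: accuracy, specificity, sensitivity, precision, MCC at
a fixed threshold, plus threshold-free ROC-AUC (trapezoidal) and AUPR
(precision–recall step integral).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from xgboost import XGBClassifier

from .autoencoder import AEConfig, AEModel, encode, train_autoencoder
from .core_data import AssociationList, AssociationMatrix
from .errors import (
    CapacityError,
    DataValidationError,
    DegenerateInputError,
    EntityLookupError,
)
from .fusion import FusedFeatureMatrix, PairDataset, pair_features

__all__ = [
    "GBTParams",
    "FoldMetrics",
    "RankingResult",
    "CVConfig",
    "sample_negatives",
    "train_classifier",
    "predict_scores",
    "compute_metrics",
    "cross_validate",
    "summarize_folds",
    "rank_candidates",
]


@dataclass(frozen=True)
class GBTParams:
    """Gradient-boosted-tree settings (exposed XGBoost surface)."""

    n_trees: int = 500
    max_depth: int = 6
    learning_rate: float = 0.1
    reg_lambda: float = 1.0
    gamma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.reg_lambda < 0 or self.gamma < 0:
            raise DataValidationError("invalid gradient-boosting parameters")


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    spec: float
    sen: float
    prec: float
    mcc: float
    auc: float
    aupr: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k)
                for k in ("acc", "spec", "sen", "prec", "mcc", "auc", "aupr")}


@dataclass(frozen=True)
class RankingResult:
    """Candidate miRNAs for one disease, scored and sorted descending
    (ties broken by name); known associations are excluded."""

    disease: str
    ranked: tuple[tuple[str, float], ...]
    excluded_known: frozenset[str]


def sample_negatives(A: AssociationMatrix, n: int, seed: int) -> AssociationList:
    """Draw n distinct unobserved (miRNA, disease) pairs uniformly.

    Sampling is without replacement over the zero cells of the
    association matrix and deterministic per seed.
    """
    zeros_d, zeros_m = np.nonzero(A.values == 0)
    if n > len(zeros_d):
        raise CapacityError(
            f"requested {n} negatives but only {len(zeros_d)} zero cells exist"
        )
    if n < 0:
        raise DataValidationError("negative sample count must be >= 0")
    rng = np.random.default_rng(seed)
    take = rng.choice(len(zeros_d), size=n, replace=False)
    pairs = tuple(
        (A.mirna_index[zeros_m[k]], A.disease_index[zeros_d[k]]) for k in take
    )
    return AssociationList(pairs=pairs)


def _make_xgb(params: GBTParams) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        reg_lambda=params.reg_lambda,
        gamma=params.gamma,
        random_state=params.seed,
        n_jobs=1,
        tree_method="hist",
        objective="binary:logistic",
        eval_metric="logloss",
    )


def train_classifier(ds: PairDataset, params: GBTParams | None = None) -> XGBClassifier:
    """Fit the gradient-boosted classifier on a pair dataset.

    Deterministic per seed at fixed thread count (n_jobs=1).  Raises if
    only one class is present.
    """
    params = params or GBTParams()
    if len(np.unique(ds.labels)) < 2:
        raise DegenerateInputError("training data contains a single class")
    model = _make_xgb(params)
    model.fit(ds.features, ds.labels)
    return model


def predict_scores(model: XGBClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def compute_metrics(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
    fold: int = 0,
) -> FoldMetrics:
    """Confusion metrics at a threshold plus ROC-AUC and AUPR.

    AUC is the trapezoidal area under the ROC curve; AUPR the step
    integral of the precision–recall curve.  An MCC denominator of zero
    yields 0 with a warning.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise DataValidationError("labels and scores must have the same length")
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("AUC undefined: only one class present")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def ratio(a, b):
        return a / b if b else 0.0

    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0.0:
        warnings.warn("MCC denominator is zero; reporting 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = float((tp * tn - fp * fn) / mcc_den)
    return FoldMetrics(
        fold=fold, tp=tp, tn=tn, fp=fp, fn=fn,
        acc=ratio(tp + tn, tp + tn + fp + fn),
        spec=ratio(tn, tn + fp),
        sen=ratio(tp, tp + fn),
        prec=ratio(tp, tp + fp),
        mcc=mcc,
        auc=float(roc_auc_score(y, s)),
        aupr=float(average_precision_score(y, s)),
    )


@dataclass(frozen=True)
class CVConfig:
    """Per-fold pipeline settings for cross-validation."""

    folds: int = 5
    stratified: bool = True
    threshold: float = 0.5
    use_autoencoder: bool = True
    ae: AEConfig = field(default_factory=AEConfig)
    gbt: GBTParams = field(default_factory=GBTParams)


def cross_validate(
    ds: PairDataset, config: CVConfig | None = None, seed: int = 0
) -> tuple[list[FoldMetrics], dict, list[dict]]:
    """k-fold cross-validation of the encode→classify pipeline.

    Samples are shuffled once per seed and split into k near-equal
    stratified folds.  Per fold the autoencoder (when enabled) and the
    classifier are fit on the k−1 training parts and scored on the
    held-out part.  Returns per-fold metrics, a mean±std summary, and a
    provenance log (one record per fold with the index sets each stage
    was fit on).
    """
    config = config or CVConfig()
    if config.folds < 2:
        raise DataValidationError("cross-validation needs k >= 2 folds")
    y = ds.labels
    splitter_cls = StratifiedKFold if config.stratified else KFold
    splitter = splitter_cls(n_splits=config.folds, shuffle=True, random_state=seed)
    fold_metrics: list[FoldMetrics] = []
    provenance: list[dict] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(ds.features, y)):
        X_train, X_test = ds.features[train_idx], ds.features[test_idx]
        record = {
            "fold": fold,
            "train_indices": train_idx.tolist(),
            "test_indices": test_idx.tolist(),
            "ae_fit_on": "train" if config.use_autoencoder else None,
            "classifier_fit_on": "train",
        }
        if config.use_autoencoder:
            ae_cfg = replace(config.ae, seed=config.ae.seed + fold)
            ae = train_autoencoder(X_train, ae_cfg)
            record["ae_initial_loss"] = ae.initial_loss
            record["ae_final_loss"] = ae.training_log[-1]
            X_train, X_test = encode(ae, X_train), encode(ae, X_test)
        gbt = replace(config.gbt, seed=config.gbt.seed + fold)
        model = _make_xgb(gbt)
        model.fit(X_train, y[train_idx])
        scores = model.predict_proba(X_test)[:, 1]
        record["test_scores"] = scores.tolist()
        record["test_labels"] = y[test_idx].tolist()
        fold_metrics.append(
            compute_metrics(y[test_idx], scores, config.threshold, fold=fold)
        )
        provenance.append(record)
    return fold_metrics, summarize_folds(fold_metrics), provenance


def summarize_folds(folds: Sequence[FoldMetrics]) -> dict:
    """Mean and (population) standard deviation per metric."""
    out = {}
    for key in ("acc", "spec", "sen", "prec", "mcc", "auc", "aupr"):
        vals = np.array([getattr(f, key) for f in folds])
        out[key] = {"mean": float(vals.mean()), "std": float(vals.std())}
    return out


def rank_candidates(
    model: XGBClassifier,
    disease: str,
    MFM: FusedFeatureMatrix,
    DFM: FusedFeatureMatrix,
    known: Mapping[str, set[str]] | set[str],
    top_k: int = 50,
    encoder: AEModel | None = None,
) -> RankingResult:
    """Score and rank every miRNA not already associated with a disease.

    ``known`` is either the disease's known-associated miRNA set or a
    mapping disease → miRNA set.  Candidates are scored with the fitted
    classifier (after encoding when an autoencoder model is supplied)
    and returned as the top_k descending by score, names breaking ties.
    """
    if disease not in DFM.index:
        raise EntityLookupError(f"disease {disease!r} not in the disease index")
    known_set = set(known[disease]) if isinstance(known, Mapping) else set(known)
    candidates = sorted(set(MFM.index) - known_set)
    if not candidates:
        return RankingResult(disease=disease, ranked=(),
                             excluded_known=frozenset(known_set))
    ds = pair_features(MFM, DFM, [(m, disease) for m in candidates],
                       [0] * len(candidates))
    X = ds.features
    if encoder is not None:
        X = encode(encoder, X)
    scores = model.predict_proba(X)[:, 1]
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i]))
    ranked = tuple((candidates[i], float(scores[i])) for i in order[:top_k])
    return RankingResult(disease=disease, ranked=ranked,
                         excluded_known=frozenset(known_set))
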