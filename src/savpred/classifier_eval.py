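"""Gradient-boosted classification of SAVs and the evaluation protocol.

The classifier is an XGBoost tree ensemble (learning rate 0.1 by default)
predicting the probability that a variant is pathogenic; class calls use a
strict 0.5 threshold.  Evaluation follows the study protocol: stratified
ten-fold cross-validation with fold-internal median imputation, the five
confusion-matrix statistics

    accuracy     = (TP + TN) / (TP + TN + FP + FN)
    sensitivity  = TP / (TP + FN)
    specificity  = TN / (TN + FP)
    F1           = TP / (TP + (FP + FN) / 2)
    MCC          = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

plus balanced accuracy, ROC/PR curves with trapezoid AUROC and
step-interpolated AUPR, leave-one-feature-out ablation, ortholog-count
stratification, and benchmarking of predictions against deep mutational
scanning (DMS) fitness scores by absolute Spearman correlation and MSE.

Zero-denominator statistics are reported as 0 with an explicit flag so
tabulated results never contain holes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.metrics import auc, average_precision_score, roc_curve, precision_recall_curve
from sklearn.model_selection import StratifiedKFold

from .feature_table import FeatureMatrix, impute

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "TrainParams",
    "TrainedModel",
    "CvResult",
    "BenchmarkReport",
    "train",
    "predict_proba",
    "classify",
    "metrics",
    "roc_pr",
    "kfold_cv",
    "ablation",
    "stratify_by_orthologs",
    "benchmark_dms",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative confusion counts")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("all-zero confusion counts")

    @classmethod
    def from_predictions(cls, labels: Sequence[int],
                         predictions: Sequence[int]) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        p = np.asarray(predictions, dtype=int)
        return cls(
            tp=int(np.sum((y == 1) & (p == 1))),
            tn=int(np.sum((y == 0) & (p == 0))),
            fp=int(np.sum((y == 0) & (p == 1))),
            fn=int(np.sum((y == 1) & (p == 0))),
        )


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    balanced_accuracy: float
    auroc: Optional[float] = None
    aupr: Optional[float] = None
    flags: Tuple[str, ...] = ()

    def as_dict(self) -> Dict[str, float]:
        d = {k: v for k, v in asdict(self).items() if k != "flags"}
        return {k: v for k, v in d.items() if v is not None}


def _safe_div(num: float, den: float, name: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(f"zero denominator in {name}")
        return 0.0
    return num / den


def metrics(cc: ConfusionCounts) -> MetricsReport:
    """Evaluate the five printed statistics plus balanced accuracy."""
    tp, tn, fp, fn = cc.tp, cc.tn, cc.fp, cc.fn
    flags: List[str] = []
    accuracy = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy", flags)
    sensitivity = _safe_div(tp, tp + fn, "sensitivity", flags)
    specificity = _safe_div(tn, tn + fp, "specificity", flags)
    f1 = _safe_div(tp, tp + 0.5 * (fp + fn), "f1", flags)
    mcc_den = math.sqrt(
        float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc", flags)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        mcc=mcc,
        balanced_accuracy=(sensitivity + specificity) / 2.0,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class TrainParams:
    """Gradient-boosting hyperparameters (learning rate 0.1 by default)."""

    learning_rate: float = 0.1
    n_estimators: int = 200
    max_depth: int = 6
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    seed: int = 0

    def to_xgb_kwargs(self) -> Dict:
        return dict(
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            random_state=self.seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            objective="binary:logistic",
        )


@dataclass
class TrainedModel:
    """A fitted booster with its feature order and hyperparameters."""

    booster: xgb.Booster
    feature_names: Tuple[str, ...]
    params: TrainParams
    importance: pd.Series  # nonnegative gain-based scores per feature

    def predict_proba(self, rows) -> np.ndarray:
        return predict_proba(self, rows)

    def save(self) -> str:
        """Serialize to a single JSON document (text, deterministic)."""
        raw = self.booster.save_raw(raw_format="json").decode()
        doc = {
            "feature_names": list(self.feature_names),
            "params": asdict(self.params),
            "importance": {k: float(v) for k, v in self.importance.items()},
            "booster": raw,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def load(cls, text: str) -> "TrainedModel":
        doc = json.loads(text)
        booster = xgb.Booster()
        booster.load_model(bytearray(doc["booster"].encode()))
        names = tuple(doc["feature_names"])
        return cls(
            booster=booster,
            feature_names=names,
            params=TrainParams(**doc["params"]),
            importance=pd.Series(doc["importance"]).reindex(list(names)),
        )


def _as_array(matrix) -> Tuple[np.ndarray, Tuple[str, ...]]:
    if isinstance(matrix, FeatureMatrix):
        return matrix.df.to_numpy(dtype=float), matrix.feature_names
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), tuple(matrix.columns)
    X = np.asarray(matrix, dtype=float)
    return X, tuple(f"f{i}" for i in range(X.shape[1]))


def train(matrix, labels, params: Optional[TrainParams] = None) -> TrainedModel:
    """Fit the gradient-boosted classifier; deterministic for a fixed seed.

    Requires both classes present and no missing cells (impute first).
    """
    params = params or TrainParams()
    X, names = _as_array(matrix)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    if np.isnan(X).any():
        raise ValueError("missing cells in training matrix; impute first")
    clf = xgb.XGBClassifier(**params.to_xgb_kwargs())
    clf.fit(X, y)
    importance = pd.Series(clf.feature_importances_, index=list(names))
    return TrainedModel(
        booster=clf.get_booster(),
        feature_names=names,
        params=params,
        importance=importance,
    )


def predict_proba(model: TrainedModel, rows) -> np.ndarray:
    """Pathogenicity probabilities in [0, 1] for rows in training order."""
    X, _ = _as_array(rows)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2d input'}"
        )
    dm = xgb.DMatrix(X, feature_names=list(model.feature_names))
    return np.asarray(model.booster.predict(dm), dtype=float)


def classify(probs: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Class calls with a strict > threshold rule (0.5 -> class 0)."""
    return (np.asarray(probs, dtype=float) > threshold).astype(int)


@dataclass(frozen=True)
class RocPrCurves:
    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auroc: float
    aupr: float


def roc_pr(labels: Sequence[int], scores: Sequence[float]) -> RocPrCurves:
    """ROC and PR curves; trapezoid AUROC and step-interpolated AUPR.

    Equal scores collapse into one threshold, which yields the tie-aware
    pair-ordering interpretation of the AUROC.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes required for ROC/PR curves")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    precision, recall, _ = precision_recall_curve(y, s)
    return RocPrCurves(
        fpr=fpr,
        tpr=tpr,
        precision=precision,
        recall=recall,
        auroc=float(auc(fpr, tpr)),
        aupr=float(average_precision_score(y, s)),
    )


@dataclass
class CvResult:
    fold_reports: List[MetricsReport]
    fold_assignments: np.ndarray  # test-fold index per row
    mean: Dict[str, float]
    std: Dict[str, float]
    oof_scores: np.ndarray  # out-of-fold probabilities, row order
    labels: np.ndarray

    def pooled_curves(self) -> RocPrCurves:
        return roc_pr(self.labels, self.oof_scores)


def _aggregate(reports: List[MetricsReport]) -> Tuple[Dict, Dict]:
    keys = ["accuracy", "sensitivity", "specificity", "f1", "mcc",
            "balanced_accuracy", "auroc", "aupr"]
    mean, std = {}, {}
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports], dtype=float)
        mean[k] = float(vals.mean())
        std[k] = float(vals.std(ddof=0))
    return mean, std


def kfold_cv(
    matrix: FeatureMatrix,
    labels: Optional[Sequence[int]] = None,
    k: int = 10,
    seed: int = 0,
    params: Optional[TrainParams] = None,
) -> CvResult:
    """Stratified k-fold cross-validation with fold-internal imputation.

    Fold assignment is deterministic per seed; imputation medians are refit
    on each training fold so test rows never influence their own fill
    values.  Requires k <= per-class counts.
    """
    y = np.asarray(matrix.labels if labels is None else labels, dtype=float)
    if np.isnan(y).any():
        raise ValueError("unlabeled rows in cross-validation")
    y = y.astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes required for cross-validation")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds minority class count {counts.min()}")
    params = params or TrainParams()

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(matrix)
    assignments = np.full(n, -1, dtype=int)
    oof = np.full(n, np.nan)
    reports: List[MetricsReport] = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(n), y)):
        train_mask = np.zeros(n, dtype=bool)
        train_mask[tr_idx] = True
        filled = impute(matrix, train_mask)
        model = train(filled.df.iloc[tr_idx], y[tr_idx], params)
        probs = predict_proba(model, filled.df.iloc[te_idx])
        assignments[te_idx] = fold
        oof[te_idx] = probs
        rep = metrics(ConfusionCounts.from_predictions(y[te_idx],
                                                       classify(probs)))
        curves = roc_pr(y[te_idx], probs)
        rep.auroc = curves.auroc
        rep.aupr = curves.aupr
        reports.append(rep)
    mean, std = _aggregate(reports)
    return CvResult(
        fold_reports=reports,
        fold_assignments=assignments,
        mean=mean,
        std=std,
        oof_scores=oof,
        labels=y,
    )


def ablation(
    matrix: FeatureMatrix,
    labels: Optional[Sequence[int]] = None,
    k: int = 10,
    seed: int = 0,
    params: Optional[TrainParams] = None,
) -> pd.DataFrame:
    """Leave-one-feature-out ablation over all features.

    Each run trains on the remaining features with the same folds; rows are
    sorted by the accuracy drop relative to the full model (largest first).
    """
    full = kfold_cv(matrix, labels, k=k, seed=seed, params=params)
    rows = []
    for name in matrix.feature_names:
        res = kfold_cv(matrix.drop_features([name]), labels, k=k, seed=seed,
                       params=params)
        rows.append(
            {
                "excluded_feature": name,
                "accuracy": res.mean["accuracy"],
                "balanced_accuracy": res.mean["balanced_accuracy"],
                "f1": res.mean["f1"],
                "accuracy_drop": full.mean["accuracy"] - res.mean["accuracy"],
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["accuracy_drop", "excluded_feature"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


def stratify_by_orthologs(
    matrix: FeatureMatrix,
    labels: Optional[Sequence[int]],
    ortholog_counts: Mapping[str, int],
    thresholds: Sequence[int] = (50, 100, 150, 200, 250, 300),
    k: int = 10,
    seed: int = 0,
    params: Optional[TrainParams] = None,
) -> Dict[int, Optional[float]]:
    """Cross-validated accuracy with training restricted per threshold.

    For each threshold, folds are shared; within a fold the model trains
    only on SAVs of proteins with at least that many orthologs and is
    evaluated on the full test fold.  Empty or single-class strata are
    skipped with a warning (value None).
    """
    y = np.asarray(matrix.labels if labels is None else labels, dtype=int)
    params = params or TrainParams()
    pids = matrix.df.index.get_level_values("protein_id")
    counts = np.array([ortholog_counts[p] for p in pids])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(matrix)
    splits = list(skf.split(np.zeros(n), y))

    results: Dict[int, Optional[float]] = {}
    for t in thresholds:
        in_stratum = counts >= t
        accs = []
        ok = True
        for tr_idx, te_idx in splits:
            tr_idx = tr_idx[in_stratum[tr_idx]]
            if len(tr_idx) == 0 or len(set(y[tr_idx].tolist())) < 2:
                ok = False
                break
            train_mask = np.zeros(n, dtype=bool)
            train_mask[tr_idx] = True
            filled = impute(matrix, train_mask)
            model = train(filled.df.iloc[tr_idx], y[tr_idx], params)
            probs = predict_proba(model, filled.df.iloc[te_idx])
            rep = metrics(ConfusionCounts.from_predictions(
                y[te_idx], classify(probs)))
            accs.append(rep.accuracy)
        if not ok:
            warnings.warn(f"ortholog threshold {t}: empty or single-class "
                          "training stratum, skipped", stacklevel=2)
            results[t] = None
        else:
            results[t] = float(np.mean(accs))
    return results


@dataclass
class BenchmarkReport:
    """Agreement of predictions with a DMS fitness screen."""

    spearman_abs: float
    mse: float
    coverage: float
    n_shared: int
    flags: Tuple[str, ...] = ()


def benchmark_dms(predictions: pd.Series, dms_scores: pd.Series) -> BenchmarkReport:
    """Absolute Spearman rho (average-rank ties), MSE and coverage.

    Both inputs are keyed by variant; only shared variants enter the
    statistics and coverage is shared / total DMS variants.  Constant
    predictions leave rho undefined: reported as 0 with a flag, MSE is
    still computed.
    """
    shared = predictions.index.intersection(dms_scores.index)
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared variants, got {len(shared)}"
        )
    p = predictions.loc[shared].to_numpy(dtype=float)
    d = dms_scores.loc[shared].to_numpy(dtype=float)
    flags: List[str] = []
    if np.all(p == p[0]) or np.all(d == d[0]):
        rho = 0.0
        flags.append("constant input: Spearman undefined, reported as 0")
    else:
        rho = float(abs(stats.spearmanr(p, d).statistic))
    return BenchmarkReport(
        spearman_abs=rho,
        mse=float(np.mean((p - d) ** 2)),
        coverage=len(shared) / len(dms_scores),
        n_shared=int(len(shared)),
        flags=tuple(flags),
    )
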