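"""Nested stratified cross-validated RBF-SVM evaluation and metrics.

Model selection happens in an inner stratified k-fold entirely inside each
outer training fold, so the aggregated out-of-fold (OOF) scores are unbiased
by hyperparameter tuning. The model is the standard pipeline
``z-score standardization -> SVC(kernel="rbf", probability=True)``, with
standardization parameters fit on outer-training data only.

Determinism: outer folds, inner folds, the probability-calibration split and
the bootstrap for curve confidence intervals are all driven by explicit
seeds, so identical seeds yield bit-identical reports.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (average_precision_score, balanced_accuracy_score,
                             f1_score, precision_recall_curve, roc_curve)
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["CVSpec", "FoldResult", "NestedCVReport", "nested_cv",
           "summarize_scores", "oof_confusion", "ovr_curves",
           "paired_fold_ttest", "fold_assignment_hash"]

#: gamma = "scale" resolves (inside the SVC) to 1 / (n_features * Var(X))
#: computed on the standardized training matrix, i.e. ~1/n_features.
GammaValue = float | str


@dataclass(frozen=True)
class CVSpec:
    """Nested-CV protocol: outer/inner stratified k-folds and the SVM grid.

    Defaults are the study protocol: 5 shuffled outer folds (seed 42),
    5 shuffled inner folds (seed 1), grid C in {0.3, 1, 3, 10, 30},
    gamma in {0.003, 0.01, 0.03, "scale"}, class_weight in {None,
    "balanced"}, inner selection by mean macro-F1.
    """

    outer_folds: int = 5
    outer_shuffle: bool = True
    outer_seed: int = 42
    inner_folds: int = 5
    inner_shuffle: bool = True
    inner_seed: int = 1
    C_grid: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0)
    gamma_grid: tuple[GammaValue, ...] = (0.003, 0.01, 0.03, "scale")
    class_weight_grid: tuple[str | None, ...] = (None, "balanced")
    inner_scoring: str = "macro_f1"  # or "balanced_accuracy"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if not (self.C_grid and self.gamma_grid and self.class_weight_grid):
            raise ValueError("hyperparameter grid must be nonempty")

    def grid(self) -> list[dict]:
        """Grid points in tie-break order: smaller C first, then smaller
        gamma with "scale" last, then class_weight None before balanced."""
        key = lambda g: (np.inf if g == "scale" else g)
        out = []
        for C in sorted(self.C_grid):
            for gamma in sorted(self.gamma_grid, key=key):
                for cw in self.class_weight_grid:
                    out.append({"C": C, "gamma": gamma, "class_weight": cw})
        return out


@dataclass(frozen=True)
class FoldResult:
    fold: int
    params: dict
    macro_f1: float
    balanced_accuracy: float
    test_indices: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray


@dataclass
class NestedCVReport:
    classes: np.ndarray
    folds: list[FoldResult]
    fold_assignment: np.ndarray     # outer fold id per sample
    fold_hash: str
    y_true: np.ndarray
    oof_pred: np.ndarray            # the classifier's direct decision
    oof_proba: np.ndarray           # calibrated probabilities, rows sum to 1
    feature_names: tuple[str, ...]

    @property
    def fold_scores(self) -> np.ndarray:
        return np.array([f.macro_f1 for f in self.folds])

    @property
    def oof_accuracy(self) -> float:
        return float(np.mean(self.oof_pred == self.y_true))

    @property
    def oof_macro_f1(self) -> float:
        return float(f1_score(self.y_true, self.oof_pred, average="macro"))

    def summary(self) -> dict:
        mean, sd, ci = summarize_scores(self.fold_scores)
        return {"macro_f1_mean": mean, "macro_f1_sd": sd,
                "macro_f1_ci95": ci, "oof_accuracy": self.oof_accuracy,
                "fold_hash": self.fold_hash,
                "chosen_params": [f.params for f in self.folds]}


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    return X, tuple(f"x{i}" for i in range(X.shape[1]))


def fold_assignment_hash(assignment: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(assignment, dtype=np.int64)
                          .tobytes()).hexdigest()[:16]


def _score(metric: str, y_true, y_pred) -> float:
    if metric == "macro_f1":
        return float(f1_score(y_true, y_pred, average="macro",
                              zero_division=0))
    if metric == "balanced_accuracy":
        return float(balanced_accuracy_score(y_true, y_pred))
    raise ValueError(f"unknown scoring {metric!r}")


def _make_pipe(params: dict, probability: bool, seed: int) -> Pipeline:
    # SVC(probability=True) is the intended model: discrete predictions are
    # the SVM's direct decision while probabilities come from the internal
    # Platt calibration on training data; newer sklearn deprecation-warns
    # about the parameter, which is irrelevant here.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(kernel="rbf", C=params["C"], gamma=params["gamma"],
                  class_weight=params["class_weight"],
                  probability=probability, random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("svc", svc)])


def _quiet_fit(pipe: Pipeline, X, y) -> Pipeline:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return pipe.fit(X, y)


def nested_cv(X, y, spec: CVSpec = CVSpec()) -> NestedCVReport:
    """Run the full nested stratified CV protocol.

    For each outer fold the inner loop scores every grid point by mean
    inner-fold score and the winner (first under the tie-break order) is
    refit with probability calibration on the whole outer-training fold.
    The inner search skips probability calibration because it only needs
    discrete predictions, which are unaffected by it.

    Raises if any class is too small for stratification (each class needs
    at least 2 samples in every outer fold) or any feature is non-finite.
    """
    Xa, names = _as_matrix(X)
    y = np.asarray(y)
    if not np.isfinite(Xa).all():
        rows, cols = np.nonzero(~np.isfinite(Xa))
        raise ValueError(
            f"non-finite feature value at row {rows[0]}, column "
            f"{names[cols[0]]!r}")
    classes, counts = np.unique(y, return_counts=True)
    deficient = classes[counts < 2 * spec.outer_folds]
    if len(deficient):
        raise ValueError(
            f"class {deficient[0]!r} has too few samples for "
            f"{spec.outer_folds}-fold nested stratification")

    outer = StratifiedKFold(n_splits=spec.outer_folds,
                            shuffle=spec.outer_shuffle,
                            random_state=spec.outer_seed if spec.outer_shuffle else None)
    inner = StratifiedKFold(n_splits=spec.inner_folds,
                            shuffle=spec.inner_shuffle,
                            random_state=spec.inner_seed if spec.inner_shuffle else None)
    grid = spec.grid()

    n = len(y)
    assignment = np.full(n, -1, dtype=np.int64)
    oof_pred = np.empty(n, dtype=y.dtype)
    oof_proba = np.zeros((n, len(classes)))
    folds: list[FoldResult] = []

    for k, (tr, te) in enumerate(outer.split(Xa, y)):
        assignment[te] = k
        Xtr, ytr = Xa[tr], y[tr]
        best_score, best_params = -np.inf, None
        for params in grid:
            inner_scores = []
            for itr, ite in inner.split(Xtr, ytr):
                pipe = _make_pipe(params, probability=False, seed=spec.inner_seed)
                _quiet_fit(pipe, Xtr[itr], ytr[itr])
                inner_scores.append(_score(spec.inner_scoring, ytr[ite],
                                           pipe.predict(Xtr[ite])))
            m = float(np.mean(inner_scores))
            if m > best_score:  # strict: ties keep the earlier grid point
                best_score, best_params = m, params
        pipe = _make_pipe(best_params, probability=True, seed=spec.inner_seed)
        _quiet_fit(pipe, Xtr, ytr)
        pred = pipe.predict(Xa[te])
        proba = pipe.predict_proba(Xa[te])
        # align probability columns to the global class order
        col = {c: i for i, c in enumerate(pipe.named_steps["svc"].classes_)}
        for j, c in enumerate(classes):
            oof_proba[te, j] = proba[:, col[c]]
        oof_pred[te] = pred
        scaler = pipe.named_steps["scale"]
        folds.append(FoldResult(
            fold=k, params=dict(best_params),
            macro_f1=_score("macro_f1", y[te], pred),
            balanced_accuracy=_score("balanced_accuracy", y[te], pred),
            test_indices=te.copy(),
            scaler_mean=scaler.mean_.copy(),
            scaler_scale=scaler.scale_.copy()))

    assert (assignment >= 0).all()
    return NestedCVReport(
        classes=classes, folds=folds, fold_assignment=assignment,
        fold_hash=fold_assignment_hash(assignment), y_true=y.copy(),
        oof_pred=oof_pred, oof_proba=oof_proba, feature_names=names)


def summarize_scores(scores) -> tuple[float, float, tuple[float, float]]:
    """Mean, sample SD and the 95% t-interval mean +- t(.975, n-1)*SD/sqrt(n).

    The interval is reported unclipped even when it extends beyond [0, 1]."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 fold scores")
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    half = stats.t.ppf(0.975, len(s) - 1) * sd / np.sqrt(len(s))
    return mean, sd, (mean - float(half), mean + float(half))


def oof_confusion(report: NestedCVReport,
                  class_order: tuple | None = None) -> pd.DataFrame:
    """Row-normalized OOF confusion matrix (rows = true class = recall).

    A class with zero true samples yields a NaN row."""
    order = list(class_order) if class_order is not None else list(report.classes)
    k = len(order)
    mat = np.zeros((k, k))
    idx = {c: i for i, c in enumerate(order)}
    for t, p in zip(report.y_true, report.oof_pred):
        mat[idx[t], idx[p]] += 1
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(sums > 0, mat / sums, np.nan)
    return pd.DataFrame(mat, index=order, columns=order)


def _stratified_boot_idx(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = []
    for c in np.unique(y):
        pos = np.nonzero(y == c)[0]
        out.append(rng.choice(pos, size=len(pos), replace=True))
    return np.concatenate(out)


def ovr_curves(report: NestedCVReport, n_boot: int = 2000,
               seed: int = 0) -> dict:
    """One-vs-rest ROC and PR analysis from OOF probabilities.

    Per class: ROC curve with trapezoidal AUC, PR curve with step-integrated
    AUPRC (average precision), the class-prevalence no-skill baseline, and
    95% CIs from a stratified bootstrap over OOF samples. Also reports
    micro- and macro-averaged AUPRC.
    """
    y, proba, classes = report.y_true, report.oof_proba, report.classes
    if len(classes) < 2:
        raise ValueError("need at least two classes in the OOF predictions")
    rng = np.random.default_rng(seed)
    boots = [_stratified_boot_idx(y, rng) for _ in range(n_boot)]
    out: dict = {"classes": list(classes), "per_class": {}}
    onehot = (y[:, None] == classes[None, :]).astype(int)
    for j, c in enumerate(classes):
        yj, pj = onehot[:, j], proba[:, j]
        fpr, tpr, _ = roc_curve(yj, pj)
        prec, rec, _ = precision_recall_curve(yj, pj)
        auc_val = float(_trapezoid_auc(fpr, tpr))
        ap = float(average_precision_score(yj, pj))
        auc_bs, ap_bs = [], []
        for idx in boots:
            if len(np.unique(yj[idx])) < 2:
                continue
            f, t, _ = roc_curve(yj[idx], pj[idx])
            auc_bs.append(_trapezoid_auc(f, t))
            ap_bs.append(average_precision_score(yj[idx], pj[idx]))
        out["per_class"][c] = {
            "roc": (fpr.tolist(), tpr.tolist()),
            "pr": (rec.tolist(), prec.tolist()),
            "auc": auc_val,
            "auc_ci95": tuple(np.percentile(auc_bs, [2.5, 97.5])) if auc_bs else (np.nan, np.nan),
            "auprc": ap,
            "auprc_ci95": tuple(np.percentile(ap_bs, [2.5, 97.5])) if ap_bs else (np.nan, np.nan),
            "prevalence_baseline": float(yj.mean()),
        }
    out["micro_auprc"] = float(average_precision_score(onehot, proba,
                                                       average="micro"))
    out["macro_auprc"] = float(average_precision_score(onehot, proba,
                                                       average="macro"))
    return out


def paired_fold_ttest(scores_a, scores_b) -> dict:
    """Two-sided paired t-test across outer folds (df = n-1).

    Returns t, p and df; when the per-fold differences have zero variance
    the statistic is undefined and the result is flagged degenerate."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("score vectors must have equal length >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    # rounding guard: a constant offset should register as zero variance
    if sd <= 1e-12 * max(1.0, float(np.abs(d).max())):
        return {"t": float("nan"), "p": float("nan"), "df": n - 1,
                "degenerate": True, "mean_diff": float(d.mean())}
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return {"t": t, "p": p, "df": n - 1, "degenerate": False,
            "mean_diff": float(d.mean())}
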