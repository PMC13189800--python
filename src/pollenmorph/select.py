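"""Multicollinearity-aware feature selection ledger.

Four complementary criteria decide which of the eleven candidate descriptors
enter the final model:

1. redundancy — pairwise Pearson correlation (|r| > 0.85 flags a pair) and
   the variance inflation factor VIF_j = 1 / (1 - R^2_j) from regressing each
   z-scored feature on all the others (flags at 5, sensitivity flags at 10);
2. predictive contribution — drop-column ablation under the frozen nested-CV
   protocol and permutation importance on out-of-fold data;
3. stability — rank agreement of permutation importance across outer folds;
4. biological validity — expert judgment, recorded as free-text reasons in
   the exclusion log rather than computed.

Exclusion decisions are explicit inputs: the module never auto-drops a
feature, it computes the evidence and applies a documented decision list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as ev
from .features import CORE9, FEATURES_11

__all__ = ["FeatureMatrix", "SelectionReport", "correlation_screen", "vif",
           "drop_column_ablation", "permutation_importance",
           "stability_across_folds", "apply_exclusions"]


@dataclass
class FeatureMatrix:
    """Samples x named features, with per-row class labels and an optional
    slide id per row (for group-aware protocols)."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.X.columns)) != self.X.shape[1]:
            raise ValueError("feature names must be unique")
        self.y = np.asarray(self.y)
        if len(self.y) != len(self.X):
            raise ValueError("labels and rows disagree in length")


@dataclass
class SelectionReport:
    correlation: pd.DataFrame | None = None
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    vif_table: pd.DataFrame | None = None
    ablation_table: pd.DataFrame | None = None
    permutation_table: pd.DataFrame | None = None
    stability: dict | None = None
    decisions: list[dict] = field(default_factory=list)


def correlation_screen(X: pd.DataFrame, threshold: float = 0.85
                       ) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Full Pearson correlation matrix plus all unordered pairs with
    |r| > threshold.

    Constant columns produce NaN correlations; their pairs are reported with
    r = NaN so the caller sees them (they cannot be flagged numerically)."""
    if len(X) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    corr = X.corr(method="pearson")
    flagged = []
    cols = list(X.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r) or abs(r) > threshold:
                flagged.append((a, b, float(r)))
    return corr, flagged


def vif(X: pd.DataFrame) -> pd.DataFrame:
    """VIF per feature from OLS of each z-scored column on all the others.

    Returns a table with the VIF value and flags at the 5 and 10 thresholds;
    perfect collinearity is reported as +inf. Computed on the full (unsplit)
    matrix: this is a diagnostic of the design, not part of the model."""
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns for VIF")
    sd = X.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant column(s) {bad} cannot enter VIF")
    Z = ((X - X.mean()) / sd).to_numpy()
    rows = []
    for j, name in enumerate(X.columns):
        yj = Z[:, j]
        A = np.column_stack([Z[:, [k for k in range(p) if k != j]],
                             np.ones(n)])
        beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(yj @ yj)  # z-scored: mean 0
        r2 = 1.0 - ss_res / ss_tot
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"feature": name, "vif": float(v), "r2": r2,
                     "flag_gt5": bool(v > 5), "flag_gt10": bool(v > 10),
                     "collinear": not np.isfinite(v)})
    return pd.DataFrame(rows).set_index("feature")


def drop_column_ablation(X: pd.DataFrame, y, base_features: list[str],
                         cv_spec: ev.CVSpec = ev.CVSpec(),
                         named_sets: dict[str, list[str]] | None = None
                         ) -> pd.DataFrame:
    """Nested-CV macro-F1 for the full feature set, every leave-one-out set,
    and any extra named sets (e.g. the core-9), under bit-identical fold
    assignments (asserted via the stored fold hashes).
    """
    missing = [f for f in base_features if f not in X.columns]
    if missing:
        raise ValueError(f"feature(s) {missing} not in the matrix")
    sets: dict[str, list[str]] = {"full": list(base_features)}
    for f in base_features:
        sets[f"drop_{f}"] = [g for g in base_features if g != f]
    for name, feats in (named_sets or {}).items():
        sets[name] = list(feats)
    rows = []
    hashes = set()
    for name, feats in sets.items():
        rep = ev.nested_cv(X[feats], y, cv_spec)
        mean, sd, _ = ev.summarize_scores(rep.fold_scores)
        hashes.add(rep.fold_hash)
        rows.append({"set_name": name, "features": tuple(feats),
                     "k": len(feats), "f1_macro_mean": mean,
                     "f1_macro_sd": sd, "fold_hash": rep.fold_hash,
                     "fold_scores": tuple(rep.fold_scores)})
    assert len(hashes) == 1, "fold assignments diverged across feature sets"
    return pd.DataFrame(rows)


def permutation_importance(X: pd.DataFrame, y,
                           cv_spec: ev.CVSpec = ev.CVSpec(),
                           n_repeats: int = 10, seed: int = 0
                           ) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Mean decrease in macro-F1 when one feature is permuted in held-out
    data.

    The nested-CV protocol is run once; then for each outer fold the fitted
    fold model is re-evaluated on its own test fold with one column shuffled
    (within the test fold only) ``n_repeats`` times. Returns the aggregate
    table and the per-fold tables used for the stability summary.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rep = ev.nested_cv(X, y, cv_spec)
    Xa = X.to_numpy(dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    per_fold: list[pd.DataFrame] = []
    for fr in rep.folds:
        tr = np.nonzero(rep.fold_assignment != fr.fold)[0]
        te = fr.test_indices
        pipe = ev._make_pipe(fr.params, probability=False, seed=cv_spec.inner_seed)
        ev._quiet_fit(pipe, Xa[tr], y[tr])
        base = ev._score("macro_f1", y[te], pipe.predict(Xa[te]))
        rows = []
        for j, name in enumerate(X.columns):
            drops = []
            for _ in range(n_repeats):
                Xp = Xa[te].copy()
                Xp[:, j] = Xp[rng.permutation(len(te)), j]
                drops.append(base - ev._score("macro_f1", y[te],
                                              pipe.predict(Xp)))
            rows.append({"feature": name,
                         "importance_mean": float(np.mean(drops)),
                         "importance_sd": float(np.std(drops, ddof=1))
                         if n_repeats > 1 else 0.0})
        per_fold.append(pd.DataFrame(rows).set_index("feature"))
    stacked = pd.concat([t["importance_mean"] for t in per_fold], axis=1)
    agg = pd.DataFrame({
        "importance_mean": stacked.mean(axis=1),
        "importance_sd": stacked.std(axis=1, ddof=1),
    })
    return agg, per_fold


def stability_across_folds(per_fold_tables: list[pd.DataFrame]) -> dict:
    """Rank agreement of permutation importance across folds.

    Rank 1 = most important within each fold. Returns the per-fold rank
    table, the pairwise Spearman rank-correlation matrix and its mean over
    fold pairs."""
    if len(per_fold_tables) < 2:
        raise ValueError("need at least 2 folds")
    ranks = pd.concat(
        [t["importance_mean"].rank(ascending=False) for t in per_fold_tables],
        axis=1)
    ranks.columns = [f"fold{k}" for k in range(len(per_fold_tables))]
    corr = ranks.corr(method="spearman")
    n = len(per_fold_tables)
    pairs = [corr.iloc[i, j] for i in range(n) for j in range(i + 1, n)]
    return {"ranks": ranks, "rank_correlation": corr,
            "mean_rank_correlation": float(np.mean(pairs))}


def apply_exclusions(X: pd.DataFrame, decisions: list[dict],
                     report: SelectionReport | None = None) -> pd.DataFrame:
    """Drop the features named in the decision list.

    Each decision is ``{"feature": name, "reason": text}``; reasons are
    appended to the report's exclusion log. Applying the two canonical
    exclusions (fractal_dim: redundant and not biologically plausible for
    exines; edge_density: redundant with spike_cnt, which carries more
    unique signal) to an 11-descriptor table yields the core-9 columns in
    canonical order.
    """
    drop = []
    for d in decisions:
        name = d["feature"]
        if name not in X.columns:
            raise ValueError(f"unknown column {name!r} in exclusion decision")
        drop.append(name)
        if report is not None:
            report.decisions.append(dict(d))
    keep = [c for c in X.columns if c not in drop]
    if not keep:
        raise ValueError("exclusions would remove every column")
    if set(keep) == set(CORE9):
        keep = list(CORE9)
    elif set(keep) == set(FEATURES_11):
        keep = list(FEATURES_11)
    return X[keep]
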