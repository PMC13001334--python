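"""Single-feature predictive evaluation by cross-validated ROC-AUC.

Each feature is scored on its own: a ridge-stabilized logistic regression is
fit on standardized training folds (stratified k-fold) and evaluated by
ROC-AUC on the held-out fold. Standardization parameters come from the
training fold only, so no information leaks into the evaluation. AUC uses
the midrank (Mann-Whitney) convention for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold


def fit_logistic(
    x: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Fit logistic regression by IRLS with a small ridge penalty.

    ``x`` is (n,) or (n, p); an intercept column is added internally.
    Returns weights [w_1..w_p, intercept]. The ridge term guarantees a
    finite optimum under perfect separation (flagged with a warning).
    Deterministic: Newton iterations from zero until the penalized
    log-loss changes by less than ``tol``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y = (y == classes.max()).astype(float)

    n, p = x.shape
    X = np.column_stack([x, np.ones(n)])
    w = np.zeros(p + 1)
    penalty = np.full(p + 1, ridge)
    penalty[-1] = 0.0  # intercept unpenalized
    prev_loss = np.inf
    for _ in range(max_iter):
        eta = X @ w
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        loss = -np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300))
        loss += 0.5 * np.sum(penalty * w**2)
        grad = X.T @ (mu - y) + penalty * w
        s = np.clip(mu * (1 - mu), 1e-10, None)
        hess = (X * s[:, None]).T @ X + np.diag(penalty + 1e-12)
        w = w - np.linalg.solve(hess, grad)
        if abs(prev_loss - loss) < tol:
            break
        prev_loss = loss
    else:
        warnings.warn("IRLS did not converge; possible perfect separation")
    eta = X @ w
    if np.all((eta > 0) == (y == 1)) and np.abs(eta).min() > 5.0:
        warnings.warn("data appear perfectly separable; ridge kept weights finite")
    return w


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC as the normalized Mann-Whitney U statistic (midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute ROC-AUC")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class EvalResult:
    """Cross-validated performance of one feature."""

    feature: str
    mean_auc: float
    fold_aucs: list[float] = field(default_factory=list)
    n_pos: int = 0
    n_neg: int = 0
    subset: str = "all"


def cv_feature_ranking(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 5,
    seed: int = 0,
    feature_columns: list[str] | None = None,
    subset: pd.Series | np.ndarray | None = None,
    subset_label: str = "all",
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Rank features by mean out-of-fold ROC-AUC of single-feature models.

    ``subset`` optionally restricts rows (e.g. to fixed-backbone-designed
    sequences only, to control method confounding). Folds are stratified
    and shuffled with ``seed``; identical seeds give identical folds and
    AUCs. Returns a DataFrame sorted by mean_auc (descending) with columns
    feature, mean_auc, fold_aucs, n_pos, n_neg, subset.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = features.set_index("design_id") if "design_id" in features.columns else features
    y = np.asarray(labels).astype(int)
    if len(y) != len(df):
        raise ValueError("labels length does not match feature table")
    if subset is not None:
        mask = np.asarray(subset).astype(bool)
        df, y = df.loc[mask], y[mask]
    if feature_columns is None:
        feature_columns = [
            c for c in df.columns if np.issubdtype(df[c].dtype, np.number)
        ]

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    rows = []
    for col in feature_columns:
        x = df[col].to_numpy(dtype=float)
        if np.isnan(x).any() or np.nanstd(x) == 0:
            continue
        fold_aucs = []
        for train, test in splits:
            m, s = x[train].mean(), x[train].std()
            s = s if s > 0 else 1.0
            xt = (x - m) / s
            w = fit_logistic(xt[train], y[train], ridge=ridge)
            scores = xt[test] * w[0] + w[1]
            if y[test].min() == y[test].max():
                continue  # fold lacks a class; cannot score
            fold_aucs.append(roc_auc(scores, y[test]))
        if not fold_aucs:
            continue
        rows.append(
            {
                "feature": col,
                "mean_auc": float(np.mean(fold_aucs)),
                "fold_aucs": fold_aucs,
                "n_pos": int(y.sum()),
                "n_neg": int(len(y) - y.sum()),
                "subset": subset_label,
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_auc", ascending=False, kind="stable")
    return out.reset_index(drop=True)
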