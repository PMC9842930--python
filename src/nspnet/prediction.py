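"""Symptom-score prediction from regional network features.

The predictive model is deliberately simple: regional features
(one NSP measure per region, z-scored) are ranked by their univariate
regression F statistic against the score, the top-K enter a multiple
linear regression, and leave-one-out cross-validation (LOO-CV) yields a
predicted score per subject. K is swept over its full range and chosen
to maximize the Pearson correlation between observed and predicted
scores. Significance comes from a permutation test that holds the
selected features fixed and re-runs the full LOO-CV on each permuted
score vector.

Feature selection on all subjects before CV is optimistic — the
selection sees the test subject's score. That optimism is deliberate
(the permutation test, which grants every permuted score the same
advantage-free fixed features, is the inferential guard) and a nested
mode that re-selects features inside every fold is available via
``nested=True`` for sensitivity analysis.

Weighted-degree and participation-coefficient baselines pass through
the identical path so comparisons between NSP features and classic
graph measures are like-for-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_regression

__all__ = [
    "PredictionResult",
    "normalize_features",
    "rank_features",
    "loo_cv_predict",
    "best_k_search",
    "permutation_pvalue",
    "system_weights",
    "graph_baselines",
    "common_score_pca",
    "cross_predict",
    "predict_scores",
]

_LEVERAGE_TOL = 1e-8


@dataclass
class PredictionResult:
    best_k: int
    selected: list                  # feature ids, ranking order
    weights: pd.Series              # per-feature coefficients, 0 if unselected
    y_pred: np.ndarray              # LOO-CV predictions, subject order
    r_obs: float
    p_perm: float | None = None
    per_k: pd.DataFrame | None = field(default=None, repr=False)
    system_means: pd.DataFrame | None = None
    seed: int | None = None


def normalize_features(x) -> np.ndarray:
    """Z-score each feature column (population SD)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column")
    return (x - x.mean(axis=0)) / sd


def rank_features(x, y) -> np.ndarray:
    """Feature order by descending univariate-regression F statistic.

    Ties are broken by ascending feature index (stable sort).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(y) == 0:
        raise ValueError("score vector has zero variance")
    f_stat, _ = f_regression(x, y)
    f_stat = np.nan_to_num(f_stat, nan=0.0)
    return np.argsort(-f_stat, kind="stable")


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(x.shape[0]), x])


def loo_cv_predict(x_selected, y) -> np.ndarray:
    """Explicit leave-one-out OLS predictions.

    Each subject's score is predicted from an intercept+features OLS fit
    on the remaining subjects. Rank-deficient folds are rejected with
    the offending fold index.
    """
    x = np.asarray(x_selected, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    n, k = x.shape
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 subjects (n={n}, k={k})")
    z = _design(x)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta, _, rank, _ = np.linalg.lstsq(z[mask], y[mask], rcond=None)
        if rank < z.shape[1]:
            raise ValueError(f"rank-deficient design in fold {i}")
        preds[i] = z[i] @ beta
    return preds


def _loo_hat_predict(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form LOO predictions via the hat matrix.

    For OLS, the leave-one-out prediction is
    ``(ŷ_i − h_ii y_i) / (1 − h_ii)`` with h the leverage; exact and
    O(n²k) instead of n separate fits. ``y`` may be a matrix whose
    columns are scored independently (used by the permutation test).
    """
    z = _design(x)
    q, r = np.linalg.qr(z)
    if np.any(np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(r[0, 0]))):
        raise np.linalg.LinAlgError("rank-deficient design")
    h_diag = np.einsum("ij,ij->i", q, q)
    if np.any(1.0 - h_diag < _LEVERAGE_TOL):
        i = int(np.argmax(h_diag))
        raise np.linalg.LinAlgError(f"rank-deficient design in fold {i}")
    hat_y = q @ (q.T @ y)
    if y.ndim == 1:
        return (hat_y - h_diag * y) / (1.0 - h_diag)
    return (hat_y - h_diag[:, None] * y) / (1.0 - h_diag)[:, None]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def best_k_search(
    x,
    y,
    feature_ids=None,
    max_k: int | None = None,
    nested: bool = False,
) -> PredictionResult:
    """Sweep K over top-K ranked features; keep the K maximizing LOO-CV r.

    Features are z-scored, ranked once on all subjects (``nested=True``
    re-ranks inside every fold instead), and for each feasible K the
    LOO-CV observed-vs-predicted correlation is recorded; ties prefer
    the smallest K. Reported weights come from a final all-subjects OLS
    on the selected normalized features.
    """
    x_raw = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_feat = x_raw.shape
    if feature_ids is None:
        feature_ids = (
            list(x.columns) if isinstance(x, pd.DataFrame)
            else [str(j) for j in range(n_feat)]
        )
    xz = normalize_features(x_raw)
    order = rank_features(xz, y)
    k_cap = min(n_feat, n - 2, max_k or n_feat)

    rows = []
    best = None
    for k in range(1, k_cap + 1):
        cols = order[:k]
        try:
            if nested:
                pred = _nested_loo(xz, y, k)
            else:
                pred = _loo_hat_predict(xz[:, cols], y)
        except np.linalg.LinAlgError:
            continue
        r = _pearson(y, pred)
        rows.append((k, r))
        if best is None or r > best[1]:
            best = (k, r, pred)
    if best is None:
        raise ValueError("no feasible K: every fold design was degenerate")
    best_k, r_obs, y_pred = best
    sel = order[:best_k]
    beta, *_ = np.linalg.lstsq(_design(xz[:, sel]), y, rcond=None)
    weights = pd.Series(0.0, index=pd.Index(feature_ids, name="feature"))
    weights.iloc[sel] = beta[1:]
    return PredictionResult(
        best_k=int(best_k),
        selected=[feature_ids[j] for j in sel],
        weights=weights,
        y_pred=y_pred,
        r_obs=float(r_obs),
        per_k=pd.DataFrame(rows, columns=["k", "r"]),
    )


def _nested_loo(xz: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """LOO predictions with feature ranking redone inside every fold."""
    n = xz.shape[0]
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        order_i = rank_features(xz[mask], y[mask])[:k]
        z = _design(xz[mask][:, order_i])
        beta, _, rank, _ = np.linalg.lstsq(z, y[mask], rcond=None)
        if rank < z.shape[1]:
            raise np.linalg.LinAlgError(f"rank-deficient design in fold {i}")
        preds[i] = np.concatenate([[1.0], xz[i, order_i]]) @ beta
    return preds


def permutation_pvalue(x_selected, y, n_perm: int = 10000, seed=None) -> float:
    """Permutation p for the LOO-CV correlation with features held fixed.

    The score vector is shuffled ``n_perm`` times; each permutation
    re-runs the complete LOO-CV with the same (fixed) features and the
    add-one estimator ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``
    keeps p strictly positive.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    x = np.asarray(x_selected, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r_obs = _pearson(y, _loo_hat_predict(x, y))
    perms = np.empty((y.shape[0], n_perm))
    for b in range(n_perm):
        perms[:, b] = rng.permutation(y)
    preds = _loo_hat_predict(x, perms)
    pc = preds - preds.mean(axis=0)
    yc = perms - perms.mean(axis=0)
    denom = np.sqrt((pc * pc).sum(axis=0) * (yc * yc).sum(axis=0))
    denom[denom == 0] = np.inf
    r_perm = (pc * yc).sum(axis=0) / denom
    return float((1 + np.sum(r_perm >= r_obs)) / (n_perm + 1))


def system_weights(weights: pd.Series, selected, atlas: pd.Series) -> pd.DataFrame:
    """Mean model weight per system over the *selected* regions.

    Systems containing no selected region report a weight of 0 and are
    flagged via ``n_selected == 0`` / ``empty == True``.
    """
    sel = pd.Index(selected)
    missing = sel.difference(atlas.index)
    if len(missing):
        raise ValueError(f"selected regions missing from atlas: {list(missing)}")
    systems = sorted(atlas.unique())
    out = pd.DataFrame(
        {"mean_weight": 0.0, "n_selected": 0, "empty": True},
        index=pd.Index(systems, name="system_name"),
    )
    if len(sel):
        grouped = weights.loc[sel].groupby(atlas.loc[sel].values)
        mw = grouped.mean()
        ns = grouped.size()
        out.loc[mw.index, "mean_weight"] = mw.values
        out.loc[ns.index, "n_selected"] = ns.values
        out["empty"] = out["n_selected"] == 0
    return out


def graph_baselines(fc, atlas: pd.Series) -> pd.DataFrame:
    """Weighted degree and participation coefficient per region.

    Degree is the summed (nonnegative) edge weight of a region;
    participation coefficient ``PC_j = 1 − Σ_s (κ_js / κ_j)²`` measures
    how evenly that weight spreads over the seven systems (0 when all
    weight stays within one system, up to 6/7 for a perfectly even
    spread). Isolated regions (κ_j = 0) get PC = 0.
    """
    if isinstance(fc, pd.DataFrame):
        region_ids = fc.index
        c = fc.to_numpy(dtype=float).copy()
    else:
        c = np.asarray(fc, dtype=float).copy()
        region_ids = pd.Index([str(j) for j in range(c.shape[0])])
    np.fill_diagonal(c, 0.0)
    degree = c.sum(axis=1)
    systems = atlas.reindex(region_ids)
    if systems.isna().any():
        raise ValueError("some regions are missing from the atlas mapping")
    sys_labels = sorted(systems.unique())
    kappa = np.zeros((c.shape[0], len(sys_labels)))
    for s_idx, s in enumerate(sys_labels):
        kappa[:, s_idx] = c[:, (systems == s).to_numpy()].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = kappa / degree[:, None]
    pc = 1.0 - np.nansum(frac**2, axis=1)
    pc[degree == 0] = 0.0
    return pd.DataFrame(
        {"degree": degree, "pc": pc},
        index=pd.Index(region_ids, name="region_id"),
    )


def common_score_pca(bd_scores, adhd_scores) -> tuple[np.ndarray, float]:
    """First principal component of standardized BD and ADHD scores.

    Both score vectors are z-scored, a 2-variable PCA is fit, and the
    first-component subject scores are returned with the sign fixed so
    the loading on the BD score is positive, together with the
    explained-variance fraction ((1+|ρ|)/2 for sample correlation ρ).
    """
    bd = np.asarray(bd_scores, dtype=float)
    adhd = np.asarray(adhd_scores, dtype=float)
    if bd.shape != adhd.shape:
        raise ValueError("score vectors must have equal length")
    if np.ptp(bd) == 0 or np.ptp(adhd) == 0:
        raise ValueError("constant score vector")
    m = np.column_stack([bd, adhd])
    m = (m - m.mean(axis=0)) / m.std(axis=0, ddof=0)
    pca = PCA(n_components=2)
    scores = pca.fit_transform(m)
    pc1 = scores[:, 0]
    if pca.components_[0, 0] < 0:
        pc1 = -pc1
    return pc1, float(pca.explained_variance_ratio_[0])


def cross_predict(x_selected, y_other, n_perm: int = 10000, seed=None):
    """Apply one model's fixed feature set to another task's scores.

    Returns (r, p_perm) of LOO-CV predictions of ``y_other`` from the
    already-selected (normalized) features of the source model.
    """
    x = np.asarray(x_selected, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y_other, dtype=float)
    pred = loo_cv_predict(x, y)
    r = _pearson(y, pred)
    p = permutation_pvalue(x, y, n_perm=n_perm, seed=seed)
    return float(r), p


def predict_scores(
    features: pd.DataFrame,
    y,
    atlas: pd.Series | None = None,
    n_perm: int = 10000,
    seed=None,
    max_k: int | None = None,
    nested: bool = False,
) -> PredictionResult:
    """Full prediction pipeline on a subjects x regions feature table."""
    result = best_k_search(features, y, max_k=max_k, nested=nested)
    xz = normalize_features(features.to_numpy(dtype=float))
    cols = [list(features.columns).index(f) for f in result.selected]
    result.p_perm = permutation_pvalue(xz[:, cols], np.asarray(y, dtype=float),
                                       n_perm=n_perm, seed=seed)
    if atlas is not None:
        result.system_means = system_weights(result.weights, result.selected,
                                             atlas)
    result.seed = seed
    return result
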