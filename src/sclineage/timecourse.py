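"""Supervised pseudotime and time-course differential expression.

Cells carry ordered day labels (0, 3, 6, 9).  Pseudotime is the linear score
of an L1-penalized cumulative-logit (proportional-odds) ordinal regression of
the day labels on standardized log-normalized expression — genes whose
expression moves monotonically with treatment time get the large weights, and
each cell's pseudotime is its weighted expression score.  Per gene and cell
group (dominant / neutral clones), expression ordered by pseudotime is
smoothed with a centered rolling median (window 51) and averaged into 50
equal-count pseudotime bins.  A gene's dominant and neutral 50-bin profiles
are then compared with a spline-basis F-test (shared-curve null against
group-offset + group x curve interaction), BH-adjusted across genes; up-
regulated driver genes (FDR < 5%, positive mean dominant-neutral difference)
are finally clustered (k-means, k = 4) into temporal response patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

N_BINS_DEFAULT = 50
WINDOW_DEFAULT = 51
SPLINE_DF = 3


# ---------------------------------------------------------------------------
# Ordinal pseudotime
# ---------------------------------------------------------------------------

@dataclass
class PseudotimeModel:
    """Fitted L1-penalized cumulative-logit pseudotime model.

    ``weights`` is one coefficient per gene (on standardized inputs);
    ``thresholds`` are the strictly increasing cut-points between adjacent
    ordinal labels.  ``pseudotime = weights . standardized expression``.
    """

    weights: pd.Series
    thresholds: np.ndarray
    lam: float
    mean_: np.ndarray
    scale_: np.ndarray
    label_order: np.ndarray
    heldout_accuracy: float

    def transform(self, norm: pd.DataFrame) -> pd.Series:
        """Pseudotime score per cell from a genes x cells normalized matrix."""
        X = norm.reindex(self.weights.index).to_numpy().T
        Z = (X - self.mean_) / self.scale_
        return pd.Series(Z @ self.weights.to_numpy(), index=norm.columns, name="pseudotime")

    def predict_label(self, norm: pd.DataFrame) -> pd.Series:
        """Predicted ordinal label per cell (threshold crossing count)."""
        s = self.transform(norm).to_numpy()
        codes = (s[:, None] > self.thresholds[None, :]).sum(axis=1)
        return pd.Series(self.label_order[codes], index=norm.columns, name="label")


def _ordinal_negloglik_grad(Z: np.ndarray, y: np.ndarray, w: np.ndarray,
                            theta: np.ndarray, n_levels: int):
    """Mean negative log-likelihood of the cumulative-logit model + gradients."""
    n = len(y)
    s = Z @ w
    # sigma(theta_k - s) with virtual boundaries 0 and 1
    upper = np.where(y < n_levels - 1,
                     _sigmoid(theta[np.minimum(y, n_levels - 2)] - s), 1.0)
    lower = np.where(y > 0, _sigmoid(theta[np.maximum(y - 1, 0)] - s), 0.0)
    prob = np.clip(upper - lower, 1e-12, 1.0)
    nll = -np.mean(np.log(prob))

    dA = np.where(y < n_levels - 1, upper * (1 - upper), 0.0)  # d upper / d theta_y
    dB = np.where(y > 0, lower * (1 - lower), 0.0)
    inv = 1.0 / prob
    # d nll / d s
    ds = (dA - dB) * inv / n
    grad_w = Z.T @ ds
    grad_theta = np.zeros(n_levels - 1)
    np.add.at(grad_theta, np.minimum(y, n_levels - 2), np.where(y < n_levels - 1, -dA * inv, 0.0))
    np.add.at(grad_theta, np.maximum(y - 1, 0), np.where(y > 0, dB * inv, 0.0))
    grad_theta /= n
    return nll, grad_w, grad_theta


def _sigmoid(x):
    return 0.5 * (1 + np.tanh(0.5 * x))


def _fit_penalized(Z: np.ndarray, y: np.ndarray, n_levels: int, lam: float,
                   max_iter: int = 400, tol: float = 1e-7):
    """Proximal-gradient fit: soft-thresholding on w, plain steps on theta."""
    n, d = Z.shape
    w = np.zeros(d)
    theta = stats.norm.ppf((np.arange(1, n_levels) / n_levels))  # spread starts
    step = 1.0
    obj_prev = np.inf
    for _ in range(max_iter):
        nll, gw, gt = _ordinal_negloglik_grad(Z, y, w, theta, n_levels)
        obj = nll + lam * np.abs(w).sum()
        # backtracking line search on the proximal step
        while True:
            w_new = _soft_threshold(w - step * gw, step * lam)
            theta_new = _project_increasing(theta - step * gt)
            nll_new, _, _ = _ordinal_negloglik_grad(Z, y, w_new, theta_new, n_levels)
            if nll_new <= nll + gw @ (w_new - w) + gt @ (theta_new - theta) \
                    + ((w_new - w) ** 2).sum() / (2 * step) \
                    + ((theta_new - theta) ** 2).sum() / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-10:
                break
        w, theta = w_new, theta_new
        obj_new = nll_new + lam * np.abs(w).sum()
        if abs(obj_prev - obj_new) < tol * max(1.0, abs(obj_prev)):
            break
        obj_prev = obj_new
        step = min(step * 2.0, 10.0)
    return w, theta


def _soft_threshold(v, t):
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _project_increasing(theta, eps=1e-4):
    out = theta.copy()
    for i in range(1, len(out)):
        out[i] = max(out[i], out[i - 1] + eps)
    return out


def fit_ordinal_pseudotime(norm: pd.DataFrame, day_labels: pd.Series,
                           lambdas=None, seed: int = 0,
                           holdout_frac: float = 0.2) -> PseudotimeModel:
    """Fit the supervised pseudotime model.

    ``norm`` is genes x cells log-normalized expression; ``day_labels`` maps
    each cell to its (ordered, numeric) sequencing day.  The L1 penalty is
    chosen on a stratified 20% held-out split by ordinal classification
    accuracy, then the model is refit on all cells.  The sign convention makes
    mean pseudotime non-decreasing in the day label.
    """
    day_labels = day_labels.reindex(norm.columns)
    if day_labels.isna().any():
        raise ValueError("every cell needs a day label")
    levels = np.sort(day_labels.unique())
    if len(levels) < 2:
        raise ValueError("need at least two ordered labels")
    y = np.searchsorted(levels, day_labels.to_numpy())
    counts = np.bincount(y)
    if counts.min() < 10:
        raise ValueError("each label needs at least 10 cells")

    X = norm.to_numpy().T  # cells x genes
    mean_ = X.mean(axis=0)
    scale_ = X.std(axis=0)
    scale_ = np.where(scale_ > 0, scale_, 1.0)
    Z = (X - mean_) / scale_
    n_levels = len(levels)

    if lambdas is None:
        lambdas = np.array([0.3, 0.1, 0.03, 0.01, 0.003])

    rng = np.random.default_rng(seed)
    holdout = np.zeros(len(y), dtype=bool)
    for k in range(n_levels):
        idx = np.flatnonzero(y == k)
        n_hold = max(1, int(round(holdout_frac * len(idx))))
        holdout[rng.choice(idx, size=n_hold, replace=False)] = True

    best = None
    for lam in lambdas:
        w, theta = _fit_penalized(Z[~holdout], y[~holdout], n_levels, lam)
        s = Z[holdout] @ w
        pred = (s[:, None] > theta[None, :]).sum(axis=1)
        acc = float(np.mean(pred == y[holdout]))
        if best is None or acc > best[0] + 1e-12:
            best = (acc, lam)
    acc, lam = best

    w, theta = _fit_penalized(Z, y, n_levels, lam)
    s = Z @ w
    if len(np.unique(s)) > 1 and stats.spearmanr(s, y).statistic < 0:
        w, theta, s = -w, -theta[::-1], -s

    return PseudotimeModel(
        weights=pd.Series(w, index=norm.index, name="weight"),
        thresholds=theta,
        lam=float(lam),
        mean_=mean_,
        scale_=scale_,
        label_order=levels,
        heldout_accuracy=acc,
    )


# ---------------------------------------------------------------------------
# Smoothing and binning
# ---------------------------------------------------------------------------

def smooth_and_bin(values: np.ndarray, window: int = WINDOW_DEFAULT,
                   n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Rolling-median smooth then equal-count bin a pseudotime-ordered series.

    The centered rolling median truncates its window symmetrically at the
    edges; the smoothed series is then split into ``n_bins`` equal-count bins
    (any remainder spread over the leading bins) and each bin is averaged.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} values, got {n}")
    smoothed = _rolling_median(values, window)
    return _equal_count_bin_means(smoothed, n_bins)


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    n = len(values)
    h = window // 2
    out = np.empty(n)
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(values, window)
        out[h:n - h] = np.median(sw, axis=1)
    for i in range(min(h, n)):
        half = min(h, i, n - 1 - i)
        out[i] = np.median(values[i - half:i + half + 1])
    for i in range(max(n - h, 0), n):
        half = min(h, i, n - 1 - i)
        out[i] = np.median(values[i - half:i + half + 1])
    if n < window:
        for i in range(n):
            half = min(h, i, n - 1 - i)
            out[i] = np.median(values[i - half:i + half + 1])
    return out


def _equal_count_bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    n = len(values)
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    edges = np.concatenate(([0], np.cumsum(sizes)))
    return np.array([values[edges[i]:edges[i + 1]].mean() for i in range(n_bins)])


def binned_profiles(norm: pd.DataFrame, pseudotime: pd.Series,
                    window: int = WINDOW_DEFAULT,
                    n_bins: int = N_BINS_DEFAULT) -> pd.DataFrame:
    """Per-gene 50-bin smoothed profiles for one cell group.

    ``norm`` is genes x cells; cells are ordered by ``pseudotime`` (ties keep
    input order) before smoothing/binning each gene.  Returns genes x n_bins.
    """
    order = pseudotime.reindex(norm.columns).to_numpy().argsort(kind="stable")
    X = norm.to_numpy()[:, order]
    prof = np.empty((X.shape[0], n_bins))
    for g in range(X.shape[0]):
        prof[g] = smooth_and_bin(X[g], window=window, n_bins=n_bins)
    return pd.DataFrame(prof, index=norm.index, columns=range(n_bins))


# ---------------------------------------------------------------------------
# Spline time-course test
# ---------------------------------------------------------------------------

def _spline_basis(x: np.ndarray, df: int = SPLINE_DF) -> np.ndarray:
    """Cubic B-spline basis with ``df`` columns (intercept excluded)."""
    lo, hi = float(x.min()), float(x.max())
    t = np.r_[[lo] * 4, np.linspace(lo, hi, df - 2)[1:-1] if df > 3 else [], [hi] * 4]
    B = interpolate.BSpline.design_matrix(x, t, 3, extrapolate=True).toarray()
    return B[:, 1:]  # drop one column: its span plus intercept = full basis


def spline_timecourse_test(dominant: pd.DataFrame, neutral: pd.DataFrame,
                           fdr_cut: float = 0.05) -> pd.DataFrame:
    """Spline-basis F-test of group differences between binned profiles.

    For each gene the 2 x n_bins stacked values are regressed on an intercept,
    a cubic B-spline basis of bin index (3 df), a group indicator and
    group x basis interactions; the group and interaction terms are tested
    jointly against the shared-curve null with an F-test.  BH across genes.
    ``up`` marks genes with FDR < ``fdr_cut`` and positive mean
    dominant-neutral difference.
    """
    if not dominant.index.equals(neutral.index):
        neutral = neutral.reindex(dominant.index)
    n_bins = dominant.shape[1]
    if neutral.shape[1] != n_bins:
        raise ValueError("profiles must have the same number of bins")

    t = np.arange(n_bins, dtype=float)
    B = _spline_basis(t)
    tt = np.concatenate([t, t])
    Bb = np.vstack([B, B])
    g = np.concatenate([np.ones(n_bins), np.zeros(n_bins)])
    X0 = np.column_stack([np.ones(2 * n_bins), Bb])
    X1 = np.column_stack([X0, g, g[:, None] * Bb])

    M0 = _residual_maker(X0)
    M1 = _residual_maker(X1)
    Y = np.hstack([dominant.to_numpy(), neutral.to_numpy()])  # genes x 2n

    rss0 = np.einsum("ij,ij->i", Y @ M0, Y)
    rss1 = np.einsum("ij,ij->i", Y @ M1, Y)
    q = X1.shape[1] - X0.shape[1]
    dfe = 2 * n_bins - X1.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / q) / np.maximum(rss1 / dfe, 1e-300)
    p = stats.f.sf(F, q, dfe)

    degenerate = Y.std(axis=1) < 1e-12
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)

    fdr = multipletests(p, method="fdr_bh")[1]
    mean_diff = (dominant.to_numpy() - neutral.to_numpy()).mean(axis=1)
    out = pd.DataFrame(
        {"F": F, "p": p, "fdr": fdr, "mean_diff": mean_diff}, index=dominant.index
    )
    out["up"] = (out["fdr"] < fdr_cut) & (out["mean_diff"] > 0)
    return out


def _residual_maker(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return np.eye(X.shape[0]) - Q @ Q.T


# ---------------------------------------------------------------------------
# Temporal pattern clustering
# ---------------------------------------------------------------------------

def cluster_temporal_patterns(profiles: pd.DataFrame, k: int = 4,
                              seed: int = 0) -> tuple[pd.Series, pd.DataFrame]:
    """k-means clustering of z-scored gene profiles into temporal patterns.

    Each gene's bin profile is z-scored (zero-variance profiles map to zeros)
    and clustered with k-means (25 restarts, fixed seed).  Returns per-gene
    labels and the cluster mean curves (k x n_bins).
    """
    if k > len(profiles):
        raise ValueError("k exceeds the number of genes")
    X = profiles.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, n_init=25, random_state=seed)
    labels = pd.Series(km.fit_predict(Z), index=profiles.index, name="cluster")
    centers = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
    return labels, centers
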