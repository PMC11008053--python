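"""Retrospective and prospective clone analyses.

Retrospective: cells of the untreated timepoint are labelled by the eventual
fate of their lineage (tolerant = detected in the terminal surviving
population, sensitive = depleted), and per-gene two-sided Wilcoxon rank-sum
tests on log-normalized expression define the marker panel at FDR < 0.05.

Prospective: per-timepoint lineage frequencies (cells of a lineage / cells
sequenced) feed a dominance call — a two-proportion z-test of first- versus
last-timepoint frequency, BH-adjusted, gated on a minimum frequency fold
change in the increasing direction.  Lineages passing are "dominant", the
rest "neutral".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sclineage.matrix import CountMatrix

LOG2FC_EPS = 1e-9


def label_cells(table: pd.DataFrame, tolerant_set) -> pd.Series:
    """Per-cell response class from the lineage assignment table.

    A cell is ``tolerant`` iff its assigned lineage is in ``tolerant_set``,
    else ``sensitive``.  Ambiguously assigned cells are excluded from the
    returned series.
    """
    tolerant_set = set(tolerant_set)
    if not tolerant_set:
        raise ValueError("tolerant_set is empty")
    unambiguous = table.loc[~table["ambiguous"].astype(bool)]
    labels = unambiguous["lineage"].isin(tolerant_set).map(
        {True: "tolerant", False: "sensitive"}
    )
    labels.name = "response"
    return labels


def lognormalize(m: CountMatrix, scale: float = 10_000.0) -> pd.DataFrame:
    """ln(1 + scale * count / cell_total), genes x cells."""
    total = m.total_umi().astype(float)
    if (total == 0).any():
        raise ValueError("zero-total cell; filter cells before normalizing")
    x = np.log1p(scale * m.counts / total[None, :])
    return pd.DataFrame(x, index=m.gene_ids, columns=m.cell_ids)


def rank_sum_markers(norm: pd.DataFrame, labels: pd.Series,
                     fdr_cut: float = 0.05) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum marker test per gene, tolerant vs sensitive.

    Uses the normal approximation with tie correction, switching to exact
    enumeration when both groups have <= 10 cells (and no ties).  The log2
    fold change is computed on de-transformed means, log2((mu_t + eps) /
    (mu_s + eps)) with mu the mean of expm1(normalized value).  BH adjustment
    across genes; the marker panel is FDR < ``fdr_cut``, split by sign.
    """
    labels = labels.reindex(norm.columns).dropna()
    tol = labels.index[labels == "tolerant"]
    sen = labels.index[labels == "sensitive"]
    if len(tol) == 0 or len(sen) == 0:
        raise ValueError("both classes must be non-empty")

    xt = norm[tol].to_numpy()
    xs = norm[sen].to_numpy()

    if len(tol) <= 10 and len(sen) <= 10:
        pvals = np.empty(norm.shape[0])
        for g in range(norm.shape[0]):
            a, b = xt[g], xs[g]
            method = "exact" if len(np.unique(np.concatenate([a, b]))) == len(a) + len(b) else "asymptotic"
            pvals[g] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    else:
        pvals = stats.mannwhitneyu(xt, xs, alternative="two-sided",
                                   method="asymptotic", axis=1).pvalue

    mu_t = np.expm1(xt).mean(axis=1)
    mu_s = np.expm1(xs).mean(axis=1)
    log2fc = np.log2((mu_t + LOG2FC_EPS) / (mu_s + LOG2FC_EPS))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "pct_tolerant": (xt > 0).mean(axis=1),
            "pct_sensitive": (xs > 0).mean(axis=1),
        },
        index=norm.index,
    )
    out["marker"] = out["fdr"] < fdr_cut
    return out


def marker_panel(markers: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """Split the significant markers into (up-in-tolerant, up-in-sensitive)."""
    sig = markers[markers["marker"]]
    return sig.index[sig["log2fc"] > 0], sig.index[sig["log2fc"] < 0]


def clone_frequencies(cells: pd.DataFrame) -> pd.DataFrame:
    """Lineage x timepoint frequency table from a per-cell table.

    ``cells`` needs ``lineage`` and ``timepoint`` columns; the frequency of a
    lineage at a timepoint is its cell count divided by all cells sequenced at
    that timepoint (so columns sum to <= 1 only when some cells are dropped
    upstream; here, over the cells given, they sum to 1).
    """
    if cells.empty:
        raise ValueError("empty cell table")
    counts = cells.groupby(["lineage", "timepoint"]).size().unstack(fill_value=0)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("timepoint with zero cells")
    freq = counts / totals
    freq.columns = [f"d{t}" for t in freq.columns]
    return freq


def classify_dominant(freq: pd.DataFrame, n_per_timepoint: pd.Series | np.ndarray,
                      fdr_cut: float = 0.05, min_fc: float = 5.0) -> pd.DataFrame:
    """Call dominant vs neutral lineages from first/last timepoint frequencies.

    Per lineage, a two-proportion z-test compares the frequency at the first
    and last timepoints; a lineage is dominant iff the BH-adjusted p-value is
    below ``fdr_cut``, the frequency fold change is at least ``min_fc`` and
    the direction is increasing.  Lineages unobserved at both endpoints are
    neutral by definition.
    """
    if freq.shape[1] < 2:
        raise ValueError("need at least two timepoints")
    n = np.asarray(n_per_timepoint, dtype=float)
    n0, n1 = n[0], n[-1]
    f0 = freq.iloc[:, 0].to_numpy()
    f1 = freq.iloc[:, -1].to_numpy()
    k0 = np.round(f0 * n0)
    k1 = np.round(f1 * n1)

    # pooled two-proportion z-test, two-sided
    pooled = (k0 + k1) / (n0 + n1)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n0 + 1 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (f1 - f0) / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(f0 > 0, f1 / np.maximum(f0, 1e-300), np.where(f1 > 0, np.inf, 1.0))
    dominant = (fdr < fdr_cut) & (fc >= min_fc) & (f1 > f0) & ((k0 + k1) > 0)
    return pd.DataFrame(
        {
            "freq_first": f0,
            "freq_last": f1,
            "fold_change": fc,
            "p": p,
            "fdr": fdr,
            "dynamics": np.where(dominant, "dominant", "neutral"),
        },
        index=freq.index,
    )
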