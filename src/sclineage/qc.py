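"""Cell- and gene-level quality-control filters for droplet UMI matrices.

Cells with fewer than 5,000 UMIs are discarded outright.  High-mitochondrial
cells and putative doublets are removed by the same loess-deviation rule: a
loess fit of a per-cell ratio against log total UMI, robust z-scores of the
residuals, one-tailed normal p-values and Benjamini-Hochberg adjustment, with
cells flagged at FDR < 0.1.  For the mitochondrial filter the ratio is
mito-UMI / total-UMI (upper tail); for the doublet filter it is detected-genes
/ total-UMI (lower tail: doublets carry many UMIs spread over relatively few
extra genes).  Genes are dropped only when simultaneously rare in absolute
cell count, rare as a fraction of cells, and weakly expressed on average.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from sclineage.matrix import CountMatrix

MIN_UMI_DEFAULT = 5000
FDR_DEFAULT = 0.1
LOESS_SPAN = 0.75


def umi_filter(m: CountMatrix, min_umi: int = MIN_UMI_DEFAULT) -> np.ndarray:
    """Boolean mask of cells with at least ``min_umi`` total UMIs.

    Cells with *fewer* than the threshold are discarded; a cell exactly at the
    threshold is kept.
    """
    return m.total_umi() >= min_umi


def loess_outlier_filter(x: np.ndarray, y: np.ndarray, tail: str,
                         fdr_cut: float = FDR_DEFAULT,
                         span: float = LOESS_SPAN) -> np.ndarray:
    """Flag cells whose ratio ``y`` deviates from its loess trend on ``x``.

    A local-linear (loess) fit of ``y`` on ``x`` gives expected ratios; the
    residuals are converted to robust z-scores (median/MAD), a one-tailed
    normal p-value is taken in the requested ``tail`` ("upper" or "lower"),
    and Benjamini-Hochberg-adjusted p-values below ``fdr_cut`` are flagged.
    Returns a boolean mask of *flagged* (to-be-discarded) cells.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if len(x) != len(y):
        raise ValueError("x and y length mismatch")
    if len(x) < 20:
        raise ValueError("need at least 20 cells for a stable loess fit")

    fitted = _loess_fit(x, y, span)
    resid = y - fitted
    mad = stats.median_abs_deviation(resid)
    if mad <= 1e-10 * max(np.abs(y).max(), 1e-30):
        # Degenerate residual spread (e.g. constant ratios): nothing can be
        # called an outlier against a zero-width reference.
        warnings.warn("zero residual MAD in loess filter; no cells flagged")
        return np.zeros(len(y), dtype=bool)
    z = (resid - np.median(resid)) / (1.4826 * mad)
    p = stats.norm.sf(z) if tail == "upper" else stats.norm.cdf(z)
    fdr = multipletests(p, method="fdr_bh")[1]
    return fdr < fdr_cut


def cell_qc_report(m: CountMatrix, min_umi: int = MIN_UMI_DEFAULT,
                   fdr_cut: float = FDR_DEFAULT, span: float = LOESS_SPAN) -> pd.DataFrame:
    """Per-cell QC metrics and pass flags for every filter.

    The loess filters are evaluated on the cells passing the UMI filter (their
    trend should not be distorted by empty/shallow droplets); cells failing the
    UMI filter get ``pass_mito = pass_doublet = False`` FDRs of NaN.
    """
    total = m.total_umi().astype(float)
    detected = m.genes_detected().astype(float)
    mito = m.mito_ratio()
    with np.errstate(divide="ignore", invalid="ignore"):
        gene_ratio = np.where(total > 0, detected / np.maximum(total, 1e-300), 0.0)

    report = pd.DataFrame(
        {
            "total_umi": total.astype(int),
            "genes_detected": detected.astype(int),
            "mito_ratio": mito,
            "gene_umi_ratio": gene_ratio,
        },
        index=m.cell_ids,
    )
    report["pass_umi"] = total >= min_umi

    deep = report["pass_umi"].to_numpy()
    fdr_mito = np.full(len(report), np.nan)
    fdr_doublet = np.full(len(report), np.nan)
    pass_mito = np.zeros(len(report), dtype=bool)
    pass_doublet = np.zeros(len(report), dtype=bool)
    if deep.sum() >= 20:
        logx = np.log(total[deep])
        flag_m, fdr_m = _flag_with_fdr(logx, mito[deep], "upper", fdr_cut, span)
        flag_d, fdr_d = _flag_with_fdr(logx, gene_ratio[deep], "lower", fdr_cut, span)
        fdr_mito[deep] = fdr_m
        fdr_doublet[deep] = fdr_d
        pass_mito[deep] = ~flag_m
        pass_doublet[deep] = ~flag_d
    report["fdr_mito"] = fdr_mito
    report["fdr_doublet"] = fdr_doublet
    report["pass_mito"] = pass_mito
    report["pass_doublet"] = pass_doublet
    report["pass_all"] = report[["pass_umi", "pass_mito", "pass_doublet"]].all(axis=1)
    return report


def _loess_fit(x, y, span):
    """Loess fitted values; a constant-x input falls back to the flat fit."""
    if np.ptp(x) < 1e-12:
        return np.full(len(y), np.mean(y))
    return lowess(y, x, frac=span, return_sorted=False)


def _flag_with_fdr(x, y, tail, fdr_cut, span):
    """loess_outlier_filter variant that also returns the per-cell FDR."""
    fitted = _loess_fit(x, y, span)
    resid = y - fitted
    mad = stats.median_abs_deviation(resid)
    if mad <= 1e-10 * max(np.abs(y).max(), 1e-30):
        return np.zeros(len(y), dtype=bool), np.ones(len(y))
    z = (resid - np.median(resid)) / (1.4826 * mad)
    p = stats.norm.sf(z) if tail == "upper" else stats.norm.cdf(z)
    fdr = multipletests(p, method="fdr_bh")[1]
    return fdr < fdr_cut, fdr


def mito_filter(m: CountMatrix, fdr_cut: float = FDR_DEFAULT,
                span: float = LOESS_SPAN) -> np.ndarray:
    """Boolean mask of cells *kept* by the mitochondrial-fraction filter."""
    total = m.total_umi().astype(float)
    ratio = m.mito_ratio()
    if not m.mito_mask.any() or np.all(ratio == 0):
        return np.ones(m.n_cells, dtype=bool)
    flagged = loess_outlier_filter(np.log(np.maximum(total, 1.0)), ratio,
                                   tail="upper", fdr_cut=fdr_cut, span=span)
    return ~flagged


def doublet_filter(m: CountMatrix, fdr_cut: float = FDR_DEFAULT,
                   span: float = LOESS_SPAN) -> np.ndarray:
    """Boolean mask of cells *kept* by the detected-genes/UMI doublet filter."""
    total = m.total_umi().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, m.genes_detected() / np.maximum(total, 1e-300), 0.0)
    flagged = loess_outlier_filter(np.log(np.maximum(total, 1.0)), ratio,
                                   tail="lower", fdr_cut=fdr_cut, span=span)
    return ~flagged


def gene_filter(m: CountMatrix, min_cells: int = 50, min_frac: float = 0.05,
                min_mean: float = 1.12) -> np.ndarray:
    """Boolean mask of genes kept.

    A gene is excluded only when *all three* hold: expressed in fewer than
    ``min_cells`` cells, expressed in less than ``min_frac`` of cells, and
    mean expression over all cells below ``min_mean`` UMIs.
    """
    expressing = (m.counts > 0).sum(axis=1)
    frac = expressing / m.n_cells
    mean = m.counts.mean(axis=1)
    exclude = (expressing < min_cells) & (frac < min_frac) & (mean < min_mean)
    return ~exclude


def run_qc(m: CountMatrix, min_umi: int = MIN_UMI_DEFAULT,
           fdr_cut: float = FDR_DEFAULT) -> tuple[CountMatrix, pd.DataFrame]:
    """Full QC pipeline: UMI -> mito -> doublet -> gene filters, in that order.

    Each loess filter is re-fit on the cells surviving the previous step.
    Returns the filtered matrix and the per-cell QC report of the input.
    """
    report = cell_qc_report(m, min_umi=min_umi, fdr_cut=fdr_cut)
    kept = m.subset_cells(umi_filter(m, min_umi))
    if kept.n_cells >= 20:
        kept = kept.subset_cells(mito_filter(kept, fdr_cut=fdr_cut))
    if kept.n_cells >= 20:
        kept = kept.subset_cells(doublet_filter(kept, fdr_cut=fdr_cut))
    kept = kept.subset_genes(gene_filter(kept))
    return kept, report
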