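"""Cell quality control, normalisation and highly-variable-gene selection.

The filtering rules mirror standard droplet scRNA-seq practice: a hard
minimum-UMI threshold for cell calling, and an adaptive mitochondrial-
fraction outlier rule in which fractions are modelled as normal with the
cohort median as centre and a MAD-derived spread; cells in the far upper
tail (BH-adjusted p < 0.05) are discarded.  The per-dataset percentage
cutoffs this produces are outputs of the rule, recomputed on every
dataset rather than fixed constants.

Size factors come either from plain library size or from a pooling/
deconvolution scheme: cells are arranged on a ring ordered by library
size, overlapping pools of several sizes are summed, each pool total is
compared against an average pseudo-cell, and the per-cell factors are
recovered from the resulting sparse linear system by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from ._utils import as_dense, bh_adjust


@dataclass
class QCReport:
    table: pd.DataFrame  # per-cell: cell, total_umi, mito_frac, pval, padj, keep, reason


@dataclass
class SizeFactors:
    values: np.ndarray
    method: str


def _totals(counts) -> np.ndarray:
    return np.asarray(sp.csr_matrix(counts).sum(axis=0)).ravel().astype(float)


def filter_min_umi(counts, cells: pd.DataFrame, min_umi: int = 5000):
    """Keep cells with total UMI >= min_umi (the threshold is inclusive).

    Returns ``(counts, cells, QCReport)`` restricted to passing cells.
    """
    counts = sp.csr_matrix(counts)
    if counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    totals = _totals(counts)
    keep = totals >= min_umi
    report = QCReport(
        pd.DataFrame(
            {
                "cell": cells["cell"].to_numpy(),
                "total_umi": totals.astype(int),
                "keep": keep,
                "reason": np.where(keep, "", "low_umi"),
            }
        )
    )
    if not keep.any():
        raise ValueError(
            f"no cell reaches the minimum UMI threshold of {min_umi}"
        )
    genes = cells.attrs.get("genes")
    out_cells = cells.loc[keep].reset_index(drop=True)
    if genes is not None:
        out_cells.attrs["genes"] = genes
    return counts[:, keep], out_cells, report


def mito_fractions(counts, gene_names) -> np.ndarray:
    counts = sp.csr_matrix(counts)
    mito = np.array([str(g).startswith("mt-") for g in gene_names])
    totals = _totals(counts)
    if np.any(totals == 0):
        raise ValueError("zero-total cell present; apply the UMI filter first")
    mito_counts = np.asarray(counts[mito].sum(axis=0)).ravel()
    return mito_counts / totals


def flag_mito_outliers(
    counts, gene_names, alpha: float = 0.05, cells: pd.DataFrame | None = None
) -> QCReport:
    """Flag cells whose mitochondrial fraction sits in the upper outlier tail.

    Fractions are referred to a normal distribution centred on their
    median with SD = 1.4826 x MAD; the one-sided upper-tail p-values are
    BH-corrected across cells and cells with adjusted p < ``alpha`` fail.
    A zero MAD (no dispersion) flags nothing.
    """
    frac = mito_fractions(counts, gene_names)
    n = frac.size
    ids = (
        cells["cell"].to_numpy()
        if cells is not None
        else np.array([f"cell{i}" for i in range(n)])
    )
    med = float(np.median(frac))
    mad = float(np.median(np.abs(frac - med)))
    sd = 1.4826 * mad
    if n < 2 or sd == 0.0:
        if sd == 0.0 and n >= 2:
            warnings.warn("MAD of mitochondrial fractions is zero; nothing flagged")
        pval = np.ones(n)
    else:
        pval = stats.norm.sf(frac, loc=med, scale=sd)
    padj = bh_adjust(pval)
    fail = padj < alpha if (n >= 2 and sd > 0.0) else np.zeros(n, bool)
    return QCReport(
        pd.DataFrame(
            {
                "cell": ids,
                "mito_frac": frac,
                "pval": pval,
                "padj": padj,
                "keep": ~fail,
                "reason": np.where(fail, "high_mito", ""),
            }
        )
    )


def _pool_sizes(n: int) -> list:
    sizes = [s for s in range(21, 102, 5) if s <= max(n // 2, 1)]
    return sizes or [min(5, n)]


def estimate_size_factors(counts, method: str = "pooled_deconvolution") -> SizeFactors:
    """Per-cell size factors, rescaled to mean 1.

    ``library_size``: proportional to total UMI.  ``pooled_deconvolution``:
    ring-ordered pools of sizes 21, 26, ..., 101 summed and compared to
    the average pseudo-cell; the pool equations are solved for the
    per-cell factors by least squares.  Non-positive solutions are
    clipped to 1/100 of the smallest positive factor with a warning.
    """
    counts = sp.csc_matrix(counts, dtype=float)
    totals = _totals(counts)
    if np.any(totals <= 0):
        raise ValueError("every cell must have a positive total count")
    n = counts.shape[1]

    if method == "library_size":
        sf = totals / totals.mean()
        return SizeFactors(sf, method)
    if method != "pooled_deconvolution":
        raise ValueError(f"unknown size-factor method: {method}")

    if n < 10:  # pooling needs a ring of reasonable size
        return SizeFactors(totals / totals.mean(), "library_size")

    # ring order: alternate low/high library sizes for balanced pools
    order = np.argsort(totals)
    ring = np.empty(n, dtype=int)
    ring[0::2] = order[: (n + 1) // 2]
    ring[1::2] = order[(n + 1) // 2 :][::-1]

    pseudo = np.asarray(counts.mean(axis=1)).ravel()
    expressed = pseudo > 0
    Xr = as_dense(counts)[:, ring]
    # cumulative sums over the doubled ring give every wrapped pool sum
    cum = np.concatenate(
        [np.zeros((Xr.shape[0], 1)), np.cumsum(np.hstack([Xr, Xr]), axis=1)],
        axis=1,
    )

    row_blocks, col_blocks, b_blocks = [], [], []
    starts = np.arange(n)
    row_offset = 0
    for size in _pool_sizes(n):
        psum = cum[:, starts + size] - cum[:, starts]  # genes x n pools
        theta = np.median(
            psum[expressed] / pseudo[expressed, None], axis=0
        )
        cols = (starts[:, None] + np.arange(size)[None, :]) % n
        rows = np.repeat(np.arange(n) + row_offset, size)
        row_blocks.append(rows)
        col_blocks.append(cols.ravel())
        b_blocks.append(theta)
        row_offset += n
    # low-weight anchor to the library-size solution keeps the system full rank
    w = 0.01
    lib = totals[ring] / pseudo.sum()
    row_blocks.append(np.arange(n) + row_offset)
    col_blocks.append(np.arange(n))
    b_blocks.append(w * lib)
    n_rows = row_offset + n
    data = np.ones(sum(len(r) for r in row_blocks))
    data[-n:] = w
    A = sp.csr_matrix(
        (data, (np.concatenate(row_blocks), np.concatenate(col_blocks))),
        shape=(n_rows, n),
    )
    sol = spla.lsqr(A, np.concatenate(b_blocks), atol=1e-10, btol=1e-10)[0]

    sf = np.empty(n)
    sf[ring] = sol
    if np.any(sf <= 0):
        pos = sf[sf > 0]
        floor = (pos.min() if pos.size else 1.0) * 1e-2
        warnings.warn(
            f"{int((sf <= 0).sum())} non-positive deconvolved factors clipped"
        )
        sf[sf <= 0] = floor
    sf = sf / sf.mean()
    return SizeFactors(sf, method)


def lognormalize(counts, sf: SizeFactors) -> np.ndarray:
    """log2(count / size factor + 1); returns a dense genes x cells array."""
    counts = sp.csr_matrix(counts, dtype=float)
    values = np.asarray(sf.values, dtype=float)
    if values.size != counts.shape[1]:
        raise ValueError("size-factor length does not match cell count")
    if np.any(values <= 0):
        raise ValueError("size factors must be positive")
    mat = as_dense(counts) / values[None, :]
    return np.log2(mat + 1.0)


def _lowess_trend(mean: np.ndarray, var: np.ndarray, span: float) -> np.ndarray:
    """Non-negative local-regression fit of variance against mean."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n = mean.size
    frac = max(span, min(1.0, 30.0 / max(n, 1)))
    fit = lowess(var, mean, frac=frac, it=3, return_sorted=False)
    return np.clip(fit, 1e-12, None)


def select_hvgs(
    expr: np.ndarray,
    gene_names,
    span: float = 0.05,
    alpha: float = 0.05,
    mean_cutoff: float = 1e-3,
    excluded_names=("Xist", "tdTomato"),
    chrY_genes=(),
) -> pd.DataFrame:
    """Highly-variable genes: variance significantly above the mean trend.

    A local-regression trend of per-gene variance against mean (of the
    log2-normalised values) estimates the technical component; each gene
    with mean above ``mean_cutoff`` is tested one-sided for total
    variance exceeding the trend via the chi-squared approximation to
    the scaled variance ratio, and selection applies BH-adjusted
    p < ``alpha``.  Sex-linked and reporter genes (Y chromosome, Xist,
    tdTomato) are excluded regardless of variance.
    """
    expr = np.asarray(expr, dtype=float)
    genes = np.asarray(list(gene_names), dtype=object)
    if expr.shape[0] != genes.size:
        raise ValueError("expression row count does not match gene names")
    n_cells = expr.shape[1]
    mean = expr.mean(axis=1)
    var = expr.var(axis=1, ddof=1) if n_cells > 1 else np.zeros_like(mean)

    excluded = np.isin(genes, np.asarray(list(excluded_names) + list(chrY_genes)))
    low = mean < mean_cutoff
    testable = ~low
    if testable.sum() < 50:
        raise ValueError("too few expressed genes to fit a variance trend")

    trend = np.full(genes.size, np.nan)
    trend[testable] = _lowess_trend(mean[testable], var[testable], span)

    pval = np.full(genes.size, np.nan)
    df = n_cells - 1
    ratio = var[testable] / trend[testable]
    pval[testable] = stats.chi2.sf(ratio * df, df)
    padj = bh_adjust(pval)
    bio = var - trend

    selected = (padj < alpha) & testable & ~excluded
    reason = np.where(excluded, "excluded", np.where(low, "low_mean", ""))
    return pd.DataFrame(
        {
            "gene": genes,
            "mean": mean,
            "total_var": var,
            "trend_var": trend,
            "bio_var": bio,
            "pval": pval,
            "padj": padj,
            "selected": selected,
            "reason": reason,
        }
    )
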