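"""Expression dynamics along trajectories and divergence statistics.

Per-trajectory gene dynamics are summarised as the mean log2-normalised
expression at each time point of the cells allocated to that
trajectory.  Two nested-polynomial F-tests operate on those per-time-
point means: a *variability* screen comparing a cubic polynomial in the
(centred) stage index against an intercept-only model within one
trajectory, and a *pairwise divergence* test on the pooled points of two
trajectories comparing a shared cubic against a cubic with trajectory-
specific coefficients for every term.  Both are corrected across genes
by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust
from .transport import TrajectoryAssignment


@dataclass
class TrajectoryCurves:
    fates: list
    stages: list  # ordered stage indices
    genes: np.ndarray
    values: dict  # fate -> genes x stages array of means (NaN where no cells)
    cell_counts: dict  # fate -> stage count vector


def trajectory_mean_curves(
    expr: np.ndarray,
    gene_names,
    cells: pd.DataFrame,
    assignment: TrajectoryAssignment,
) -> TrajectoryCurves:
    """Mean expression per (trajectory, time point).

    Cells allocated to several trajectories contribute to each of their
    curves.  Trajectories with no cells at any time point are dropped
    with a warning.
    """
    genes = np.asarray(list(gene_names), dtype=object)
    expr = np.asarray(expr, dtype=float)
    tab = assignment.table
    fates = [f for f in tab.columns if f not in ("cell", "stage_index", "assigned_fates")]
    stages = sorted(tab["stage_index"].unique())
    pos = {c: i for i, c in enumerate(cells["cell"])}

    values: dict = {}
    counts: dict = {}
    for fate in fates:
        mat = np.full((genes.size, len(stages)), np.nan)
        nvec = np.zeros(len(stages), dtype=int)
        has = tab["assigned_fates"].str.split(";").apply(lambda s: fate in s)
        for si, stage in enumerate(stages):
            sel = tab.loc[has & (tab["stage_index"] == stage), "cell"]
            idx = [pos[c] for c in sel if c in pos]
            nvec[si] = len(idx)
            if idx:
                mat[:, si] = expr[:, idx].mean(axis=1)
        if nvec.sum() == 0:
            warnings.warn(f"trajectory {fate!r} has no assigned cells; dropped")
            continue
        values[fate] = mat
        counts[fate] = nvec
    return TrajectoryCurves(
        fates=list(values), stages=stages, genes=genes, values=values, cell_counts=counts
    )


def _cubic_design(stage_idx: np.ndarray) -> np.ndarray:
    t = stage_idx - stage_idx.mean()
    return np.column_stack([np.ones_like(t), t, t**2, t**3])


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares per row of Y for the design X (via projection)."""
    Q, _ = np.linalg.qr(X)
    resid = Y - (Y @ Q) @ Q.T
    return (resid**2).sum(axis=1)


def _nested_f(Y, X0, X1):
    """Row-wise F-test of nested linear models (X0 within X1)."""
    n = Y.shape[1]
    p0 = np.linalg.matrix_rank(X0)
    p1 = np.linalg.matrix_rank(X1)
    df1 = p1 - p0
    df2 = n - p1
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degenerate model comparison: check time-point support")
    rss0 = _rss(Y, X0)
    rss1 = _rss(Y, X1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    pvals = np.where(
        rss1 <= 1e-300,
        np.where(rss0 - rss1 <= 1e-300, 1.0, 0.0),  # saturated: flat -> p=1
        stats.f.sf(np.clip(F, 0, None), df1, df2),
    )
    F = np.where(np.isfinite(F), F, np.inf)
    return F, pvals, df1, df2


def test_variability_along(
    curves: TrajectoryCurves, fate: str, genes=None, alpha: float = 0.1
) -> pd.DataFrame:
    """Screen for genes whose trajectory curve varies with time.

    Cubic-vs-intercept F-test on the per-time-point means of one
    trajectory; selection at BH-adjusted p < ``alpha``.
    """
    if fate not in curves.values:
        raise ValueError(f"no curve for trajectory {fate!r}")
    mat = curves.values[fate]
    stages = np.asarray(curves.stages, dtype=float)
    ok = ~np.isnan(mat[0])
    if ok.sum() < 6:
        raise ValueError("need >= 6 time points with cells for the cubic fit")
    Y = mat[:, ok]
    t = stages[ok]
    X1 = _cubic_design(t)
    X0 = X1[:, :1]
    F, p, df1, df2 = _nested_f(Y, X0, X1)

    mask = np.ones(curves.genes.size, dtype=bool)
    if genes is not None:
        mask = np.isin(curves.genes, np.asarray(list(genes), dtype=object))
    pv = np.where(mask, p, np.nan)
    padj = bh_adjust(pv)
    return pd.DataFrame(
        {
            "gene": curves.genes,
            "fate": fate,
            "F": F,
            "df1": df1,
            "df2": df2,
            "pval": pv,
            "padj": padj,
            "selected": (padj < alpha) & mask,
            "test": "variability",
        }
    )


def variable_genes_union(curves: TrajectoryCurves, genes=None, alpha: float = 0.1):
    """Union over trajectories of the variability-screen selections."""
    selected: set = set()
    for fate in curves.fates:
        res = test_variability_along(curves, fate, genes=genes, alpha=alpha)
        selected |= set(res.loc[res["selected"], "gene"])
    return sorted(selected)


def test_pairwise_divergence(
    curves: TrajectoryCurves,
    fate_pair,
    genes=None,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Divergence of two trajectories' expression dynamics.

    The per-time-point means of both trajectories are pooled; a shared
    cubic (null) is compared against a cubic with trajectory-specific
    coefficients for all four terms (alternative) by F-test, BH-adjusted
    across genes.  Genes whose curves are numerically identical carry
    p = 1 (no evidence of difference).
    """
    fa, fb = fate_pair
    for f in (fa, fb):
        if f not in curves.values:
            raise ValueError(f"no curve for trajectory {f!r}")
    ma, mb = curves.values[fa], curves.values[fb]
    stages = np.asarray(curves.stages, dtype=float)
    ok = ~np.isnan(ma[0]) & ~np.isnan(mb[0])
    if ok.sum() < 6:
        raise ValueError("need >= 6 shared time points for the divergence test")
    t = stages[ok]
    Y = np.hstack([ma[:, ok], mb[:, ok]])
    base = _cubic_design(np.concatenate([t, t]))
    grp = np.concatenate([np.zeros(ok.sum()), np.ones(ok.sum())])
    X0 = base
    X1 = np.hstack([base, base * grp[:, None]])
    F, p, df1, df2 = _nested_f(Y, X0, X1)
    same = np.all(np.isclose(ma[:, ok], mb[:, ok], atol=1e-12), axis=1)
    if same.any():
        p = np.where(same, 1.0, p)

    mask = np.ones(curves.genes.size, dtype=bool)
    if genes is not None:
        mask = np.isin(curves.genes, np.asarray(list(genes), dtype=object))
    pv = np.where(mask, p, np.nan)
    padj = bh_adjust(pv)
    return pd.DataFrame(
        {
            "gene": curves.genes,
            "pair": f"{fa}|{fb}",
            "F": F,
            "df1": df1,
            "df2": df2,
            "pval": pv,
            "padj": padj,
            "selected": (padj < fdr) & mask,
            "test": "pairwise",
        }
    )


def differential_expression(
    expr: np.ndarray,
    gene_names,
    group_a,
    group_b,
    covariate: np.ndarray | None = None,
    lfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """Two-group differential expression on log2-normalised values.

    Default mode: per-gene Welch t-test with BH correction; log2FC is
    the mean difference (group A minus group B).  Covariate mode (e.g.
    centred DPT as a nuisance regressor): per-gene OLS of expression on
    group and covariate, with the group coefficient tested against the
    shifted null |coef| <= ``lfc_threshold`` (the tail beyond the
    threshold on the observed side, doubled and capped at 1).
    """
    expr = np.asarray(expr, dtype=float)
    genes = np.asarray(list(gene_names), dtype=object)
    ga = np.asarray(group_a)
    gb = np.asarray(group_b)
    if ga.size < 2 or gb.size < 2:
        raise ValueError("both groups need at least two cells")
    A, B = expr[:, ga], expr[:, gb]
    lfc = A.mean(axis=1) - B.mean(axis=1)

    if covariate is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tstat, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        # degenerate genes: no variance anywhere
        degen = np.isnan(p)
        p = np.where(degen, np.where(np.abs(lfc) > 0, 0.0, 1.0), p)
    else:
        cov = np.asarray(covariate, dtype=float)
        idx = np.concatenate([ga, gb])
        y = expr[:, idx]
        g = np.concatenate([np.ones(ga.size), np.zeros(gb.size)])
        c = cov[idx]
        c = c - c.mean()
        X = np.column_stack([np.ones(idx.size), g, c])
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = y @ X @ XtX_inv.T  # genes x 3
        resid = y - beta @ X.T
        df = idx.size - np.linalg.matrix_rank(X)
        s2 = (resid**2).sum(axis=1) / df
        se = np.sqrt(np.clip(s2 * XtX_inv[1, 1], 1e-300, None))
        b = beta[:, 1]
        lfc = b
        t_hi = (b - lfc_threshold) / se
        t_lo = (b + lfc_threshold) / se
        p = np.minimum(
            1.0, 2.0 * np.minimum(stats.t.sf(t_hi, df), stats.t.cdf(t_lo, df))
        )
    return pd.DataFrame(
        {"gene": genes, "log2fc": lfc, "pval": p, "padj": bh_adjust(p)}
    )


def signature_score(expr: np.ndarray, gene_names, gene_set) -> np.ndarray:
    """Per-cell mean z-score over a gene set.

    Each gene is z-scored across cells; zero-variance genes contribute
    z = 0 with a warning.  The score is the mean over the genes of the
    set that are present in the matrix.
    """
    genes = np.asarray(list(gene_names), dtype=object)
    members = np.isin(genes, np.asarray(list(gene_set), dtype=object))
    if not members.any():
        raise ValueError("gene set shares no genes with the expression matrix")
    sub = np.asarray(expr, dtype=float)[members]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance genes score 0 in signature")
    z = np.where(sd > 0, (sub - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return z.mean(axis=0)


def overlap_enrichment(hits, reference, universe):
    """One-sided Fisher (hypergeometric upper tail) gene-set overlap test.

    Returns ``(k, n_hits, p)``: the overlap size, the number of hits,
    and the probability of an overlap at least that large under random
    draws from the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    h = set(hits) & uni
    r = set(reference) & uni
    k = len(h & r)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(r), len(h)))
    return k, len(h), p
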