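"""Mapping chimera cells onto the atlas and chimera fate-bias statistics.

Chimera samples are mapped one at a time onto the batch-corrected atlas
in the shared PC space (each sample independently, so no mapped cell can
influence another sample's mapping); the 10 nearest atlas cells of every
chimera cell supply its transferred cell type, stage and trajectory by
majority vote (ties to the nearest tied neighbour), and the mean over
the 5 nearest supplies its diffusion-pseudotime position.

Downstream statistics: per-cell-type differential abundance between the
injected compartments of knockout and wild-type chimeras (negative-
binomial log-linear model with replicate-pool intercepts and a factor
per injected genotype, testing the KO-injected minus WT-injected
contrast), the relative lineage-contribution ratio with its label-
permutation test, and two-sample Kolmogorov-Smirnov comparison of
pseudotime distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from ._utils import bh_adjust
from .manifold import Embedding, mnn_shift

EXCLUDED_LABELS = ("doublet", "stripped_nucleus")


@dataclass
class MappingResult:
    cell_ids: np.ndarray  # chimera cells
    atlas_ids: np.ndarray  # atlas cells (columns of neighbour arrays refer here)
    neighbor_idx: np.ndarray  # chimera cells x 10, ascending distance
    neighbor_dist: np.ndarray
    mapped_coords: np.ndarray
    table: pd.DataFrame | None = None  # transferred labels etc.


def subsample_atlas(
    cells: pd.DataFrame, n_per_stage: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """Per-stage random subsample of the atlas cell table.

    Stages at or below ``n_per_stage`` cells are kept whole; larger
    stages are sampled without replacement.  Sampling is seeded and
    row order within a stage is preserved.
    """
    if "timepoint" not in cells:
        raise ValueError("cell table lacks 'timepoint'")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(cells), dtype=bool)
    for _, idx in cells.groupby("timepoint").indices.items():
        if idx.size <= n_per_stage:
            keep[idx] = True
        else:
            keep[rng.choice(idx, size=n_per_stage, replace=False)] = True
    out = cells.loc[keep].reset_index(drop=True)
    genes = cells.attrs.get("genes")
    if genes is not None:
        out.attrs["genes"] = genes
    return out


def map_to_atlas(
    atlas_embedding: Embedding,
    chimera_embedding: Embedding,
    chimera_samples,
    k_mnn: int = 20,
    sigma: float | None = None,
    n_neighbors: int = 10,
    max_rounds: int = 8,
) -> MappingResult:
    """MNN-map each chimera sample independently onto the corrected atlas.

    Both embeddings must live in the same (shared, corrected) PC space;
    use :func:`somitraj.manifold.project_onto` to place chimera cells
    into the atlas PC basis first.  Per chimera cell the ``n_neighbors``
    nearest atlas cells and distances are recorded.

    Unlike sequential atlas integration, mapping aligns each sample as a
    whole onto an already-corrected reference, so the default kernel is
    wide (bandwidth = RMS spread of the atlas, making each round close
    to a rigid translation) and match-shift rounds repeat until the
    sample sits on the reference.  This preserves within-sample
    structure while removing the sample's batch displacement.
    """
    samples = np.asarray(chimera_samples)
    coords = chimera_embedding.coords.copy()
    ref = atlas_embedding.coords
    if sigma is None:
        sigma = float(
            np.sqrt(np.mean(np.sum((ref - ref.mean(axis=0)) ** 2, axis=1)))
        )
    for s in np.unique(samples):
        mask = samples == s
        try:
            shift, _ = mnn_shift(
                ref, coords[mask], k=k_mnn, sigma=sigma, max_rounds=max_rounds
            )
        except RuntimeError:
            raise RuntimeError(f"no MNN pairs between atlas and sample {s!r}")
        coords[mask] += shift
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(ref)
    dist, idx = nn.kneighbors(coords)
    return MappingResult(
        cell_ids=np.asarray(chimera_embedding.cell_ids),
        atlas_ids=np.asarray(atlas_embedding.cell_ids),
        neighbor_idx=idx,
        neighbor_dist=dist,
        mapped_coords=coords,
    )


def _vote(labels: np.ndarray, dists: np.ndarray):
    """Majority label; ties broken by the nearest neighbour carrying a tied label."""
    uniq, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    tied = set(uniq[counts == top])
    if len(tied) == 1:
        return next(iter(tied))
    for lab in labels[np.argsort(dists, kind="stable")]:
        if lab in tied:
            return lab
    return labels[0]  # unreachable


def transfer_labels(
    mapping: MappingResult,
    atlas_labels: pd.DataFrame,
    k: int = 10,
    label_cols=("cell_type", "timepoint"),
    trajectory_col: str | None = "trajectory",
    excluded_labels=EXCLUDED_LABELS,
) -> pd.DataFrame:
    """Transfer atlas annotations to chimera cells by k-NN majority vote.

    ``atlas_labels`` is indexed like ``mapping.atlas_ids`` (a column
    ``cell`` is aligned if present).  Cells whose transferred cell type
    is a technical-artifact label (doublet, stripped nucleus) are
    flagged ``excluded`` and must not enter downstream statistics.
    """
    if k > mapping.neighbor_idx.shape[1]:
        raise ValueError("k exceeds the number of stored neighbours")
    lab = atlas_labels
    if "cell" in lab.columns:
        lab = lab.set_index("cell")
    lab = lab.reindex(mapping.atlas_ids)
    out = {"cell": mapping.cell_ids}
    for col in list(label_cols) + ([trajectory_col] if trajectory_col else []):
        if col is None:
            continue
        if col not in lab.columns:
            if col == trajectory_col:
                continue
            raise ValueError(f"atlas labels lack column {col!r}")
        values = lab[col].to_numpy()
        if pd.isna(values[mapping.neighbor_idx[:, :k]]).any():
            raise ValueError(f"missing {col!r} labels on mapped neighbours")
        transferred = np.empty(mapping.cell_ids.size, dtype=object)
        for i in range(mapping.cell_ids.size):
            nb = mapping.neighbor_idx[i, :k]
            transferred[i] = _vote(values[nb], mapping.neighbor_dist[i, :k])
        out[f"mapped_{col}"] = transferred
    table = pd.DataFrame(out)
    if "mapped_cell_type" in table:
        table["excluded"] = table["mapped_cell_type"].isin(list(excluded_labels))
    mapping.table = table
    return table


def transfer_dpt(
    mapping: MappingResult, atlas_dpt: pd.Series, k: int = 5
) -> np.ndarray:
    """Chimera-cell pseudotime: mean DPT of the k nearest atlas cells.

    Atlas cells outside the ordering carry NaN DPT; if fewer than ``k``
    of a cell's neighbours have DPT the available ones are averaged
    (with a warning), and cells with none are masked NaN.
    """
    dpt = atlas_dpt.reindex(mapping.atlas_ids).to_numpy(dtype=float)
    out = np.full(mapping.cell_ids.size, np.nan)
    short = 0
    for i in range(mapping.cell_ids.size):
        vals = dpt[mapping.neighbor_idx[i]]
        vals = vals[~np.isnan(vals)][:k]
        if vals.size == 0:
            continue
        if vals.size < k:
            short += 1
        out[i] = vals.mean()
    if short:
        warnings.warn(f"{short} cells had fewer than {k} neighbours with DPT")
    return out


def _tmm_factors(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05):
    """Trimmed-mean-of-M-values normalisation factors (reference: first sample
    with median library size)."""
    lib = counts.sum(axis=0).astype(float)
    ref_idx = int(np.argsort(np.abs(lib - np.median(lib)))[0])
    ref = counts[:, ref_idx] / lib[ref_idx]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        obs = counts[:, j] / lib[j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 3:
            continue
        M = np.log2(obs[ok] / ref[ok])
        A = 0.5 * np.log2(obs[ok] * ref[ok])
        keep = np.ones(M.size, dtype=bool)
        for arr, trim in ((M, trim_m), (A, trim_a)):
            lo, hi = np.quantile(arr, [trim, 1 - trim])
            keep &= (arr >= lo) & (arr <= hi)
        if keep.sum() == 0:
            continue
        factors[j] = 2 ** np.mean(M[keep])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def test_differential_abundance(
    table: pd.DataFrame,
    counts_cols=None,
    alpha_bh: float = 0.1,
) -> pd.DataFrame:
    """Per-cell-type differential abundance between KO and WT chimeras.

    ``table`` holds one row per sample with covariate columns ``pool``,
    ``tdTom`` ('tdTom+'/'tdTom-') and ``genotype`` of the injected line
    ('KO'/'WT'), plus one integer count column per mapped cell type.
    The model per cell type is a negative-binomial log-linear model with
    pool-specific intercepts, one factor for WT-injected samples and one
    for KO-injected samples, with log normalised library sizes as
    offset; the reported test is the Wald test of the KO-injected minus
    WT-injected contrast, BH-corrected across cell types.
    """
    meta_cols = {"sample", "pool", "tdTom", "genotype"}
    if counts_cols is None:
        counts_cols = [c for c in table.columns if c not in meta_cols]
    missing = meta_cols - set(table.columns) - {"sample"}
    if missing:
        raise ValueError(f"abundance table lacks columns {sorted(missing)}")
    for geno in ("KO", "WT"):
        pools = table.loc[table["genotype"] == geno, "pool"].nunique()
        if pools < 2:
            raise ValueError(f"need >= 2 replicate pools for genotype {geno}")

    counts = table[counts_cols].to_numpy(dtype=float).T  # cell types x samples
    present = counts.sum(axis=1) > 0
    dropped = [c for c, ok in zip(counts_cols, present) if not ok]
    counts = counts[present]
    kept = [c for c, ok in zip(counts_cols, present) if ok]

    lib = counts.sum(axis=0)
    norm = _tmm_factors(counts)
    offset = np.log(lib * norm)

    pools = pd.get_dummies(table["pool"], dtype=float).to_numpy()
    inj = (table["tdTom"] == "tdTom+").to_numpy(dtype=float)
    wt_inj = inj * (table["genotype"] == "WT").to_numpy(dtype=float)
    ko_inj = inj * (table["genotype"] == "KO").to_numpy(dtype=float)
    X = np.column_stack([pools, wt_inj, ko_inj])
    contrast = np.zeros(X.shape[1])
    contrast[-2] = -1.0
    contrast[-1] = 1.0

    # moment-based NB dispersions, shrunk toward the cohort median
    alphas = []
    for y in counts:
        mu0 = np.exp(offset) * y.sum() / np.exp(offset).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.nanmean((((y - mu0) ** 2 - mu0) / mu0**2))
        alphas.append(np.clip(a, 1e-4, 10.0))
    alphas = np.asarray(alphas)
    common = float(np.median(alphas))
    alphas = np.exp(0.5 * np.log(alphas) + 0.5 * np.log(common))

    rows = []
    for y, a, name in zip(counts, alphas, kept):
        try:
            model = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=float(a)), offset=offset
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(maxiter=200)
            est = float(contrast @ fit.params)
            se = float(np.sqrt(contrast @ fit.cov_params() @ contrast))
            z = est / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                dict(cell_type=name, log2fc=est / np.log(2), contrast=est, se=se, pval=p)
            )
        except Exception as e:  # inestimable contrast
            rows.append(
                dict(
                    cell_type=name,
                    log2fc=np.nan,
                    contrast=np.nan,
                    se=np.nan,
                    pval=np.nan,
                )
            )
            warnings.warn(f"differential abundance fit failed for {name}: {e}")
    res = pd.DataFrame(rows)
    res["padj"] = bh_adjust(res["pval"].to_numpy())
    res["significant"] = res["padj"] < alpha_bh
    for name in dropped:
        res = pd.concat(
            [res, pd.DataFrame([dict(cell_type=name, pval=np.nan, padj=np.nan,
                                     log2fc=np.nan, contrast=np.nan, se=np.nan,
                                     significant=False)])],
            ignore_index=True,
        )
    return res


def relative_ratio(
    n_inj_a: int, n_host_a: int, n_inj_b: int, n_host_b: int
) -> tuple[float, bool]:
    """Injected/host contribution ratio on lineage A over that on lineage B.

    ``(n_inj_a / n_host_a) / (n_inj_b / n_host_b)``.  Any zero count in
    a denominator position triggers a +0.5 continuity correction applied
    to all four counts; the returned flag marks corrected values.
    """
    counts = [n_inj_a, n_host_a, n_inj_b, n_host_b]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    corrected = any(c == 0 for c in counts)
    if corrected:
        n_inj_a, n_host_a, n_inj_b, n_host_b = (c + 0.5 for c in counts)
    return (n_inj_a / n_host_a) / (n_inj_b / n_host_b), corrected


def _pool_ratios(cells: pd.DataFrame, traj_a: str, traj_b: str, traj_col: str):
    """log2 relative ratio per pool; pools with empty lineages are dropped."""
    out = {}
    for pool, sub in cells.groupby("pool"):
        inj = sub["tdTom"] == "tdTom+"
        on_a = sub[traj_col] == traj_a
        on_b = sub[traj_col] == traj_b
        if (on_a | on_b).sum() < 2:
            warnings.warn(f"pool {pool!r} has <2 cells on the tested trajectories")
            continue
        r, _ = relative_ratio(
            int((inj & on_a).sum()),
            int((~inj & on_a).sum()),
            int((inj & on_b).sum()),
            int((~inj & on_b).sum()),
        )
        out[pool] = np.log2(r)
    return out


def permutation_ratio_test(
    cells: pd.DataFrame,
    traj_a: str,
    traj_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    traj_col: str = "trajectory",
) -> dict:
    """Permutation test of the fate-bias difference between chimera types.

    The observed statistic is the difference in mean log2 relative ratio
    (lineage A vs lineage B) between KO-injected pools and WT-injected
    pools.  The null is generated by permuting trajectory labels within
    each pool (per-pool label totals and each cell's tdTom status are
    preserved); the two-sided p-value is
    ``(1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1)``.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    for col in ("pool", "tdTom", traj_col, "genotype"):
        if col not in cells:
            raise ValueError(f"cell table lacks {col!r}")
    rng = np.random.default_rng(seed)
    geno_of_pool = cells.groupby("pool")["genotype"].agg(
        lambda s: "KO" if (s == "KO").any() else "WT"
    )

    def _log_ratio(nia, nha, nib, nhb):
        corr = (nia == 0) | (nha == 0) | (nib == 0) | (nhb == 0)
        off = np.where(corr, 0.5, 0.0)
        return np.log2(
            ((nia + off) / (nha + off)) / ((nib + off) / (nhb + off))
        )

    pools = cells["pool"].to_numpy()
    inj_all = (cells["tdTom"] == "tdTom+").to_numpy()
    on_a_all = (cells[traj_col] == traj_a).to_numpy()
    on_b_all = (cells[traj_col] == traj_b).to_numpy()

    usable, obs_ratio, perm_ratio, genos = [], [], [], []
    # the number of cells on the tested trajectories per pool is invariant
    # under within-pool label permutation, so the drop rule is applied once
    for p in np.unique(pools):
        idx = np.flatnonzero(pools == p)
        A, B, inj = on_a_all[idx], on_b_all[idx], inj_all[idx]
        if (A | B).sum() < 2:
            warnings.warn(f"pool {p!r} has <2 cells on the tested trajectories")
            continue
        usable.append(p)
        genos.append(geno_of_pool[p])
        obs_ratio.append(
            _log_ratio(
                float((inj & A).sum()), float((~inj & A).sum()),
                float((inj & B).sum()), float((~inj & B).sum()),
            )
        )
        # permute labels within the pool: cell i keeps its tdTom status and
        # receives the label of cell order[i]
        order = np.argsort(rng.random((n_perm, idx.size)), axis=1)
        pa, pb = A[order], B[order]
        perm_ratio.append(
            _log_ratio(
                (pa & inj[None, :]).sum(axis=1).astype(float),
                (pa & ~inj[None, :]).sum(axis=1).astype(float),
                (pb & inj[None, :]).sum(axis=1).astype(float),
                (pb & ~inj[None, :]).sum(axis=1).astype(float),
            )
        )
    genos = np.asarray(genos)
    is_ko = genos == "KO"
    if not is_ko.any() or is_ko.all():
        raise ValueError("need pools of both chimera types with usable counts")
    obs_ratio = np.asarray(obs_ratio)
    perm_ratio = np.stack(perm_ratio, axis=1)  # n_perm x pools
    t_obs = float(obs_ratio[is_ko].mean() - obs_ratio[~is_ko].mean())
    perm_stats = perm_ratio[:, is_ko].mean(axis=1) - perm_ratio[:, ~is_ko].mean(
        axis=1
    )
    p = (1.0 + np.sum(np.abs(perm_stats) >= abs(t_obs) - 1e-12)) / (n_perm + 1.0)
    return dict(
        statistic=t_obs,
        pvalue=float(p),
        n_perm=n_perm,
        seed=seed,
        pool_ratios=dict(zip(usable, obs_ratio)),
        perm_stats=perm_stats,
    )


def ks_compare_orderings(dpt_a, dpt_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of two DPT distributions."""
    a = np.asarray(dpt_a, dtype=float)
    b = np.asarray(dpt_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return 0.0, 1.0
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
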