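"""Dimensionality reduction, batch integration, clustering and pseudotime.

The manifold recipe: a 50-dimensional PCA of the highly-variable genes
(genes centred, not scaled), sequential mutual-nearest-neighbour (MNN)
batch correction following a data-driven merge order, a diffusion map
with locally adaptive Gaussian kernel on the corrected components, and
diffusion pseudotime (DPT) measured from a root cell chosen as the most
extreme cell of the first diffusion component within a designated root
population.
"""

from __future__ import annotations

import random as _py_random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors


@dataclass
class Embedding:
    cell_ids: np.ndarray
    coords: np.ndarray  # cells x D
    space: str  # pca | pca_corrected | diffusion
    loadings: np.ndarray | None = None  # genes x D, for projecting new data
    gene_means: np.ndarray | None = None
    genes: np.ndarray | None = None

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in embedding")
        if self.coords.shape[0] != self.cell_ids.size:
            raise ValueError("coordinate rows do not match cell ids")


@dataclass
class DiffusionResult:
    cell_ids: np.ndarray
    eigenvalues: np.ndarray  # descending, trivial eigenvalue removed
    components: np.ndarray  # cells x C
    dpt: np.ndarray | None = None
    root: str | None = None


@dataclass
class MergePlan:
    order: list = field(default_factory=list)  # batch ids, reference first


def compute_pca(
    expr: np.ndarray,
    gene_names,
    cell_ids,
    hvgs: pd.DataFrame | None = None,
    n_components: int = 50,
) -> Embedding:
    """Truncated PCA of the HVG-subset expression (genes centred, not scaled).

    Component signs are fixed so the largest-magnitude gene loading of
    each component is positive, making the embedding deterministic.
    """
    expr = np.asarray(expr, dtype=float)
    genes = np.asarray(list(gene_names), dtype=object)
    if hvgs is not None:
        keep = np.isin(genes, hvgs.loc[hvgs["selected"], "gene"].to_numpy())
        if keep.sum() < n_components:
            raise ValueError(
                f"need >= {n_components} selected HVGs, have {int(keep.sum())}"
            )
        expr = expr[keep]
        genes = genes[keep]
    n_cells = expr.shape[1]
    if n_cells < n_components:
        raise ValueError("fewer cells than requested components")

    gene_means = expr.mean(axis=1)
    X = (expr - gene_means[:, None]).T  # cells x genes
    # deterministic truncated SVD via LAPACK on the smaller Gram side
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, s.size)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign fix: largest-|loading| positive per component
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    coords = U * s[None, :]
    if k < n_components:  # rank-deficient input: pad with zeros
        coords = np.hstack([coords, np.zeros((n_cells, n_components - k))])
        Vt = np.vstack([Vt, np.zeros((n_components - k, Vt.shape[1]))])
    return Embedding(
        cell_ids=np.asarray(cell_ids),
        coords=coords,
        space="pca",
        loadings=Vt.T,
        gene_means=gene_means,
        genes=genes,
    )


def project_onto(embedding: Embedding, expr: np.ndarray, gene_names, cell_ids) -> Embedding:
    """Project new cells into an existing PC space using its stored loadings."""
    if embedding.loadings is None or embedding.genes is None:
        raise ValueError("embedding carries no loadings to project with")
    genes = np.asarray(list(gene_names), dtype=object)
    idx = {g: i for i, g in enumerate(genes)}
    try:
        rows = np.array([idx[g] for g in embedding.genes])
    except KeyError as e:
        raise ValueError(f"gene {e} of the PC space missing from new data")
    X = (np.asarray(expr, dtype=float)[rows] - embedding.gene_means[:, None]).T
    return Embedding(
        cell_ids=np.asarray(cell_ids),
        coords=X @ embedding.loadings,
        space=embedding.space,
        loadings=embedding.loadings,
        gene_means=embedding.gene_means,
        genes=embedding.genes,
    )


def build_merge_order(cells: pd.DataFrame, mode: str = "atlas") -> MergePlan:
    """Batch merge order for sequential MNN correction.

    Atlas mode: within each time point, samples from most to fewest
    cells; time points from oldest to youngest.  Chimera mode: within
    each genotype largest sample first, then across genotypes (larger
    genotype first).  Cell-count ties break lexicographically.
    """
    if "sample" not in cells:
        raise ValueError("cell table lacks a 'sample' column")
    sizes = cells.groupby("sample").size()

    def by_size(samples):
        return sorted(samples, key=lambda s: (-sizes[s], s))

    if mode == "atlas":
        if "stage_index" not in cells:
            raise ValueError("atlas merge order needs a 'stage_index' column")
        order = []
        stage_of = cells.groupby("sample")["stage_index"].first()
        for stage in sorted(stage_of.unique()):
            order.extend(by_size(stage_of.index[stage_of == stage]))
        return MergePlan(order)
    if mode == "chimera":
        if "genotype" not in cells:
            raise ValueError("chimera merge order needs a 'genotype' column")
        geno_of = cells.groupby("sample")["genotype"].first()
        geno_sizes = cells.groupby("genotype").size()
        order = []
        for geno in sorted(geno_sizes.index, key=lambda g: (-geno_sizes[g], g)):
            order.extend(by_size(geno_of.index[geno_of == geno]))
        return MergePlan(order)
    raise ValueError(f"unknown merge mode: {mode}")


def _mnn_pairs(ref: np.ndarray, new: np.ndarray, k: int):
    k_r = min(k, ref.shape[0])
    k_n = min(k, new.shape[0])
    nn_ref = NearestNeighbors(n_neighbors=k_r).fit(ref)
    nn_new = NearestNeighbors(n_neighbors=k_n).fit(new)
    ref_of_new = nn_ref.kneighbors(new, return_distance=False)  # new -> ref
    new_of_ref = nn_new.kneighbors(ref, return_distance=False)  # ref -> new
    new_sets = [set(row) for row in ref_of_new]
    pairs = []
    for i in range(ref.shape[0]):
        for j in new_of_ref[i]:
            if i in new_sets[j]:
                pairs.append((i, j))
    return pairs


def _kernel_shift(ref, new, k, sigma):
    pairs = _mnn_pairs(ref, new, k)
    if not pairs:
        raise RuntimeError("no mutual nearest neighbours between batches")
    if sigma is None:
        sigma = 0.1 * float(
            np.sqrt(np.mean(np.sum((ref - ref.mean(axis=0)) ** 2, axis=1)))
        )
        sigma = max(sigma, 1e-12)
    pi = np.array([p[0] for p in pairs])
    pj = np.array([p[1] for p in pairs])
    vecs = ref[pi] - new[pj]
    anchors = new[pj]
    d2 = ((new[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * sigma**2))
    w_sum = w.sum(axis=1, keepdims=True)
    # cells far from every anchor fall back to the mean pair vector
    far = w_sum.ravel() <= 1e-300
    w = np.where(w_sum > 1e-300, w / np.where(w_sum == 0, 1, w_sum), 0.0)
    shift = w @ vecs
    if far.any():
        shift[far] = vecs.mean(axis=0)
    return shift, pairs


def mnn_shift(
    ref: np.ndarray,
    new: np.ndarray,
    k: int = 20,
    sigma: float | None = None,
    max_rounds: int = 1,
):
    """Correction vectors moving ``new`` onto ``ref`` via mutual nearest neighbours.

    Pair vectors (ref - new) are averaged per incoming cell with Gaussian
    kernel weights in the incoming batch's coordinates; bandwidth
    defaults to 0.1 x RMS spread of the reference batch.  The default is
    a single match-and-shift pass (repeated passes align batches more
    aggressively, which is wrong when the incoming batch carries real
    biological progression relative to the reference; ``max_rounds`` > 1
    is available for mapping problems where full alignment is intended).
    """
    spread = float(
        np.sqrt(np.mean(np.sum((ref - ref.mean(axis=0)) ** 2, axis=1)))
    )
    total = np.zeros_like(new, dtype=float)
    moved = np.asarray(new, dtype=float).copy()
    pairs = []
    for _ in range(max_rounds):
        shift, pairs = _kernel_shift(ref, moved, k, sigma)
        total += shift
        moved += shift
        if np.linalg.norm(shift.mean(axis=0)) < 0.01 * max(spread, 1e-12):
            break
    return total, pairs


def mnn_correct(
    embedding: Embedding,
    batches,
    plan: MergePlan,
    k: int = 20,
    sigma: float | None = None,
    max_rounds: int = 1,
) -> Embedding:
    """Sequential MNN batch correction along a merge plan.

    The first batch in the plan is the untouched reference; each later
    batch is shifted onto the growing reference by its kernel-weighted
    MNN correction vectors.  ``max_rounds`` = 1 (default) is the
    conservative single-pass merge appropriate when successive batches
    carry real biological progression (e.g. consecutive embryonic
    stages); larger values repeat matching and shifting until two
    samples of the *same* population are fully aligned, removing large
    planted batch vectors that a single pass systematically
    under-corrects.
    """
    batches = np.asarray(batches)
    if set(plan.order) != set(np.unique(batches)):
        raise ValueError("merge plan does not cover exactly the observed batches")
    coords = embedding.coords.copy()
    merged = np.zeros(coords.shape[0], dtype=bool)
    first = plan.order[0]
    merged[batches == first] = True
    for b in plan.order[1:]:
        incoming = batches == b
        try:
            shift, _ = mnn_shift(
                coords[merged], coords[incoming], k=k, sigma=sigma,
                max_rounds=max_rounds,
            )
        except RuntimeError:
            raise RuntimeError(f"no MNN pairs between merged set and batch {b!r}")
        coords[incoming] += shift
        merged[incoming] = True
    return Embedding(embedding.cell_ids, coords, "pca_corrected")


def cluster_cells(
    embedding: Embedding,
    k_graph: int = 15,
    seed: int = 42,
    resolution: float = 0.2,
) -> np.ndarray:
    """Louvain communities on a shared-nearest-neighbour graph.

    Edges join kNN pairs weighted by their Jaccard neighbourhood
    overlap; community detection uses igraph's multilevel (Louvain)
    algorithm, seeded for determinism.  The default resolution is
    coarse: it keeps an isotropic cloud in one community and separates
    well-isolated groups, which is the granularity wanted for
    subclustering a cell type rather than shattering it.
    """
    import igraph

    X = embedding.coords
    n = X.shape[0]
    if k_graph >= n:
        raise ValueError("k_graph must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k_graph + 1).fit(X)
    knn = nn.kneighbors(X, return_distance=False)[:, 1:]
    neigh = [set(row) | {i} for i, row in enumerate(knn)]
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in knn[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            edges.append((a, b))
            weights.append(inter / union)
    g = igraph.Graph(n=n, edges=edges)
    _py_random.seed(seed)
    part = g.community_multilevel(weights=weights, resolution=resolution)
    return np.asarray(part.membership)


def diffusion_map(
    embedding: Embedding, n_components: int = 20, k_kernel: int = 30
) -> DiffusionResult:
    """Diffusion map with locally adaptive Gaussian kernel.

    Kernel bandwidth at each cell is its distance to the ``k_kernel``-th
    neighbour; the kernel is density-normalised before forming the
    Markov transition operator, whose leading non-trivial eigenpairs are
    the diffusion components.
    """
    X = embedding.coords
    n = X.shape[0]
    k = min(k_kernel, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    local = np.maximum(dist[:, -1], 1e-12)

    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    d2 = dist[:, 1:].ravel() ** 2
    vals = np.exp(-d2 / (local[rows] * local[cols]))
    K = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    K = K.maximum(K.T)
    K = K + sp.identity(n, format="csr")

    n_comp, labels = connected_components(K, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise RuntimeError(
            f"kernel graph is disconnected (component sizes {sizes.tolist()}); "
            "increase k_kernel"
        )

    q = np.asarray(K.sum(axis=1)).ravel()
    Dq = sp.diags(1.0 / q)
    W = Dq @ K @ Dq  # density normalisation (alpha = 1)
    d = np.asarray(W.sum(axis=1)).ravel()
    Dh = sp.diags(1.0 / np.sqrt(d))
    S = Dh @ W @ Dh  # symmetric conjugate of the transition matrix

    ncv = min(n, max(2 * (n_components + 1) + 1, 20))
    v0 = np.full(n, 1.0 / np.sqrt(n))  # deterministic Lanczos start
    vals, vecs = spla.eigsh(
        S, k=min(n_components + 1, n - 1), which="LA", ncv=ncv, v0=v0
    )
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    psi = Dh @ vecs  # right eigenvectors of the transition matrix
    # drop the trivial (constant) eigenvector
    lam = vals[1:]
    comps = psi[:, 1:]
    # normalise each component and fix sign deterministically
    comps = comps / np.linalg.norm(comps, axis=0, keepdims=True)
    sign = np.sign(comps[np.argmax(np.abs(comps), axis=0), np.arange(comps.shape[1])])
    sign[sign == 0] = 1.0
    comps = comps * sign[None, :]
    if np.any(lam >= 1.0 - 1e-12):
        warnings.warn("near-unit eigenvalue retained; graph may be nearly split")
    return DiffusionResult(
        cell_ids=embedding.cell_ids, eigenvalues=lam, components=comps
    )


def compute_dpt(dm: DiffusionResult, root_group) -> DiffusionResult:
    """Diffusion pseudotime from a root chosen within ``root_group``.

    The root is the group cell with the most extreme (largest absolute)
    first diffusion component, ties broken by smallest cell identifier.
    DPT(i) is the Euclidean distance between rows of the matrix with
    entries (lambda_c / (1 - lambda_c)) DC_c, measured from the root,
    with the first component oriented so the root sits at the negative
    end.
    """
    root_group = list(root_group)
    if not root_group:
        raise ValueError("root group is empty")
    ids = list(dm.cell_ids)
    pos = {c: i for i, c in enumerate(ids)}
    members = [pos[c] for c in root_group if c in pos]
    if not members:
        raise ValueError("no root-group cell present in the diffusion result")
    lam = dm.eigenvalues
    if np.any(lam >= 1.0):
        raise ValueError("unit eigenvalue retained: graph disconnected")
    dc1 = dm.components[:, 0]
    extreme = np.abs(dc1[members])
    best = extreme.max()
    tied = [members[i] for i in np.flatnonzero(extreme == best)]
    root_idx = min(tied, key=lambda i: str(ids[i]))

    comps = dm.components.copy()
    if dc1[root_idx] > 0:  # orient DC1 with the root at the negative end
        comps[:, 0] = -comps[:, 0]
    M = comps * (lam / (1.0 - lam))[None, :]
    dpt = np.linalg.norm(M - M[root_idx], axis=1)
    return DiffusionResult(
        cell_ids=dm.cell_ids,
        eigenvalues=lam,
        components=comps,
        dpt=dpt,
        root=str(ids[root_idx]),
    )


def windowed_profile(
    values: np.ndarray,
    dpt: np.ndarray,
    window_frac: float = 0.10,
    n_points: int = 100,
):
    """Sliding-window mean of per-cell values along a DPT ordering.

    The window width is ``window_frac`` of the DPT range; evaluation
    points span the range evenly and the profile at each point is the
    mean over cells within half a window.  Empty windows give NaN.
    Returns ``(centers, profile)``.
    """
    if not 0.0 < window_frac <= 1.0:
        raise ValueError("window_frac must be in (0, 1]")
    values = np.asarray(values, dtype=float)
    dpt = np.asarray(dpt, dtype=float)
    lo, hi = dpt.min(), dpt.max()
    width = window_frac * (hi - lo)
    centers = np.linspace(lo, hi, n_points)
    profile = np.full(n_points, np.nan)
    for i, c in enumerate(centers):
        # windows are clamped inside the DPT range so edge windows keep
        # their full width (window_frac = 1 reduces to the global mean)
        left = min(max(c - width / 2.0, lo), hi - width)
        mask = (dpt >= left - 1e-12) & (dpt <= left + width + 1e-12)
        if mask.any():
            profile[i] = values[mask].mean()
    return centers, profile
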