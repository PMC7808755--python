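"""Synthetic mouse-embryo scRNA-seq generator with known ground truth.

The generator emulates the structure of a gastrulation time course: nine
sequential stages (E6.5 to E8.5 in quarter-day steps), a branching
differentiation landscape whose three terminal fates are anterior somitic
mesoderm, posterior somitic mesoderm and neuromesodermal progenitors
(NMPs), plus transcriptionally static bystander cell types, per-sample
batch effects, and chimera designs in which injected (tdTom+) cells may
carry a fate-biasing knockout.

The latent model is a piecewise-linear trajectory tree: a cell with fate
``f`` and latent pseudotime ``t`` in [0, 1] travels along a shared trunk
axis until the fate's branch time and then along a fate-specific axis.
Gene means are ``gain * softplus(W z + b)`` for a sparse program loading
matrix ``W``; counts are negative-binomial around those means with a
per-cell sequencing-depth multiplier.  Batch effects are additive shifts
in latent space shared by all cells of a sample - exactly the structure
mutual-nearest-neighbour correction is designed to remove.

All randomness flows through one ``numpy`` generator seeded from the
config, so a fixed seed gives bit-identical integer count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import softplus

FATE_NAMES = ("anterior_somitic", "posterior_somitic", "NMP")

DEFAULT_BRANCH_TIMES = {
    "anterior_somitic": 0.2,
    "posterior_somitic": 0.5,
    "NMP": 0.5,
}


def default_stage_labels(n: int = 9) -> list:
    """E6.5, E6.75, ... in 0.25-day steps."""
    return [f"E{6.5 + 0.25 * i:.2f}".rstrip("0").rstrip(".") for i in range(n)]


@dataclass
class SimConfig:
    """Parameters of the synthetic embryo.

    Defaults correspond to the study design being emulated: 9 stages,
    3 terminal fates with branch times 0.2 / 0.5 / 0.5 on the unit
    pseudotime axis, two biological samples per stage so batch
    correction has something to do.
    """

    n_timepoints: int = 9
    timepoint_labels: Optional[list] = None
    n_cells_per_timepoint: int = 300
    n_genes: int = 2000
    n_fates: int = 3
    n_bystander_types: int = 2
    branch_times: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_TIMES)
    )
    latent_dim: int = 10
    batch_effect_sd: float = 0.15
    nb_dispersion: float = 0.1
    mito_gene_count: int = 10
    seed: int = 0
    # the latent->expression map (gene programs, loadings, intercepts) is
    # the shared biology of the simulated universe: datasets meant to be
    # comparable (atlas and its chimeras) must use the same model_seed
    # even when their sampling seeds differ
    model_seed: int = 0
    # secondary knobs (held at these values throughout the study conditions)
    n_samples_per_timepoint: int = 2
    bystander_fraction: float = 0.3
    stage_pseudotime_sd: float = 0.05
    latent_noise_sd: float = 0.15
    path_scale: float = 5.0
    depth_log_sd: float = 0.25
    expression_gain: float = 3.0
    mito_fraction: float = 0.02

    def __post_init__(self):
        if self.timepoint_labels is None:
            self.timepoint_labels = default_stage_labels(self.n_timepoints)
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_timepoints",
            "n_cells_per_timepoint",
            "n_genes",
            "n_fates",
            "latent_dim",
            "mito_gene_count",
            "n_samples_per_timepoint",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")
        if len(self.timepoint_labels) != self.n_timepoints:
            raise ValueError("timepoint_labels length != n_timepoints")
        if list(self.timepoint_labels) != sorted(
            set(self.timepoint_labels), key=list(self.timepoint_labels).index
        ) or len(set(self.timepoint_labels)) != self.n_timepoints:
            raise ValueError("timepoint_labels must be distinct")
        if self.n_fates > len(FATE_NAMES):
            raise ValueError(f"at most {len(FATE_NAMES)} fates supported")
        for f, bt in self.branch_times.items():
            if not 0.0 <= bt <= 1.0:
                raise ValueError(f"branch time for {f} outside [0, 1]")
        needed = 1 + self.n_fates + self.n_bystander_types
        if self.latent_dim < needed:
            raise ValueError(
                f"latent_dim must be >= {needed} "
                "(trunk + one axis per fate and bystander type)"
            )

    @property
    def fate_names(self) -> list:
        return list(FATE_NAMES[: self.n_fates])

    @property
    def bystander_names(self) -> list:
        return [f"bystander_{i}" for i in range(self.n_bystander_types)]


@dataclass
class GroundTruth:
    """Planted truth: per-cell fate/pseudotime, per-gene program, parameters."""

    cells: pd.DataFrame
    genes: pd.DataFrame
    params: dict


class _Programs:
    """Deterministic gene-program layout and latent->expression map."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        c = config
        g = c.n_genes
        m = c.mito_gene_count
        if m >= g:
            raise ValueError("mito_gene_count must be < n_genes")
        n_body = g - m
        n_shared = max(int(0.10 * n_body), 5)
        n_per_fate = max(int(0.10 * n_body), 5)
        n_per_byst = max(int(0.05 * n_body), 3)
        program = np.array(["noise"] * n_body, dtype=object)
        pos = 0
        program[pos : pos + n_shared] = "shared"
        pos += n_shared
        for f in c.fate_names:
            program[pos : pos + n_per_fate] = f
            pos += n_per_fate
        for b in c.bystander_names:
            program[pos : pos + n_per_byst] = b
            pos += n_per_byst
        if pos > n_body:
            raise ValueError("n_genes too small for the program layout")

        names = [f"G{i + 1:06d}" for i in range(n_body)]
        mito_names = [f"mt-M{i + 1:03d}" for i in range(m)]
        self.gene_names = names + mito_names
        self.program = np.concatenate([program, np.array(["mito"] * m, dtype=object)])

        # loading matrix over latent axes: 0 trunk, 1..n_fates fates, then bystanders
        W = rng.normal(0.0, 0.04, size=(n_body, c.latent_dim))
        axis_of = {"shared": 0}
        for i, f in enumerate(c.fate_names):
            axis_of[f] = 1 + i
        for i, b in enumerate(c.bystander_names):
            axis_of[b] = 1 + c.n_fates + i
        for prog, axis in axis_of.items():
            rows = np.where(program == prog)[0]
            W[rows, axis] += rng.normal(0.9, 0.15, size=rows.size) * rng.choice(
                [1.0, 1.0, 1.0, -0.5], size=rows.size
            )
        self.W = W
        self.intercept = rng.normal(1.2, 1.2, size=n_body)
        # relative abundances of the mitochondrial genes (sum to 1)
        w = rng.gamma(4.0, 1.0, size=m)
        self.mito_weights = w / w.sum()
        self.config = c

    def mean_matrix(self, latent: np.ndarray) -> np.ndarray:
        """Genes x cells expected counts at unit depth (mito block included)."""
        c = self.config
        body = c.expression_gain * softplus(
            self.W @ latent.T + self.intercept[:, None]
        )
        total_body = body.sum(axis=0)
        frac = c.mito_fraction
        mito_total = total_body * frac / (1.0 - frac)
        mito = self.mito_weights[:, None] * mito_total[None, :]
        return np.vstack([body, mito])


def _fate_path(config: SimConfig, fate: str, t: np.ndarray) -> np.ndarray:
    """Latent position of lineage cells: trunk until branch time, then fate axis."""
    c = config
    bt = c.branch_times.get(fate, 0.0)
    axis = 1 + c.fate_names.index(fate)
    z = np.zeros((t.size, c.latent_dim))
    z[:, 0] = np.minimum(t, bt) * c.path_scale
    z[:, axis] = np.clip(t - bt, 0.0, None) * c.path_scale
    return z


def _bystander_pos(config: SimConfig, which: int, n: int) -> np.ndarray:
    c = config
    z = np.zeros((n, c.latent_dim))
    z[:, 0] = 0.4 * c.path_scale
    z[:, 1 + c.n_fates + which] = 0.8 * c.path_scale
    return z


def _sample_counts(
    means: np.ndarray, dispersion: float, depth: np.ndarray, rng: np.random.Generator
) -> sp.csr_matrix:
    """NB(mu, alpha) counts via the gamma-Poisson mixture; genes x cells."""
    mu = means * depth[None, :]
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    counts = rng.poisson(lam)
    return sp.csr_matrix(counts)


def _simulate_cohort(
    config: SimConfig,
    rng: np.random.Generator,
    fate_probs_of,
    sample_of,
    extra_cols,
    stages=None,
):
    """Shared machinery: draw fates, pseudotimes, latent positions, counts.

    ``fate_probs_of(cell_index)`` returns the fate-probability vector used
    for lineage cells; ``sample_of(stage_index, cell_index)`` the sample
    id; ``extra_cols(cell_index)`` a dict of additional metadata.
    """
    c = config
    programs = _Programs(c, np.random.default_rng(c.model_seed))
    stage_list = list(range(c.n_timepoints)) if stages is None else list(stages)
    fates = c.fate_names
    bysts = c.bystander_names
    per_byst = (
        c.bystander_fraction / c.n_bystander_types if c.n_bystander_types else 0.0
    )

    rows = []
    latents = []
    ci = 0
    for si in stage_list:
        stage_mean = si / max(c.n_timepoints - 1, 1)
        for _ in range(c.n_cells_per_timepoint):
            t = float(
                np.clip(rng.normal(stage_mean, c.stage_pseudotime_sd), 0.0, 1.0)
            )
            if c.n_bystander_types and rng.random() < c.bystander_fraction:
                which = int(rng.integers(c.n_bystander_types))
                label = bysts[which]
                z = _bystander_pos(c, which, 1)[0]
                fate = label
                cell_type = label
            else:
                p = np.asarray(fate_probs_of(ci), dtype=float)
                fate = fates[int(rng.choice(len(fates), p=p))]
                z = _fate_path(c, fate, np.array([t]))[0]
                bt = c.branch_times.get(fate, 0.0)
                cell_type = fate if t >= bt else "trunk_progenitor"
            z = z + rng.normal(0.0, c.latent_noise_sd, size=c.latent_dim)
            sample = sample_of(si, ci)
            rows.append(
                dict(
                    sample=sample,
                    timepoint=c.timepoint_labels[si],
                    stage_index=si,
                    true_fate=fate,
                    true_pseudotime=t,
                    cell_type=cell_type,
                    **extra_cols(ci),
                )
            )
            latents.append(z)
            ci += 1

    cells = pd.DataFrame(rows)
    cells["cell"] = [
        f"{s}_c{i:05d}" for i, s in enumerate(cells["sample"].tolist())
    ]
    latent = np.asarray(latents)

    # per-sample additive batch shift in latent space
    samples = cells["sample"].unique()
    shifts = {
        s: rng.normal(0.0, c.batch_effect_sd, size=c.latent_dim) for s in samples
    }
    shifted = latent + np.stack([shifts[s] for s in cells["sample"]])

    depth = rng.lognormal(0.0, c.depth_log_sd, size=len(cells))
    means = programs.mean_matrix(shifted)
    counts = _sample_counts(means, c.nb_dispersion, depth, rng)

    gene_truth = pd.DataFrame(
        {"gene": programs.gene_names, "program": programs.program}
    )
    cell_truth = cells[
        ["cell", "sample", "timepoint", "true_fate", "true_pseudotime"]
    ].copy()
    cell_truth["latent_depth"] = depth
    truth = GroundTruth(
        cells=cell_truth,
        genes=gene_truth,
        params={"batch_shifts": {s: shifts[s].tolist() for s in samples}},
    )
    order = [
        "cell",
        "sample",
        "timepoint",
        "stage_index",
        "cell_type",
        "true_fate",
        "true_pseudotime",
    ]
    order += [k for k in cells.columns if k not in order]
    return counts, cells[order], truth, programs.gene_names


def simulate_atlas(config: SimConfig):
    """Reference-atlas-like dataset: all stages, wild-type fate proportions.

    Returns ``(counts, cell_table, ground_truth)`` with counts as a sparse
    genes x cells integer matrix.  Each stage contributes
    ``n_samples_per_timepoint`` samples so batch correction is testable.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    uniform = np.full(c.n_fates, 1.0 / c.n_fates)
    n_per_sample = int(np.ceil(c.n_cells_per_timepoint / c.n_samples_per_timepoint))

    def sample_of(si, ci):
        j = (ci % c.n_cells_per_timepoint) // n_per_sample
        return f"{c.timepoint_labels[si]}_s{j + 1}"

    counts, cells, truth, genes = _simulate_cohort(
        c,
        rng,
        fate_probs_of=lambda ci: uniform,
        sample_of=sample_of,
        extra_cols=lambda ci: dict(genotype="WT", tdTom="NA", pool="NA"),
    )
    cells.attrs["genes"] = genes
    return counts, cells, truth


def simulate_chimera(
    config: SimConfig,
    ko_bias: Mapping[str, float],
    n_pools: int = 3,
    injected_fraction: float = 0.5,
    harvest_stage: Optional[int] = None,
):
    """Chimera-like dataset: injected (tdTom+) vs host (tdTom-) cells.

    Host cells follow the wild-type fate probabilities; injected-cell
    probabilities are the host probabilities multiplied per fate by
    ``ko_bias`` and renormalised.  ``ko_bias`` of all ones is the
    wild-type-injection control.  Each of the ``n_pools`` replicate
    pools (independent chimera experiments) yields one tdTom+ and one
    tdTom- sample; all pools are harvested at ``harvest_stage``
    (default: the final time point).
    """
    c = config
    for f, m in ko_bias.items():
        if m < 0:
            raise ValueError(f"ko_bias for {f} must be >= 0")
        if f not in c.fate_names:
            raise ValueError(f"unknown fate in ko_bias: {f}")
    base = np.full(c.n_fates, 1.0 / c.n_fates)
    mult = np.array([ko_bias.get(f, 1.0) for f in c.fate_names])
    if mult.sum() == 0:
        raise ValueError("all ko_bias multipliers are zero")
    biased = base * mult
    biased = biased / biased.sum()
    is_ko = any(abs(ko_bias.get(f, 1.0) - 1.0) > 1e-12 for f in c.fate_names)
    genotype = "KO" if is_ko else "WT"

    rng = np.random.default_rng(c.seed + 1)
    si = c.n_timepoints - 1 if harvest_stage is None else int(harvest_stage)
    n_per_pool = c.n_cells_per_timepoint

    # one pass per pool so each pool is an independent cohort
    all_counts, all_cells, all_truth = [], [], []
    genes = None
    for p in range(n_pools):
        injected = rng.random(n_per_pool) < injected_fraction

        def probs_of(ci):
            return biased if injected[ci % n_per_pool] else base

        def sample_of(_si, ci):
            tag = "tdTomP" if injected[ci % n_per_pool] else "tdTomN"
            return f"pool{p + 1}_{tag}"

        def extra(ci):
            inj = bool(injected[ci % n_per_pool])
            return dict(
                genotype=genotype if inj else "WT",
                tdTom="tdTom+" if inj else "tdTom-",
                pool=f"pool{p + 1}",
            )

        counts, cells, truth, genes = _simulate_cohort(
            c, rng, probs_of, sample_of, extra, stages=[si]
        )
        all_counts.append(counts)
        all_cells.append(cells)
        all_truth.append(truth)

    counts = sp.hstack(all_counts, format="csr")
    cells = pd.concat(all_cells, ignore_index=True)
    cell_truth = pd.concat([t.cells for t in all_truth], ignore_index=True)
    truth = GroundTruth(
        cells=cell_truth,
        genes=all_truth[0].genes,
        params={
            "ko_bias": dict(ko_bias),
            "genotype": genotype,
            "fate_probs_injected": biased.tolist(),
            "fate_probs_host": base.tolist(),
        },
    )
    cells.attrs["genes"] = genes
    return counts, cells, truth


def spike_qc_artifacts(
    counts: sp.spmatrix,
    cells: pd.DataFrame,
    frac_high_mito: float = 0.0,
    frac_low_umi: float = 0.0,
    seed: int = 0,
    mito_factor: float = 12.0,
    umi_ceiling: int = 5000,
):
    """Plant QC-positive cells: inflated mitochondrial load and shallow barcodes.

    A ``frac_high_mito`` fraction of cells has its mitochondrial counts
    multiplied by ``mito_factor`` (pushing their mito fraction well past
    5x the cohort median); a disjoint ``frac_low_umi`` fraction is
    binomially thinned below ``umi_ceiling`` total UMIs.  Truth labels
    are added as boolean columns ``planted_high_mito`` / ``planted_low_umi``.
    """
    for name, f in (("frac_high_mito", frac_high_mito), ("frac_low_umi", frac_low_umi)):
        if not 0.0 <= f < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    if frac_high_mito + frac_low_umi >= 1.0:
        raise ValueError("artifact fractions must sum to < 1")

    cells = cells.copy()
    n = counts.shape[1]
    cells["planted_high_mito"] = False
    cells["planted_low_umi"] = False
    if frac_high_mito == 0.0 and frac_low_umi == 0.0:
        return counts.copy(), cells

    rng = np.random.default_rng(seed)
    genes = cells.attrs.get("genes")
    if genes is None:
        raise ValueError("cell table lacks the gene list (cells.attrs['genes'])")
    mito_rows = np.array([g.startswith("mt-") for g in genes])
    if frac_high_mito > 0 and not mito_rows.any():
        raise ValueError("no mitochondrial (mt-) genes to inflate")

    n_hm = int(round(frac_high_mito * n))
    n_lu = int(round(frac_low_umi * n))
    chosen = rng.choice(n, size=n_hm + n_lu, replace=False)
    hm_idx, lu_idx = chosen[:n_hm], chosen[n_hm:]

    mat = np.asarray(counts.todense(), dtype=np.int64)
    mat[np.ix_(mito_rows, hm_idx)] *= int(round(mito_factor))

    for j in lu_idx:
        col = mat[:, j]
        total = col.sum()
        target = rng.integers(umi_ceiling // 10, int(0.8 * umi_ceiling))
        p = min(0.95, target / max(total, 1))
        thinned = rng.binomial(col, p)
        while thinned.sum() >= umi_ceiling:  # guard against binomial overshoot
            thinned = rng.binomial(thinned, 0.8)
        mat[:, j] = thinned

    cells.loc[cells.index[hm_idx], "planted_high_mito"] = True
    cells.loc[cells.index[lu_idx], "planted_low_umi"] = True
    cells.attrs["genes"] = genes
    return sp.csr_matrix(mat), cells


def simulate_abundance_table(
    rng: np.random.Generator,
    n_pools_per_geno: int = 4,
    n_types: int = 8,
    cells_per_sample: int = 2000,
    ko_multiplier: Optional[float] = None,
) -> pd.DataFrame:
    """Sample-level cell-type counts for a two-genotype chimera cohort.

    Host and injected compartments share a Dirichlet-drawn base
    composition; in knockout pools the injected compartment's frequency
    of the first cell type is scaled by ``ko_multiplier`` (None = null).
    One row per sample with ``pool``/``tdTom``/``genotype`` covariates,
    ready for differential abundance testing.
    """
    base = rng.dirichlet(np.full(n_types, 5.0))
    rows = []
    for geno in ("KO", "WT"):
        for p in range(n_pools_per_geno):
            pool = f"{geno}_pool{p}"
            for td in ("tdTom+", "tdTom-"):
                probs = base.copy()
                if ko_multiplier is not None and geno == "KO" and td == "tdTom+":
                    probs[0] *= ko_multiplier
                    probs = probs / probs.sum()
                counts = rng.multinomial(cells_per_sample, probs)
                row = dict(
                    sample=f"{pool}_{td}", pool=pool, tdTom=td, genotype=geno
                )
                row.update({f"ct{t}": int(c) for t, c in enumerate(counts)})
                rows.append(row)
    return pd.DataFrame(rows)


def simulate_ratio_cohort(
    rng: np.random.Generator,
    n_pools: int = 3,
    n_cells: int = 200,
    ko_post_odds: float = 1.0,
) -> pd.DataFrame:
    """Per-cell table for the lineage-ratio permutation test.

    Trajectory labels (two lineages of interest plus a remainder) are
    drawn independently of tdTom status except in KO pools, where the
    injected compartment's odds of the second lineage are scaled by
    ``ko_post_odds`` (1.0 = null).
    """
    frames = []
    for geno in ("KO", "WT"):
        for p in range(n_pools):
            inj = rng.random(n_cells) < 0.5
            probs = np.array([0.35, 0.35, 0.30])  # lineage A, B, other
            labels = []
            for i in range(n_cells):
                pr = probs.copy()
                if geno == "KO" and inj[i] and ko_post_odds != 1.0:
                    pr[1] *= ko_post_odds
                    pr /= pr.sum()
                labels.append(rng.choice(["A", "B", "other"], p=pr))
            frames.append(
                pd.DataFrame(
                    {
                        "cell": [f"{geno}{p}_{i}" for i in range(n_cells)],
                        "pool": f"{geno}_pool{p}",
                        "tdTom": np.where(inj, "tdTom+", "tdTom-"),
                        "genotype": geno,
                        "trajectory": labels,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
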