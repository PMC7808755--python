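"""Session fixtures: the default synthetic study conditions, processed once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somitraj import manifold, qc, transport
from somitraj.simulate import SimConfig, simulate_atlas, simulate_chimera

FATES = ["anterior_somitic", "posterior_somitic", "NMP"]


@pytest.fixture(scope="session")
def atlas_sim():
    """Default synthetic atlas: 9 stages x 300 cells, 2000 genes, seed 7."""
    cfg = SimConfig(n_cells_per_timepoint=300, n_genes=2000, seed=7)
    counts, cells, truth = simulate_atlas(cfg)
    return cfg, counts, cells, truth


@pytest.fixture(scope="session")
def atlas_processed(atlas_sim):
    """Atlas carried through QC, normalisation, HVGs, PCA, MNN and transport."""
    cfg, counts, cells, truth = atlas_sim
    genes = cells.attrs["genes"]
    counts, cells, _ = qc.filter_min_umi(counts, cells)
    sf = qc.estimate_size_factors(counts)
    expr = qc.lognormalize(counts, sf)
    hvgs = qc.select_hvgs(expr, genes)
    emb = manifold.compute_pca(
        expr, genes, cells["cell"], hvgs=hvgs,
        n_components=min(50, int(hvgs["selected"].sum())),
    )
    plan = manifold.build_merge_order(cells, mode="atlas")
    corrected = manifold.mnn_correct(emb, cells["sample"], plan)
    with np.errstate(all="ignore"):
        tplan = transport.fit_couplings(corrected, cells, epsilon=0.05)
    last = int(cells["stage_index"].max())
    final = cells[cells["stage_index"] == last]
    endpoint = pd.DataFrame(
        {f: (final["cell_type"] == f).to_numpy(float) for f in FATES},
        index=final["cell"],
    )
    masses = transport.pull_back_mass(tplan, endpoint)
    assignment = transport.assign_trajectories(masses, rho=0.9)
    return dict(
        config=cfg,
        counts=counts,
        cells=cells,
        truth=truth,
        genes=genes,
        sf=sf,
        expr=expr,
        hvgs=hvgs,
        pca=emb,
        corrected=corrected,
        transport=tplan,
        masses=masses,
        assignment=assignment,
    )


@pytest.fixture(scope="session")
def wt_chimera_sim(atlas_sim):
    """Chimera cells drawn from the atlas generative model (no fate bias)."""
    cfg, *_ = atlas_sim
    ccfg = SimConfig(n_cells_per_timepoint=300, n_genes=2000, seed=11)
    return simulate_chimera(ccfg, {}, n_pools=2)
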