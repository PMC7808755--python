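"""End-to-end pipeline: configuration, stage execution, artifact manifest.

Each stage reads the artifacts of earlier stages from the output
directory, computes, and writes its own artifacts as plain-text tables,
so any stage can be rerun in isolation and a complete run is fully
described by the resolved configuration snapshot plus the manifest of
output checksums.
"""

from __future__ import annotations

import json
import os
import warnings

import numpy as np
import pandas as pd
import yaml

from . import chimera as ch
from . import io as sio
from . import manifold, qc, trajstats, transport
from .simulate import SimConfig, simulate_atlas, simulate_chimera

DEFAULT_CONFIG = {
    "seed": 0,
    "out": "pipeline_out",
    "simulate": {
        "n_timepoints": 9,
        "n_cells_per_timepoint": 300,
        "n_genes": 2000,
        "n_fates": 3,
        "n_bystander_types": 2,
        "latent_dim": 10,
        "batch_effect_sd": 0.15,
        "nb_dispersion": 0.1,
        "mito_gene_count": 10,
        "ko_bias": {"posterior_somitic": 0.1, "NMP": 2.0},
        "n_pools_ko": 3,
        "n_pools_wt": 3,
    },
    "qc": {"min_umi": 5000, "mito_alpha": 0.05},
    "normalize": {"method": "pooled_deconvolution"},
    "hvg": {"span": 0.05, "alpha": 0.05},
    "integrate": {"n_components": 50, "k_mnn": 20},
    "order": {"n_diffusion_components": 20, "k_kernel": 30},
    "transport": {"epsilon": 0.05, "rho": 0.9},
    "diverge": {"alpha_variability": 0.1, "fdr_pairwise": 0.01},
    "map": {"n_per_stage": 10000, "k_label": 10, "k_dpt": 5},
    "abundance": {"alpha_bh": 0.1},
    "ratio_test": {
        "n_perm": 1000,
        "traj_a": "NMP",
        "traj_b": "posterior_somitic",
    },
}

STAGES = (
    "simulate",
    "qc",
    "hvg",
    "integrate",
    "order",
    "transport",
    "diverge",
    "map",
    "abundance",
    "ratio_test",
)


def _merge_validate(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in (override or {}).items():
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {path}{key}")
        if key == "ko_bias":  # free-form fate -> multiplier mapping
            out[key] = dict(val)
        elif isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"configuration key {path}{key} must be a mapping")
            out[key] = _merge_validate(defaults[key], val, path=f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Resolved pipeline configuration: defaults, file values, overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge_validate(cfg, user)
    if overrides:
        cfg = _merge_validate(cfg, overrides)
    return cfg


class Pipeline:
    def __init__(self, config: dict):
        self.cfg = config
        self.out = config["out"]
        os.makedirs(self.out, exist_ok=True)

    # -- helpers ---------------------------------------------------------
    def path(self, *parts) -> str:
        p = os.path.join(self.out, *parts)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        return p

    def _load_counts(self, which: str):
        counts, genes, barcodes = sio.read_mtx_dir(os.path.join(self.out, which))
        cells = sio.read_table(self.path(which, "cells.tsv"))
        cells.attrs["genes"] = genes
        return counts, genes, cells

    def _expression(self, which: str = "atlas_qc"):
        counts, genes, cells = self._load_counts(which)
        sf = sio.read_table(self.path("qc", f"{which}_size_factors.tsv"))
        expr = qc.lognormalize(counts, qc.SizeFactors(sf["size_factor"].to_numpy(),
                                                      sf["method"].iloc[0]))
        return expr, genes, cells

    # -- stages ----------------------------------------------------------
    def stage_simulate(self):
        sim = self.cfg["simulate"]
        sim_kwargs = {
            k: v
            for k, v in sim.items()
            if k not in ("ko_bias", "n_pools_ko", "n_pools_wt")
        }
        config = SimConfig(seed=self.cfg["seed"], **sim_kwargs)
        counts, cells, truth = simulate_atlas(config)
        genes = cells.attrs["genes"]
        sio.write_mtx_dir(self.path("atlas"), counts, genes, cells["cell"])
        sio.write_table(self.path("atlas", "cells.tsv"), cells)
        sio.write_table(self.path("atlas", "truth_cells.tsv"), truth.cells)
        sio.write_table(self.path("atlas", "truth_genes.tsv"), truth.genes)

        for tag, bias, pools, seed_off in (
            ("chimera_ko", sim["ko_bias"], sim["n_pools_ko"], 1),
            ("chimera_wt", {}, sim["n_pools_wt"], 2),
        ):
            ccfg = SimConfig(seed=self.cfg["seed"] + seed_off, **sim_kwargs)
            ccounts, ccells, ctruth = simulate_chimera(ccfg, bias, n_pools=pools)
            sio.write_mtx_dir(self.path(tag), ccounts, genes, ccells["cell"])
            sio.write_table(self.path(tag, "cells.tsv"), ccells)
            sio.write_table(self.path(tag, "truth_cells.tsv"), ctruth.cells)

    def stage_qc(self):
        params = self.cfg["qc"]
        for which in ("atlas", "chimera_ko", "chimera_wt"):
            counts, genes, cells = self._load_counts(which)
            counts, cells, umi_report = qc.filter_min_umi(
                counts, cells, min_umi=params["min_umi"]
            )
            mito_report = qc.flag_mito_outliers(
                counts, genes, alpha=params["mito_alpha"], cells=cells
            )
            keep = mito_report.table["keep"].to_numpy()
            counts, cells = counts[:, keep], cells.loc[keep].reset_index(drop=True)
            cells.attrs["genes"] = genes
            report = umi_report.table.merge(mito_report.table, on="cell", how="left")
            sio.write_table(self.path("qc", f"{which}_report.tsv"), report)
            sio.write_mtx_dir(self.path(f"{which}_qc"), counts, genes, cells["cell"])
            sio.write_table(self.path(f"{which}_qc", "cells.tsv"), cells)
            sf = qc.estimate_size_factors(counts, method=self.cfg["normalize"]["method"])
            sio.write_table(
                self.path("qc", f"{which}_qc_size_factors.tsv"),
                pd.DataFrame(
                    {"cell": cells["cell"], "size_factor": sf.values, "method": sf.method}
                ),
            )

    def stage_hvg(self):
        expr, genes, _ = self._expression("atlas_qc")
        hvgs = qc.select_hvgs(
            expr, genes, span=self.cfg["hvg"]["span"], alpha=self.cfg["hvg"]["alpha"]
        )
        sio.write_table(self.path("hvg", "hvg.tsv"), hvgs)

    def stage_integrate(self):
        expr, genes, cells = self._expression("atlas_qc")
        hvgs = sio.read_table(self.path("hvg", "hvg.tsv"))
        emb = manifold.compute_pca(
            expr, genes, cells["cell"], hvgs=hvgs,
            n_components=min(self.cfg["integrate"]["n_components"],
                             int(hvgs["selected"].sum())),
        )
        plan = manifold.build_merge_order(cells, mode="atlas")
        corrected = manifold.mnn_correct(
            emb, cells["sample"], plan, k=self.cfg["integrate"]["k_mnn"]
        )
        self._save_embedding("atlas_pca", emb)
        self._save_embedding("atlas_corrected", corrected)

    def _save_embedding(self, name: str, emb: manifold.Embedding):
        df = pd.DataFrame(
            emb.coords, columns=[f"PC{i + 1}" for i in range(emb.coords.shape[1])]
        )
        df.insert(0, "cell", emb.cell_ids)
        df.attrs["space"] = emb.space
        sio.write_table(self.path("embed", f"{name}.tsv"), df)
        if emb.loadings is not None:
            ld = pd.DataFrame(
                emb.loadings,
                columns=[f"PC{i + 1}" for i in range(emb.loadings.shape[1])],
            )
            ld.insert(0, "gene", emb.genes)
            ld.insert(1, "gene_mean", emb.gene_means)
            sio.write_table(self.path("embed", f"{name}_loadings.tsv"), ld)

    def _load_embedding(self, name: str, space: str) -> manifold.Embedding:
        df = sio.read_table(self.path("embed", f"{name}.tsv"))
        emb = manifold.Embedding(
            cell_ids=df["cell"].to_numpy(),
            coords=df.drop(columns="cell").to_numpy(float),
            space=space,
        )
        lpath = self.path("embed", f"{name}_loadings.tsv")
        if os.path.exists(lpath):
            ld = sio.read_table(lpath)
            emb.genes = ld["gene"].to_numpy(object)
            emb.gene_means = ld["gene_mean"].to_numpy(float)
            emb.loadings = ld.drop(columns=["gene", "gene_mean"]).to_numpy(float)
        return emb

    def stage_order(self):
        emb = self._load_embedding("atlas_corrected", "pca_corrected")
        cells = sio.read_table(self.path("atlas_qc", "cells.tsv"))
        # the one-dimensional ordering lives on the axial-elongation
        # continuum; transcriptionally static bystander types are
        # disconnected islands and are left out of the diffusion map
        on_traj = ~cells["cell_type"].str.startswith("bystander")
        keep_ids = set(cells.loc[on_traj, "cell"])
        mask = np.array([c in keep_ids for c in emb.cell_ids])
        sub = manifold.Embedding(
            emb.cell_ids[mask], emb.coords[mask], emb.space
        )
        dm = manifold.diffusion_map(
            sub,
            n_components=self.cfg["order"]["n_diffusion_components"],
            k_kernel=self.cfg["order"]["k_kernel"],
        )
        # root population: least-differentiated cells (trunk progenitors
        # of the earliest stage stand in for the spinal-cord root)
        first = cells["stage_index"].min()
        root_group = cells.loc[
            on_traj & (cells["stage_index"] == first), "cell"
        ]
        dm = manifold.compute_dpt(dm, root_group)
        sio.write_table(
            self.path("order", "dpt.tsv"),
            pd.DataFrame({"cell": dm.cell_ids, "dpt": dm.dpt,
                          "dc1": dm.components[:, 0]}),
        )

    def stage_transport(self):
        emb = self._load_embedding("atlas_corrected", "pca_corrected")
        cells = sio.read_table(self.path("atlas_qc", "cells.tsv"))
        plan = transport.fit_couplings(
            emb, cells, epsilon=self.cfg["transport"]["epsilon"]
        )
        last = cells["stage_index"].max()
        final = cells[cells["stage_index"] == last]
        fates = [
            f
            for f in ("anterior_somitic", "posterior_somitic", "NMP")
            if (final["cell_type"] == f).any()
        ]
        endpoint = pd.DataFrame(
            {f: (final["cell_type"] == f).to_numpy(float) for f in fates},
            index=final["cell"],
        )
        masses = transport.pull_back_mass(plan, endpoint)
        assignment = transport.assign_trajectories(
            masses, rho=self.cfg["transport"]["rho"]
        )
        tab = assignment.table.copy()
        # primary trajectory label = fate of largest mass (or unassigned)
        prim = tab[fates].to_numpy().argmax(axis=1)
        tab["trajectory"] = np.where(
            tab["assigned_fates"] == "", "unassigned",
            np.asarray(fates, dtype=object)[prim],
        )
        sio.write_table(self.path("transport", "assignments.tsv"), tab)
        diag = pd.DataFrame(
            [
                dict(pair=f"{t0}-{t1}", n_iter=c.n_iter,
                     residual=c.marginal_residual, converged=c.converged)
                for (t0, t1), c in plan.couplings.items()
            ]
        )
        sio.write_table(self.path("transport", "diagnostics.tsv"), diag)

    def stage_diverge(self):
        expr, genes, cells = self._expression("atlas_qc")
        tab = sio.read_table(self.path("transport", "assignments.tsv"))
        tab["assigned_fates"] = tab["assigned_fates"].fillna("")
        assignment = transport.TrajectoryAssignment(
            rho=self.cfg["transport"]["rho"], table=tab
        )
        hvgs = sio.read_table(self.path("hvg", "hvg.tsv"))
        hvg_names = hvgs.loc[hvgs["selected"], "gene"].tolist()
        curves = trajstats.trajectory_mean_curves(expr, genes, cells, assignment)
        frames = []
        for fate in curves.fates:
            frames.append(
                trajstats.test_variability_along(
                    curves, fate, genes=hvg_names,
                    alpha=self.cfg["diverge"]["alpha_variability"],
                )
            )
        variable = sorted(
            set().union(*[set(f.loc[f["selected"], "gene"]) for f in frames])
        )
        for i, fa in enumerate(curves.fates):
            for fb in curves.fates[i + 1 :]:
                frames.append(
                    trajstats.test_pairwise_divergence(
                        curves, (fa, fb), genes=variable,
                        fdr=self.cfg["diverge"]["fdr_pairwise"],
                    )
                )
        sio.write_table(
            self.path("diverge", "tests.tsv"), pd.concat(frames, ignore_index=True)
        )

    def stage_map(self):
        atlas_expr, genes, atlas_cells = self._expression("atlas_qc")
        dpt = sio.read_table(self.path("order", "dpt.tsv")).set_index("cell")["dpt"]
        traj = sio.read_table(self.path("transport", "assignments.tsv")).set_index(
            "cell"
        )["trajectory"]
        atlas_cells = atlas_cells.copy()
        atlas_cells["trajectory"] = (
            atlas_cells["cell"].map(traj).fillna("unassigned")
        )
        sub = ch.subsample_atlas(
            atlas_cells, n_per_stage=self.cfg["map"]["n_per_stage"],
            seed=self.cfg["seed"] + 10,
        )
        sub_idx = atlas_cells["cell"].isin(sub["cell"]).to_numpy()
        hvgs = sio.read_table(self.path("hvg", "hvg.tsv"))

        # shared PC space: atlas-centred loadings over the atlas HVGs
        shared = manifold.compute_pca(
            atlas_expr[:, sub_idx], genes, sub["cell"], hvgs=hvgs,
            n_components=min(self.cfg["integrate"]["n_components"],
                             int(hvgs["selected"].sum())),
        )
        plan = manifold.build_merge_order(sub, mode="atlas")
        corrected = manifold.mnn_correct(
            shared, sub["sample"], plan, k=self.cfg["integrate"]["k_mnn"]
        )
        for tag in ("chimera_ko", "chimera_wt"):
            chim_expr, cgenes, chim_cells = self._expression(f"{tag}_qc")
            chim_emb = manifold.project_onto(shared, chim_expr, cgenes,
                                             chim_cells["cell"])
            mapping = ch.map_to_atlas(corrected, chim_emb, chim_cells["sample"])
            labels = ch.transfer_labels(
                mapping, sub, k=self.cfg["map"]["k_label"],
                label_cols=("cell_type", "timepoint"),
            )
            labels["mapped_dpt"] = ch.transfer_dpt(
                mapping, dpt, k=self.cfg["map"]["k_dpt"]
            )
            out = chim_cells.merge(labels, on="cell")
            sio.write_table(self.path("map", f"{tag}_mapped.tsv"), out)

    def _abundance_table(self) -> pd.DataFrame:
        rows = []
        for tag, geno in (("chimera_ko", "KO"), ("chimera_wt", "WT")):
            mapped = sio.read_table(self.path("map", f"{tag}_mapped.tsv"))
            if "excluded" in mapped:
                mapped = mapped[~mapped["excluded"]]
            for (sample, pool, td), sub in mapped.groupby(["sample", "pool", "tdTom"]):
                row = dict(sample=f"{tag}_{sample}", pool=f"{tag}_{pool}",
                           tdTom=td, genotype=geno)
                for ct, n in sub["mapped_cell_type"].value_counts().items():
                    row[ct] = int(n)
                rows.append(row)
        table = pd.DataFrame(rows).fillna(0)
        count_cols = [c for c in table.columns
                      if c not in ("sample", "pool", "tdTom", "genotype")]
        table[count_cols] = table[count_cols].astype(int)
        return table

    def stage_abundance(self):
        table = self._abundance_table()
        sio.write_table(self.path("abundance", "counts.tsv"), table)
        res = ch.test_differential_abundance(
            table, alpha_bh=self.cfg["abundance"]["alpha_bh"]
        )
        sio.write_table(self.path("abundance", "tests.tsv"), res)

    def stage_ratio_test(self):
        params = self.cfg["ratio_test"]
        frames = []
        for tag, geno in (("chimera_ko", "KO"), ("chimera_wt", "WT")):
            mapped = sio.read_table(self.path("map", f"{tag}_mapped.tsv"))
            if "excluded" in mapped:
                mapped = mapped[~mapped["excluded"]]
            mapped = mapped.copy()
            mapped["pool"] = tag + "_" + mapped["pool"]
            mapped["genotype"] = geno
            frames.append(mapped)
        cells = pd.concat(frames, ignore_index=True)
        # trajectory membership via the 10-NN majority trajectory state
        traj_source = (
            "mapped_trajectory" if "mapped_trajectory" in cells
            else "mapped_cell_type"
        )
        cells["trajectory"] = cells[traj_source]
        res = ch.permutation_ratio_test(
            cells, params["traj_a"], params["traj_b"],
            n_perm=params["n_perm"], seed=self.cfg["seed"] + 20,
        )
        out = {k: v for k, v in res.items() if k != "perm_stats"}
        out["pool_ratios"] = {str(k): float(v) for k, v in out["pool_ratios"].items()}
        with open(self.path("ratio_test", "result.json"), "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)

    # -- driver ----------------------------------------------------------
    def run(self, stages=None) -> dict:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        snapshot = {k: v for k, v in self.cfg.items() if k != "out"}
        with open(self.path("config_resolved.yaml"), "w") as fh:
            yaml.safe_dump(snapshot, fh, sort_keys=True)
        done = []
        for stage in STAGES:
            if stage not in stages:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                getattr(self, f"stage_{stage}")()
            done.append(stage)
        manifest = self.build_manifest(done)
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest

    def build_manifest(self, stages) -> dict:
        files = {}
        for root, _, names in os.walk(self.out):
            for name in sorted(names):
                if name == "manifest.json":
                    continue
                full = os.path.join(root, name)
                rel = os.path.relpath(full, self.out)
                files[rel] = sio.checksum(full)
        return {"seed": self.cfg["seed"], "stages": stages, "files": files}


def run_pipeline(config: dict, stages=None) -> dict:
    """Execute the pipeline and return the artifact manifest."""
    return Pipeline(config).run(stages=stages)
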