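"""PCA, merge order, MNN correction, clustering, diffusion maps and DPT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from somitraj import manifold


def _embedding(X, ids=None, space="pca_corrected"):
    ids = ids if ids is not None else [f"c{i}" for i in range(len(X))]
    return manifold.Embedding(cell_ids=ids, coords=np.asarray(X, float), space=space)


class TestPCA:
    def _data(self, rng, n_genes=60, n_cells=120, rank=None):
        X = rng.normal(size=(n_genes, n_cells))
        if rank is not None:
            A = rng.normal(size=(n_genes, rank))
            B = rng.normal(size=(rank, n_cells))
            X = A @ B + rng.normal(0, 0, size=(n_genes, n_cells))
        return X

    def test_rank_deficient_data_has_zero_trailing_variance(self):
        rng = np.random.default_rng(0)
        X = self._data(rng, rank=3)
        emb = manifold.compute_pca(
            X, [f"g{i}" for i in range(60)], [f"c{i}" for i in range(120)],
            n_components=50,
        )
        var = emb.coords.var(axis=0)
        assert var[3:].max() <= 1e-8 * var[0]

    def test_duplicated_cells_get_identical_coordinates(self):
        rng = np.random.default_rng(1)
        X = self._data(rng)
        Xd = np.hstack([X, X[:, :5]])
        emb = manifold.compute_pca(
            Xd, [f"g{i}" for i in range(60)], [f"c{i}" for i in range(125)],
            n_components=20,
        )
        np.testing.assert_allclose(emb.coords[:5], emb.coords[120:], atol=1e-8)

    def test_reconstruction_error_nested_in_components(self):
        rng = np.random.default_rng(2)
        X = self._data(rng)
        gm = X.mean(axis=1, keepdims=True)

        def recon_err(k):
            emb = manifold.compute_pca(
                X, [f"g{i}" for i in range(60)], [f"c{i}" for i in range(120)],
                n_components=k,
            )
            approx = (emb.coords @ emb.loadings.T).T + gm
            return ((X - approx) ** 2).sum()

        assert recon_err(50) <= recon_err(10) + 1e-9

    def test_fewer_cells_than_components_raises(self):
        with pytest.raises(ValueError):
            manifold.compute_pca(
                np.ones((30, 10)), [f"g{i}" for i in range(30)],
                [f"c{i}" for i in range(10)], n_components=20,
            )

    def test_embedding_invariant_under_cell_permutation(self):
        rng = np.random.default_rng(3)
        X = self._data(rng)
        ids = [f"c{i}" for i in range(120)]
        emb = manifold.compute_pca(
            X, [f"g{i}" for i in range(60)], ids, n_components=10
        )
        perm = rng.permutation(120)
        emb_p = manifold.compute_pca(
            X[:, perm], [f"g{i}" for i in range(60)],
            [ids[i] for i in perm], n_components=10,
        )
        np.testing.assert_allclose(emb.coords[perm], emb_p.coords, atol=1e-8)


class TestMergeOrder:
    def test_atlas_order_oldest_first_largest_within_stage(self):
        cells = pd.DataFrame(
            {
                "cell": [f"c{i}" for i in range(1400)],
                "sample": ["s1"] * 500 + ["s2"] * 800 + ["s3"] * 100,
                "stage_index": [1] * 1300 + [0] * 100,
            }
        )
        plan = manifold.build_merge_order(cells, mode="atlas")
        assert plan.order == ["s3", "s2", "s1"]

    def test_chimera_order_within_genotype_then_across(self):
        cells = pd.DataFrame(
            {
                "cell": [f"c{i}" for i in range(100)],
                "sample": ["a1"] * 30 + ["a2"] * 40 + ["b1"] * 20 + ["b2"] * 10,
                "genotype": ["KO"] * 70 + ["WT"] * 30,
            }
        )
        plan = manifold.build_merge_order(cells, mode="chimera")
        assert plan.order == ["a2", "a1", "b1", "b2"]

    def test_singleton_and_tie_rules(self):
        cells = pd.DataFrame(
            {"cell": ["x"], "sample": ["only"], "stage_index": [0]}
        )
        assert manifold.build_merge_order(cells).order == ["only"]
        tied = pd.DataFrame(
            {
                "cell": [f"c{i}" for i in range(4)],
                "sample": ["b", "b", "a", "a"],
                "stage_index": [0] * 4,
            }
        )
        assert manifold.build_merge_order(tied).order == ["a", "b"]

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            manifold.build_merge_order(pd.DataFrame({"cell": ["x"]}))


class TestMNN:
    def _two_batches(self, rng, offset, n=200, d=10, noise=0.05):
        """The second batch carries the same cell states shifted by a
        constant batch vector (plus small technical noise)."""
        ref = rng.normal(size=(n, d))
        new = ref + offset + rng.normal(0, noise, size=(n, d))
        X = np.vstack([ref, new])
        batches = np.array(["ref"] * n + ["new"] * n)
        return X, batches

    def test_constant_offset_removed(self):
        """Same-population batches separated by a planted batch vector are
        fully aligned by repeated match-and-shift rounds."""
        rng = np.random.default_rng(5)
        offset = np.zeros(10)
        offset[0] = 4.0
        X, batches = self._two_batches(rng, offset)
        emb = _embedding(X)
        plan = manifold.MergePlan(["ref", "new"])
        spread = float(
            np.sqrt(np.mean(np.sum((X[:200] - X[:200].mean(0)) ** 2, axis=1)))
        )
        out = manifold.mnn_correct(
            emb, batches, plan, k=20, sigma=spread, max_rounds=8
        )
        gap = out.coords[batches == "new"].mean(0) - out.coords[
            batches == "ref"
        ].mean(0)
        assert np.linalg.norm(gap) <= 0.1 * np.linalg.norm(offset)

    def test_reference_batch_untouched(self):
        rng = np.random.default_rng(6)
        X, batches = self._two_batches(rng, 2.0)
        emb = _embedding(X)
        out = manifold.mnn_correct(emb, batches, manifold.MergePlan(["ref", "new"]), k=15)
        np.testing.assert_array_equal(
            out.coords[batches == "ref"], emb.coords[batches == "ref"]
        )

    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 5))
        emb = _embedding(X)
        out = manifold.mnn_correct(
            emb, np.array(["b"] * 50), manifold.MergePlan(["b"])
        )
        np.testing.assert_array_equal(out.coords, emb.coords)
        assert out.space == "pca_corrected"

    def test_rerun_with_same_plan_identical(self):
        rng = np.random.default_rng(8)
        X, batches = self._two_batches(rng, 1.0)
        emb = _embedding(X)
        plan = manifold.MergePlan(["ref", "new"])
        a = manifold.mnn_correct(emb, batches, plan, k=10)
        b = manifold.mnn_correct(emb, batches, plan, k=10)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_plan_mismatch_raises(self):
        rng = np.random.default_rng(9)
        X, batches = self._two_batches(rng, 1.0)
        with pytest.raises(ValueError):
            manifold.mnn_correct(
                _embedding(X), batches, manifold.MergePlan(["ref"])
            )


class TestClustering:
    def test_two_separated_blobs_perfectly_recovered(self):
        rng = np.random.default_rng(10)
        X = np.vstack(
            [rng.normal(0, 1, size=(100, 5)), rng.normal(8, 1, size=(100, 5))]
        )
        truth = np.array([0] * 100 + [1] * 100)
        labels = manifold.cluster_cells(_embedding(X), k_graph=15, seed=42)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_one_blob_one_cluster(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(80, 4))
        labels = manifold.cluster_cells(_embedding(X), k_graph=20, seed=42)
        assert len(np.unique(labels)) == 1

    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(150, 6))
        a = manifold.cluster_cells(_embedding(X), k_graph=10, seed=1)
        b = manifold.cluster_cells(_embedding(X), k_graph=10, seed=1)
        assert np.array_equal(a, b)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            manifold.cluster_cells(_embedding(np.ones((5, 2))), k_graph=5)


def _chain_embedding(n=60, d=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, d))
    X[:, 0] = np.arange(n, dtype=float)
    X += rng.normal(0, noise, size=X.shape)
    return _embedding(X)


class TestDiffusion:
    def test_first_component_monotone_on_chain(self):
        emb = _chain_embedding()
        dm = manifold.diffusion_map(emb, n_components=5, k_kernel=10)
        rho = stats.spearmanr(dm.components[:, 0], np.arange(60)).statistic
        assert abs(rho) == 1.0

    def test_eigenvalues_descending_in_unit_interval(self):
        emb = _chain_embedding(noise=0.05, seed=3)
        dm = manifold.diffusion_map(emb, n_components=8, k_kernel=10)
        assert (np.diff(dm.eigenvalues) <= 1e-12).all()
        assert (dm.eigenvalues > 0).all() and (dm.eigenvalues <= 1.0 + 1e-9).all()

    def test_disconnected_graph_reported_with_sizes(self):
        X = np.vstack([np.zeros((10, 2)), np.full((15, 2), 1e6)])
        with pytest.raises(RuntimeError, match="component sizes"):
            manifold.diffusion_map(_embedding(X), n_components=3, k_kernel=3)


class TestDPT:
    def test_root_distance_zero_and_nonnegative(self):
        emb = _chain_embedding()
        dm = manifold.diffusion_map(emb, n_components=5, k_kernel=10)
        res = manifold.compute_dpt(dm, ["c0"])
        assert res.dpt[list(res.cell_ids).index(res.root)] == 0.0
        assert (res.dpt >= 0).all()

    def test_chain_order_recovered(self):
        emb = _chain_embedding()
        dm = manifold.diffusion_map(emb, n_components=5, k_kernel=10)
        res = manifold.compute_dpt(dm, ["c0", "c1"])
        rho = stats.spearmanr(res.dpt, np.arange(60)).statistic
        assert abs(rho) >= 0.99

    def test_branching_topology_orders_group_medians(self):
        """Cells laid out spinal-cord -> NMP -> somite along one axis must
        order their group DPT medians accordingly from a spinal-cord root."""
        rng = np.random.default_rng(20)
        groups = {"spinal_cord": (0.0, 60), "NMP": (6.0, 60), "somitic": (12.0, 60)}
        X, labels, ids = [], [], []
        k = 0
        for g, (center, n) in groups.items():
            pts = rng.normal(0, 0.8, size=(n, 3))
            pts[:, 0] += center + rng.uniform(-2.5, 2.5, size=n)
            X.append(pts)
            labels += [g] * n
            ids += [f"{g}{k}_{i}" for i in range(n)]
            k += 1
        emb = _embedding(np.vstack(X), ids=ids)
        dm = manifold.diffusion_map(emb, n_components=10, k_kernel=15)
        root_group = [i for i, l in zip(ids, labels) if l == "spinal_cord"]
        res = manifold.compute_dpt(dm, root_group)
        med = pd.Series(res.dpt).groupby(np.array(labels)).median()
        assert med["spinal_cord"] < med["NMP"] < med["somitic"]

    def test_dpt_matches_independent_implementation(self):
        """Cross-check the DPT ordering against scanpy's diffusion pseudotime
        on the same corrected coordinates (independent code path)."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        emb = _chain_embedding(noise=0.1, seed=4)
        dm = manifold.diffusion_map(emb, n_components=10, k_kernel=10)
        res = manifold.compute_dpt(dm, ["c0"])

        adata = ad.AnnData(X=emb.coords.astype(np.float32))
        adata.obsm["X_pca"] = emb.coords
        sc.pp.neighbors(adata, n_neighbors=10, use_rep="X_pca")
        sc.tl.diffmap(adata)
        adata.uns["iroot"] = 0
        sc.tl.dpt(adata)
        rho = stats.spearmanr(res.dpt, adata.obs["dpt_pseudotime"]).statistic
        assert abs(rho) >= 0.95


class TestWindowedProfile:
    def test_constant_signal_constant_profile(self):
        dpt = np.linspace(0, 1, 50)
        _, prof = manifold.windowed_profile(np.full(50, 3.3), dpt)
        np.testing.assert_allclose(prof, 3.3)

    def test_full_window_gives_global_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=40)
        dpt = rng.uniform(size=40)
        _, prof = manifold.windowed_profile(vals, dpt, window_frac=1.0)
        np.testing.assert_allclose(prof, vals.mean())

    def test_step_function_smoothed_to_ramp_of_window_width(self):
        n = 2001
        dpt = np.linspace(0, 1, n)
        vals = (dpt > 0.5).astype(float)
        centers, prof = manifold.windowed_profile(
            vals, dpt, window_frac=0.10, n_points=201
        )
        # ramp spans [0.45, 0.55]; flat at 0 before, 1 after
        assert prof[centers < 0.44].max() == 0.0
        assert prof[centers > 0.56].min() == 1.0
        inside = (centers > 0.46) & (centers < 0.54)
        expected = (centers[inside] - 0.45) / 0.10
        np.testing.assert_allclose(prof[inside], expected, atol=0.02)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            manifold.windowed_profile(np.ones(5), np.arange(5.0), window_frac=0.0)
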