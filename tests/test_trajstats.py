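"""Trajectory curves, polynomial divergence tests, DE, scores, overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somitraj import trajstats
from somitraj.transport import TrajectoryAssignment
from somitraj.trajstats import (
    TrajectoryCurves,
    differential_expression,
    overlap_enrichment,
    signature_score,
    trajectory_mean_curves,
)
from somitraj.trajstats import test_pairwise_divergence as pairwise_divergence
from somitraj.trajstats import test_variability_along as variability_along


def _curves(values: dict, stages=None):
    genes = np.array(
        [f"G{i}" for i in range(next(iter(values.values())).shape[0])], dtype=object
    )
    stages = stages if stages is not None else list(range(9))
    return TrajectoryCurves(
        fates=list(values),
        stages=stages,
        genes=genes,
        values={k: np.asarray(v, float) for k, v in values.items()},
        cell_counts={k: np.full(len(stages), 50) for k in values},
    )


class TestMeanCurves:
    def _assignment(self, cells, fates_of):
        rows = []
        for i, c in enumerate(cells["cell"]):
            rows.append(
                {
                    "cell": c,
                    "stage_index": cells["stage_index"].iloc[i],
                    "fateA": 1.0,
                    "fateB": 0.0,
                    "assigned_fates": fates_of(i),
                }
            )
        return TrajectoryAssignment(rho=0.9, table=pd.DataFrame(rows))

    def test_single_cell_curve_equals_cell_values(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(5, 2))
        cells = pd.DataFrame({"cell": ["a", "b"], "stage_index": [0, 1]})
        assign = self._assignment(cells, lambda i: "fateA")
        curves = trajectory_mean_curves(
            expr, [f"G{i}" for i in range(5)], cells, assign
        )
        np.testing.assert_allclose(curves.values["fateA"][:, 0], expr[:, 0])
        np.testing.assert_allclose(curves.values["fateA"][:, 1], expr[:, 1])

    def test_multi_assigned_cells_count_in_both_curves(self):
        expr = np.array([[1.0, 3.0]])
        cells = pd.DataFrame({"cell": ["a", "b"], "stage_index": [0, 0]})
        assign = self._assignment(
            cells, lambda i: "fateA;fateB" if i == 0 else "fateA"
        )
        curves = trajectory_mean_curves(expr, ["G0"], cells, assign)
        assert curves.values["fateA"][0, 0] == pytest.approx(2.0)
        assert curves.values["fateB"][0, 0] == pytest.approx(1.0)

    def test_planted_linear_slope_recovered(self):
        rng = np.random.default_rng(1)
        n_per = 200
        stages = np.repeat(np.arange(9), n_per)
        slope = 0.7
        expr = (slope * stages + rng.normal(0, 0.5, size=stages.size))[None, :]
        cells = pd.DataFrame(
            {"cell": [f"c{i}" for i in range(stages.size)], "stage_index": stages}
        )
        assign = self._assignment(cells, lambda i: "fateA")
        curves = trajectory_mean_curves(expr, ["G0"], cells, assign)
        fitted = np.polyfit(np.arange(9), curves.values["fateA"][0], 1)[0]
        assert fitted == pytest.approx(slope, rel=0.05)


class TestVariabilityScreen:
    def test_constant_curve_not_selected(self):
        curves = _curves({"f": np.full((3, 9), 2.5)})
        res = variability_along(curves, "f")
        assert (res["F"] <= 1e-9).all()
        assert not res["selected"].any()

    def test_exact_cubic_saturates(self):
        t = np.arange(9) - 4.0
        cubic = 0.2 * t**3 - t + 5
        noise = np.random.default_rng(2).normal(5, 0.3, size=(50, 9))
        Y = np.vstack([cubic[None, :], noise])
        res = variability_along(_curves({"f": Y}), "f")
        assert res.loc[0, "pval"] < 1e-12
        assert res.loc[0, "selected"]

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(4.0, 0.2, size=(2000, 9))
        res = variability_along(_curves({"f": Y}), "f", alpha=0.1)
        assert res["selected"].mean() <= 0.12

    def test_too_few_timepoints_rejected(self):
        curves = _curves({"f": np.ones((3, 4))}, stages=list(range(4)))
        with pytest.raises(ValueError):
            variability_along(curves, "f")

    def test_affine_time_recoding_invariance(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(20, 9))
        a = variability_along(_curves({"f": Y}, stages=list(range(9))), "f")
        b = variability_along(
            _curves({"f": Y}, stages=[10 + 3 * s for s in range(9)]), "f"
        )
        np.testing.assert_allclose(a["F"], b["F"], rtol=1e-8)

    def test_matches_statsmodels_anova_single_gene(self):
        """Cross-check the vectorised F-test against an explicit OLS nested
        comparison for one gene."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        y = rng.normal(size=9)
        res = variability_along(_curves({"f": y[None, :]}), "f")
        t = np.arange(9) - 4.0
        X1 = np.column_stack([np.ones(9), t, t**2, t**3])
        fit1 = sm.OLS(y, X1).fit()
        fit0 = sm.OLS(y, np.ones((9, 1))).fit()
        F = ((fit0.ssr - fit1.ssr) / 3) / (fit1.ssr / (9 - 4))
        assert res.loc[0, "F"] == pytest.approx(F, rel=1e-9)
        assert res.loc[0, "pval"] == pytest.approx(
            stats.f.sf(F, 3, 5), rel=1e-9
        )


class TestPairwiseDivergence:
    def test_identical_curves_not_flagged(self):
        Y = np.random.default_rng(6).normal(size=(10, 9))
        curves = _curves({"a": Y, "b": Y.copy()})
        res = pairwise_divergence(curves, ("a", "b"))
        assert (res["pval"] == 1.0).all()
        assert not res["selected"].any()

    def test_large_offset_flagged(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(2.0, 0.3, size=(30, 9))
        curves = _curves({"a": Y, "b": Y + rng.normal(3.0, 0.1, size=Y.shape)})
        res = pairwise_divergence(curves, ("a", "b"))
        assert res.loc[0, "pval"] < 1e-6
        assert res["selected"].mean() > 0.9

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        A = rng.normal(4.0, 0.2, size=(2000, 9))
        B = rng.normal(4.0, 0.2, size=(2000, 9))
        res = pairwise_divergence(_curves({"a": A, "b": B}), ("a", "b"))
        assert res["selected"].mean() <= 0.02

    def test_symmetric_in_fate_pair(self):
        rng = np.random.default_rng(9)
        curves = _curves(
            {"a": rng.normal(size=(15, 9)), "b": rng.normal(size=(15, 9))}
        )
        ab = pairwise_divergence(curves, ("a", "b"))
        ba = pairwise_divergence(curves, ("b", "a"))
        np.testing.assert_allclose(ab["F"], ba["F"], rtol=1e-9)


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(10)
        expr = rng.normal(size=(100, 40))
        expr[:, 20:] = expr[:, :20]
        res = differential_expression(
            expr, [f"G{i}" for i in range(100)], np.arange(20), np.arange(20, 40)
        )
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        assert not (res["padj"] < 0.1).any()

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(11)
        n_genes, n = 2000, 400
        expr = rng.normal(5.0, 1.0, size=(n_genes, n))
        planted = rng.choice(n_genes, 100, replace=False)
        expr[np.ix_(planted, np.arange(200))] += 2.0
        res = differential_expression(
            expr, [f"G{i}" for i in range(n_genes)],
            np.arange(200), np.arange(200, 400),
        )
        flagged = set(res.loc[res["padj"] < 0.1, "gene"])
        hits = sum(f"G{i}" in flagged for i in planted)
        assert hits >= 95
        false = len(flagged) - hits
        assert false <= 0.1 * max(len(flagged), 1)

    def test_swapping_groups_negates_lfc(self):
        rng = np.random.default_rng(12)
        expr = rng.normal(size=(50, 30))
        ga, gb = np.arange(15), np.arange(15, 30)
        ab = differential_expression(expr, [f"G{i}" for i in range(50)], ga, gb)
        ba = differential_expression(expr, [f"G{i}" for i in range(50)], gb, ga)
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
        np.testing.assert_allclose(ab["pval"], ba["pval"], atol=1e-12)

    def test_covariate_mode_threshold_boundary(self):
        """A group effect exactly at the fold-change threshold carries no
        evidence against the shifted null."""
        rng = np.random.default_rng(13)
        n = 200
        g = np.concatenate([np.ones(n), np.zeros(n)])
        cov = rng.normal(size=2 * n)
        X = np.column_stack([np.ones(2 * n), g, cov - cov.mean()])
        noise = rng.normal(0, 0.5, size=2 * n)
        noise -= X @ np.linalg.lstsq(X, noise, rcond=None)[0]  # fit lands at 0.5
        y = (0.5 * g + 0.3 * cov + noise)[None, :]
        res = differential_expression(
            y, ["G0"], np.arange(n), np.arange(n, 2 * n),
            covariate=cov, lfc_threshold=0.5,
        )
        assert res.loc[0, "pval"] > 0.9

    def test_covariate_mode_large_effect_flagged(self):
        rng = np.random.default_rng(14)
        n = 200
        cov = rng.normal(size=2 * n)
        g = np.concatenate([np.ones(n), np.zeros(n)])
        y = (2.0 * g + 0.5 * cov + rng.normal(0, 0.3, size=2 * n))[None, :]
        res = differential_expression(
            y, ["G0"], np.arange(n), np.arange(n, 2 * n),
            covariate=cov, lfc_threshold=0.5,
        )
        assert res.loc[0, "pval"] < 1e-10

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            differential_expression(np.ones((5, 3)), list("ABCDE"), [0], [1, 2])


class TestSignatureScore:
    def test_single_gene_score_is_its_zscore(self):
        rng = np.random.default_rng(15)
        expr = rng.normal(size=(10, 50))
        score = signature_score(expr, [f"G{i}" for i in range(10)], ["G3"])
        z = (expr[3] - expr[3].mean()) / expr[3].std()
        np.testing.assert_allclose(score, z, atol=1e-12)

    def test_random_set_centred(self):
        rng = np.random.default_rng(16)
        expr = rng.normal(size=(200, 500))
        score = signature_score(
            expr, [f"G{i}" for i in range(200)], [f"G{i}" for i in range(0, 50)]
        )
        assert abs(score.mean()) < 3 / np.sqrt(500)

    def test_planted_module_elevates_scores(self):
        rng = np.random.default_rng(17)
        expr = rng.normal(size=(100, 300))
        members = [f"G{i}" for i in range(20)]
        expr[:20, :100] += 1.5  # co-expressed in the first 100 cells
        score = signature_score(expr, [f"G{i}" for i in range(100)], members)
        p = stats.mannwhitneyu(
            score[:100], score[100:], alternative="greater"
        ).pvalue
        assert p < 0.01

    def test_zero_variance_gene_scores_zero(self):
        expr = np.vstack([np.full(20, 7.0), np.random.default_rng(18).normal(size=20)])
        with pytest.warns(UserWarning, match="zero-variance"):
            score = signature_score(expr, ["G0", "G1"], ["G0"])
        np.testing.assert_allclose(score, 0.0)


class TestOverlapEnrichment:
    def test_certain_overlap_p_one(self):
        uni = [f"G{i}" for i in range(30)]
        k, n, p = overlap_enrichment(uni[:10], uni, uni)
        assert k == 10 and p == pytest.approx(1.0)

    def test_disjoint_overlap_upper_tail_near_one(self):
        uni = [f"G{i}" for i in range(100)]
        _, _, p = overlap_enrichment(uni[:40], uni[40:90], uni)
        assert p > 0.999999

    def test_matches_bruteforce_enumeration_small_universe(self):
        """Exact check against enumeration of all draws from a 12-gene
        universe."""
        from itertools import combinations

        uni = [f"G{i}" for i in range(12)]
        ref = set(uni[:5])
        hits = uni[:3] + uni[8:10]  # overlap 3, |hits| 5
        k, n, p = overlap_enrichment(hits, ref, uni)
        assert (k, n) == (3, 5)
        total = hit = 0
        for draw in combinations(uni, 5):
            total += 1
            hit += len(set(draw) & ref) >= 3
        assert p == pytest.approx(hit / total, rel=1e-12)

    def test_matches_scipy_fisher(self):
        uni = [f"G{i}" for i in range(100)]
        ref = set(uni[:20])
        hits = uni[10:25]
        k, n, p = overlap_enrichment(hits, ref, uni)
        table = [[k, n - k], [20 - k, 100 - 20 - (n - k)]]
        assert p == pytest.approx(
            stats.fisher_exact(table, alternative="greater")[1], rel=1e-9
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment([], [], [])
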