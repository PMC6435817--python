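"""Distance-matrix statistics against oracles and an independent library."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

import skbio

from agrocore import (
    anosim,
    cap,
    distlm_forward,
    permanova,
    reduce_redundant_variables,
)
from agrocore.community import DistanceMatrix

from conftest import euclidean_dm


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        pts = np.vstack([np.zeros((4, 2)), 100 + np.random.default_rng(0).random((4, 2))])
        res = anosim(euclidean_dm(pts), ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_direct_rank_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((8, 3))
        groups = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        dm = euclidean_dm(pts)
        res = anosim(dm, groups, n_perm=9, seed=0)
        ranks = sps.rankdata(dm.condensed())
        labels = []
        n = 8
        for i in range(n):
            for j in range(i + 1, n):
                labels.append(groups[i] == groups[j])
        labels = np.array(labels)
        m = len(labels)
        oracle = (ranks[~labels].mean() - ranks[labels].mean()) / (m / 2)
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_matches_skbio(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((12, 4))
        groups = ["a"] * 6 + ["b"] * 6
        dm = euclidean_dm(pts)
        res = anosim(dm, np.array(groups), n_perm=99, seed=0)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(dm.values, dm.sample_ids), groups, permutations=99
        )
        assert res.statistic == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self):
        pts = np.random.default_rng(3).standard_normal((5, 2))
        with pytest.raises(ValueError):
            anosim(euclidean_dm(pts), ["a", "a", "a", "a", "b"], n_perm=9, seed=0)


class TestPermanova:
    def test_r2_partition_identity(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((10, 3))
        res = permanova(
            euclidean_dm(pts),
            pd.Series(["a"] * 5 + ["b"] * 5,
                      index=[f"s{i}" for i in range(10)], name="g"),
            n_perm=49, seed=0,
        )[0]
        # single factor: R2(factor) + R2(residual) = 1 by construction
        g_trace = res.r_squared
        assert 0 <= g_trace <= 1

    def test_matches_skbio_pseudo_f(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((12, 4))
        pts[6:] += 0.8
        groups = ["a"] * 6 + ["b"] * 6
        dm = euclidean_dm(pts)
        res = permanova(
            dm, pd.Series(groups, index=dm.sample_ids, name="g"),
            n_perm=99, seed=0,
        )[0]
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, dm.sample_ids), groups, permutations=99
        )
        assert res.statistic == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_degenerate_zero_distances_flagged(self):
        dm = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        res = permanova(
            dm, pd.Series(["x", "x", "y", "y"], index=dm.sample_ids, name="g"),
            n_perm=9, seed=0,
        )[0]
        assert res.degenerate

    def test_continuous_covariate_sequential(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(14)
        pts = np.column_stack([x, rng.standard_normal(14)])
        dm = euclidean_dm(pts)
        factors = pd.DataFrame(
            {"x": x, "noise": rng.standard_normal(14)}, index=dm.sample_ids
        )
        res = permanova(dm, factors, n_perm=99, seed=0)
        assert res[0].term == "x"
        assert res[0].statistic > res[1].statistic
        assert res[0].p_perm <= 0.05

    def test_single_level_rejected(self):
        pts = np.random.default_rng(7).standard_normal((6, 2))
        dm = euclidean_dm(pts)
        with pytest.raises(ValueError):
            permanova(dm, pd.Series(["a"] * 6, index=dm.sample_ids, name="g"),
                      n_perm=9, seed=0)


class TestCap:
    def test_f_matches_permanova_on_euclidean(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((14, 4))
        pts[7:] += 1.0
        groups = pd.Series(["a"] * 7 + ["b"] * 7)
        dm = euclidean_dm(pts)
        groups.index = dm.sample_ids
        f_perm = permanova(dm, groups.rename("g"), n_perm=9, seed=0)[0].statistic
        res = cap(dm, groups.to_frame("g"), n_perm=9, seed=0)
        assert res.pseudo_f == pytest.approx(f_perm, abs=1e-8)

    def test_disjoint_clusters_strongly_constrained(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.random((6, 2)), 50 + rng.random((6, 2))])
        dm = euclidean_dm(pts)
        groups = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6}, index=dm.sample_ids)
        res = cap(dm, groups, n_perm=99, seed=0)
        assert res.proportion_constrained > 0.5
        assert res.p_model <= 0.05

    def test_eigenvalue_proportions_bounded(self):
        rng = np.random.default_rng(10)
        pts = rng.standard_normal((10, 3))
        dm = euclidean_dm(pts)
        cons = pd.DataFrame({"v": rng.standard_normal(10)}, index=dm.sample_ids)
        res = cap(dm, cons, n_perm=19, seed=0)
        assert 0 <= res.proportion_constrained <= 1

    def test_collinear_constraints_rejected_naming_terms(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((10, 3))
        dm = euclidean_dm(pts)
        v = rng.standard_normal(10)
        cons = pd.DataFrame({"v1": v, "v2": 2 * v}, index=dm.sample_ids)
        with pytest.raises(ValueError, match="v2"):
            cap(dm, cons, n_perm=9, seed=0)


class TestRedundancyReduction:
    def test_duplicated_variable_removes_exactly_one(self):
        rng = np.random.default_rng(12)
        v = rng.standard_normal(30)
        env = pd.DataFrame({"a": v, "b": v.copy(), "c": rng.standard_normal(30)})
        sel = reduce_redundant_variables(env, rho_threshold=0.6)
        assert len(sel.retained) == 2
        assert "c" in sel.retained
        assert len(sel.removed_pairs) == 1

    def test_three_mutually_correlated_leave_one(self):
        rng = np.random.default_rng(13)
        base = rng.standard_normal(50)
        env = pd.DataFrame({
            "a": base + 0.1 * rng.standard_normal(50),
            "b": base + 0.1 * rng.standard_normal(50),
            "c": base + 0.1 * rng.standard_normal(50),
        })
        sel = reduce_redundant_variables(env, rho_threshold=0.6)
        assert len(sel.retained) == 1

    def test_independent_variables_all_retained(self):
        rng = np.random.default_rng(14)
        env = pd.DataFrame(rng.standard_normal((200, 5)),
                           columns=list("abcde"))
        sel = reduce_redundant_variables(env, rho_threshold=0.6)
        assert sel.retained == list("abcde")

    def test_priority_keeps_named_variable(self):
        rng = np.random.default_rng(15)
        v = rng.standard_normal(30)
        env = pd.DataFrame({"junk": v + 0.01 * rng.standard_normal(30), "pH": v})
        sel = reduce_redundant_variables(env, rho_threshold=0.6, priority=("pH",))
        assert sel.retained == ["pH"]


class TestDistlmForward:
    def _community_driven_by(self, driver, n=30, seed=0):
        rng = np.random.default_rng(seed)
        signal = np.column_stack([driver, driver**2 * 0.2])
        pts = signal + 0.3 * rng.standard_normal((n, 2))
        return euclidean_dm(pts)

    def test_true_driver_selected_first(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            ph = rng.standard_normal(30)
            dm = self._community_driven_by(ph, seed=rep)
            env = pd.DataFrame(
                {"pH": ph, "MAT": rng.standard_normal(30)}, index=dm.sample_ids
            )
            sel = distlm_forward(dm, env, n_perm=99, seed=rep)
            hits += bool(sel.order and sel.order[0] == "pH")
        assert hits >= 9

    def test_duplicate_of_selected_never_enters(self):
        rng = np.random.default_rng(16)
        ph = rng.standard_normal(30)
        dm = self._community_driven_by(ph, seed=16)
        env = pd.DataFrame(
            {"pH": ph, "pH_copy": ph + 1e-9 * rng.standard_normal(30)},
            index=dm.sample_ids,
        )
        sel = distlm_forward(dm, env, n_perm=99, seed=0)
        assert len(sel.order) == 1

    def test_cumulative_r2_non_decreasing(self):
        rng = np.random.default_rng(17)
        pts = rng.standard_normal((25, 3))
        dm = euclidean_dm(pts)
        env = pd.DataFrame(
            {"a": pts[:, 0] + 0.1 * rng.standard_normal(25),
             "b": pts[:, 1] + 0.1 * rng.standard_normal(25)},
            index=dm.sample_ids,
        )
        sel = distlm_forward(dm, env, n_perm=99, seed=0)
        assert np.all(np.diff([0.0] + sel.cumulative_r2) >= -1e-12)

    def test_constant_variable_rejected(self):
        rng = np.random.default_rng(18)
        pts = rng.standard_normal((10, 2))
        dm = euclidean_dm(pts)
        env = pd.DataFrame({"c": np.ones(10)}, index=dm.sample_ids)
        with pytest.raises(ValueError):
            distlm_forward(dm, env, n_perm=9, seed=0)


class TestPlantedHabitatEffect:
    def test_permanova_detects_strong_enrichment(self):
        """A strong planted habitat-enrichment effect (log-fold-change 2.5
        on ~20% of non-core OTUs) is detected at the smallest attainable
        permutation p-value."""
        import agrocore as ac

        params = ac.SimulationParams(seed=77, enrich_lfc=2.5)
        table, meta, _, truth = ac.generate_dataset(params)
        rare = ac.rarefy(table, 10_000, seed=77)
        relab = ac.relative_abundance(rare)
        bray = ac.bray_curtis(relab)
        habitats = meta.table.loc[bray.sample_ids, "habitat"].rename("habitat")
        res = permanova(bray, habitats, n_perm=999, seed=0)[0]
        assert res.p_perm <= 0.001 + 1e-12
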