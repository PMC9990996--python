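"""LD estimation, greedy clumping and approximate conditional analysis."""

import numpy as np
import pytest

from cismr.exceptions import CollinearityError
from cismr.ld_tools import (LDMatrix, clump, conditional_assoc, conditional_z,
                            estimate_ld)
from cismr.simdata import (ScenarioConfig, TraitSpec, beta_for_z,
                           make_ld_matrix, simulate_summary_stats)
from cismr.sumstats import two_sided_p
from conftest import make_assoc


def greedy_clump_oracle(pvals, positions, r2, p_index, r2_thresh, window_bp):
    """Independent transliteration of the stated greedy clumping rule."""
    ids = list(pvals)
    unassigned = set(ids)
    index = []
    while True:
        candidates = [v for v in unassigned if pvals[v] <= p_index]
        if not candidates:
            break
        v = min(candidates, key=lambda u: (pvals[u], positions[u], u))
        absorbed = False
        for ix in index:
            if r2[(v, ix)] >= r2_thresh:
                unassigned.discard(v)
                absorbed = True
                break
        if absorbed:
            continue
        index.append(v)
        unassigned.discard(v)
        for u in list(unassigned):
            if (abs(positions[u] - positions[v]) <= window_bp
                    and r2[(u, v)] >= r2_thresh):
                unassigned.discard(u)
    return index


class TestEstimateLD:
    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=100).astype(float)
        y = rng.integers(0, 3, size=100).astype(float)
        ld = estimate_ld(np.column_stack([x, x, y]), ["a", "b", "c"])
        assert ld.r[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero_correlation(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.3, size=(10_000, 8)).astype(float)
        ld = estimate_ld(X, [f"v{i}" for i in range(8)])
        off = ld.r[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_single_variant_identity(self):
        ld = estimate_ld(np.array([[0.0], [1.0], [2.0]]), ["v"])
        assert ld.r.shape == (1, 1) and ld.r[0, 0] == 1.0

    def test_monomorphic_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(50), rng.integers(0, 3, 50).astype(float)])
        with pytest.warns(UserWarning, match="monomorphic"):
            ld = estimate_ld(X, ["mono", "poly"])
        assert ld.variant_ids == ["poly"]


class TestClump:
    def test_three_variant_forced_case(self):
        # r2(1,2)=0.5 -> rs2 pruned by rs1; rs3 independent index
        r = np.eye(3)
        r[0, 1] = r[1, 0] = np.sqrt(0.5)
        r[0, 2] = r[2, 0] = np.sqrt(0.001)
        r[1, 2] = r[2, 1] = np.sqrt(0.001)
        ld = LDMatrix(["rs1", "rs2", "rs3"], r)
        a = make_assoc("t", betas=[6.5, 6.2, 5.8], ses=[1, 1, 1],
                       positions=[1000, 2000, 3000])
        a.records["pval"] = [1e-10, 1e-9, 1e-8]
        res = clump(a, ld)
        assert res.index_variants == ["rs1", "rs3"]
        assert res.assignments == {"rs2": "rs1"}

    def test_uncorrelated_variants_all_become_indexes(self):
        ld = LDMatrix([f"rs{i+1}" for i in range(4)], np.eye(4))
        a = make_assoc("t", betas=[6, 6, 6, 4], ses=[1] * 4)
        a.records["pval"] = [1e-9, 1e-10, 1e-8, 1e-3]
        res = clump(a, ld)
        assert sorted(res.index_variants) == ["rs1", "rs2", "rs3"]

    def test_no_significant_variant_gives_empty_result(self):
        ld = LDMatrix(["rs1"], np.eye(1))
        a = make_assoc("t", betas=[0.1], ses=[1.0])
        res = clump(a, ld)
        assert res.index_variants == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = 10
        A = rng.standard_normal((m, m))
        corr = np.corrcoef(A)
        ids = [f"rs{i+1}" for i in range(m)]
        positions = dict(zip(ids, rng.choice(np.arange(1, 3_000_000, 1000),
                                             size=m, replace=False).tolist()))
        pvals = dict(zip(ids, 10.0 ** rng.uniform(-12, -5, m)))
        ld = LDMatrix(ids, corr)
        a = make_assoc("t", betas=[1] * m, ses=[1] * m, variants=ids,
                       positions=[positions[v] for v in ids])
        a.records["pval"] = [pvals[v] for v in a.records["variant_id"]]
        r2 = {(u, v): corr[i, j] ** 2 for i, u in enumerate(ids)
              for j, v in enumerate(ids)}
        expected = greedy_clump_oracle(pvals, positions, r2, 5e-8, 0.3,
                                       1_000_000)
        got = clump(a, ld, r2_thresh=0.3, window_kb=1000)
        assert got.index_variants == expected

    def test_index_set_satisfies_r2_invariant(self):
        rng = np.random.default_rng(7)
        for seed in range(10):
            reg = simulate_summary_stats(ScenarioConfig(
                50, 0.95,
                traits=(TraitSpec("e", "quantitative", 1194, (10, 40),
                                  (beta_for_z(9, 1194),) * 2),),
                seed=seed))
            res = clump(reg.assoc["e"], reg.ld, r2_thresh=0.01)
            for i, u in enumerate(res.index_variants):
                for v in res.index_variants[i + 1:]:
                    assert reg.ld.r2(u, v) < 0.01

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(3)
        reg = simulate_summary_stats(ScenarioConfig(
            30, 0.9, traits=(TraitSpec("e", "quantitative", 1194, (15,),
                                       (beta_for_z(9, 1194),)),), seed=5))
        a = reg.assoc["e"]
        shuffled = a.records.sample(frac=1, random_state=1)
        from cismr.sumstats import AssocSet
        b = AssocSet("e", shuffled)
        assert (clump(a, reg.ld).index_variants
                == clump(b, reg.ld).index_variants)


class TestConditionalZ:
    def test_closed_form_single_condition(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDMatrix(["a", "b"], r)
        z = np.array([3.0, 5.0])
        got = conditional_z(z, ld, [1], 0)
        assert got == pytest.approx((3 - 0.5 * 5) / np.sqrt(0.75), abs=1e-4)
        assert got == pytest.approx(0.5774, abs=1e-4)

    def test_zero_correlation_leaves_z_unchanged(self):
        ld = LDMatrix(["a", "b"], np.eye(2))
        assert conditional_z(np.array([3.0, 5.0]), ld, [1], 0) == 3.0

    def test_empty_condition_set_is_identity(self):
        ld = LDMatrix(["a", "b"], np.eye(2))
        assert conditional_z(np.array([3.0, 5.0]), ld, [], 0) == 3.0

    def test_matches_mvn_conditional_oracle(self):
        # independent oracle: conditional mean/var of an MVN with cov = R
        rng = np.random.default_rng(11)
        A = rng.standard_normal((4, 4))
        R = np.corrcoef(A)
        ld = LDMatrix(list("abcd"), R)
        z = rng.standard_normal(4) * 2
        cond, target = [1, 3], 0
        Sigma_cc = R[np.ix_(cond, cond)]
        Sigma_tc = R[target, cond]
        mean = Sigma_tc @ np.linalg.solve(Sigma_cc, z[cond])
        var = 1.0 - Sigma_tc @ np.linalg.solve(Sigma_cc, Sigma_tc)
        expected = (z[target] - mean) / np.sqrt(var)
        assert conditional_z(z, ld, cond, target) == pytest.approx(expected)

    def test_collinear_condition_raises(self):
        c = 1.0 - 1e-14
        r = np.array([[1.0, c], [c, 1.0]])
        ld = LDMatrix(["a", "b"], r)
        with pytest.raises(CollinearityError):
            conditional_z(np.array([3.0, 3.0]), ld, [1], 0)


class TestConditionalAssoc:
    def test_empty_condition_is_identity(self):
        reg = simulate_summary_stats(ScenarioConfig(
            20, 0.9, traits=(TraitSpec("e", "quantitative", 1194, (10,),
                                       (beta_for_z(8, 1194),)),), seed=0))
        a = reg.assoc["e"]
        out = conditional_assoc(a, reg.ld, [])
        np.testing.assert_allclose(out.records["beta"], a.records["beta"])

    def test_conditioning_on_causal_yields_null_residuals(self):
        # single-causal region: residual z's should look standard normal
        m, exceed, total = 30, 0, 0
        for seed in range(300):
            reg = simulate_summary_stats(ScenarioConfig(
                m, 0.9, traits=(TraitSpec("e", "quantitative", 1194,
                                          (m // 2,),
                                          (beta_for_z(9, 1194),)),),
                seed=seed))
            causal = reg.ld.variant_ids[m // 2]
            out = conditional_assoc(reg.assoc["e"], reg.ld, [causal])
            zres = np.abs(out.zscores())
            exceed += int((zres > 3.29).sum())
            total += len(zres)
        assert exceed / total <= 0.02

    def test_condition_variants_removed_and_p_recomputed(self):
        reg = simulate_summary_stats(ScenarioConfig(
            10, 0.5, traits=(TraitSpec("e", "quantitative", 1194, (5,),
                                       (beta_for_z(8, 1194),)),), seed=1))
        causal = reg.ld.variant_ids[5]
        out = conditional_assoc(reg.assoc["e"], reg.ld, [causal])
        assert causal not in out.variant_ids
        np.testing.assert_allclose(out.records["pval"],
                                   two_sided_p(out.zscores()))
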