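"""Three-trait colocalization: configuration space, posteriors, CpG scan."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from cismr.coloc_engine import ColocPriors, coloc_abf, log_abf
from cismr.moloc_engine import (DEFAULT_PRIOR_WEIGHTS, decompose_and_moloc,
                                enumerate_configs, moloc, moloc_from_abf,
                                scan_cpgs)
from cismr.simdata import (ScenarioConfig, TraitSpec, beta_for_z,
                           scenario_library, simulate_summary_stats)
from cismr.sumstats import GenomicWindow
from conftest import make_assoc


def brute_force_partitions(items):
    """Independent subset-partition enumerator (different algorithm: grow
    partitions by assigning each item to an existing or new block)."""
    parts = [[]]
    for x in items:
        new = []
        for p in parts:
            for i in range(len(p)):
                new.append([blk | {x} if j == i else blk
                            for j, blk in enumerate(p)])
            new.append(p + [{x}])
        parts = new
    return parts


def brute_force_config_count(k):
    total = 0
    for size in range(0, k + 1):
        for subset in combinations(range(k), size):
            total += len(brute_force_partitions(subset)) if subset else 1
    return total


def brute_force_moloc(lbfs, weights):
    """Oracle: direct sum over variant assignments for every configuration."""
    k = len(lbfs)
    m = len(lbfs[0])
    bfs = [np.exp(v) for v in lbfs]
    results = {}
    for size in range(0, k + 1):
        for subset in combinations(range(k), size):
            partitions = brute_force_partitions(subset) if subset else [[]]
            for part in partitions:
                groups = tuple(sorted(tuple(sorted(b)) for b in part))
                like = 0.0
                if not groups:
                    like = 1.0
                else:
                    prior = np.prod([weights[len(g) - 1] for g in groups])
                    for assign in product(range(m), repeat=len(groups)):
                        if len(set(assign)) != len(assign):
                            continue
                        term = 1.0
                        for g, i in zip(groups, assign):
                            for t in g:
                                term *= bfs[t][i]
                        like += term
                    like *= prior
                results[groups] = results.get(groups, 0.0) + like
    total = sum(results.values())
    return {g: v / total for g, v in results.items()}


def posteriors_by_groups(res, trait_labels=("E", "M", "G")):
    out = {}
    for label, p in res.posteriors.items():
        if label == "null":
            out[()] = p
        else:
            groups = tuple(sorted(
                tuple(sorted(trait_labels.index(c) for c in grp))
                for grp in label.split(".")))
            out[groups] = p
    return out


class TestEnumerateConfigs:
    @pytest.mark.parametrize("k,expected", [(1, 2), (2, 5), (3, 15), (4, 52)])
    def test_counts_match_brute_force(self, k, expected):
        configs = enumerate_configs(k)
        assert len(configs) == expected
        assert len(configs) == brute_force_config_count(k)
        assert len({c.groups for c in configs}) == len(configs)

    def test_k2_reduces_to_pairwise_hypotheses(self):
        labels = [c.label(("A", "B")) for c in enumerate_configs(2)]
        assert set(labels) == {"null", "A", "B", "A.B", "AB"}


class TestMolocPosteriors:
    def test_one_snp_matches_hand_enumeration(self):
        l10 = np.array([np.log(10.0)])
        res = moloc_from_abf([l10, l10, l10], DEFAULT_PRIOR_WEIGHTS)
        # only single-group configurations are possible with one variant
        total = 1 + 3 * 1e-3 + 3 * 1e-4 + 1e-4
        assert res.posteriors["null"] == pytest.approx(1 / total, rel=1e-10)
        assert res.posteriors["E"] == pytest.approx(1e-3 / total, rel=1e-10)
        assert res.posteriors["EM"] == pytest.approx(1e-4 / total, rel=1e-10)
        assert res.ppa_full == pytest.approx(1e-4 / total, rel=1e-10)
        assert res.posteriors["E.M"] == 0.0
        assert res.posteriors["E.M.G"] == 0.0

    @pytest.mark.parametrize("seed,m", [(0, 3), (1, 4), (2, 5), (3, 6)])
    def test_random_small_instances_match_assignment_oracle(self, seed, m):
        rng = np.random.default_rng(seed)
        lbfs = [rng.normal(0, 3, m) for _ in range(3)]
        got = posteriors_by_groups(moloc_from_abf(lbfs))
        expected = brute_force_moloc(lbfs, DEFAULT_PRIOR_WEIGHTS)
        assert set(got) == set(expected)
        for g in expected:
            assert got[g] == pytest.approx(expected[g], rel=1e-8, abs=1e-12)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(9)
        res = moloc_from_abf([rng.normal(0, 8, 100) for _ in range(3)])
        assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-10)

    def test_null_third_trait_reduces_to_pairwise_ranking(self):
        # with G fully null, the (E, M) sharing question inside moloc should
        # rank E.M vs EM the same way pairwise colocalization ranks H3 vs H4
        for name, expect_shared in (("three-way-shared", True),
                                    ("H3-distinct", False)):
            if name == "three-way-shared":
                reg = simulate_summary_stats(scenario_library(3)[name])
                e, mth = reg.assoc["expression"], reg.assoc["methylation"]
            else:
                reg = simulate_summary_stats(scenario_library(3)[name])
                e, mth = reg.assoc["expression"], reg.assoc["trait"]
            null_g = e.records.copy()
            null_g["beta"] = 0.0
            null_g["pval"] = 1.0
            from cismr.sumstats import AssocSet
            g = AssocSet("null_trait", null_g)
            res = moloc(e, mth, g)
            pair = coloc_abf(e, mth)
            moloc_shared = res.posteriors["EM"] > res.posteriors["E.M"]
            pair_shared = pair["H4"] > pair["H3"]
            assert moloc_shared == pair_shared == expect_shared

    def test_trait_relabeling_permutes_posteriors(self):
        rng = np.random.default_rng(4)
        lbfs = [rng.normal(0, 3, 8) for _ in range(3)]
        base = posteriors_by_groups(moloc_from_abf(lbfs))
        perm = [2, 0, 1]  # new trait t was old trait perm[t]
        permuted = posteriors_by_groups(
            moloc_from_abf([lbfs[p] for p in perm]))
        for groups, p in base.items():
            relabeled = tuple(sorted(
                tuple(sorted(perm.index(t) for t in g)) for g in groups))
            assert permuted[relabeled] == pytest.approx(p, rel=1e-10)


class TestScanCpgs:
    def _inputs(self, seed=0):
        reg = simulate_summary_stats(scenario_library(seed)["three-way-shared"])
        e, mth, g = (reg.assoc["expression"], reg.assoc["methylation"],
                     reg.assoc["trait"])
        causal_pos = reg.ld.positions[reg.ld.variant_ids[100]]
        window = GenomicWindow("1", causal_pos - 2000, causal_pos + 2000)
        return reg, e, mth, g, window, causal_pos

    def test_single_eligible_cpg_is_identity(self):
        _, e, mth, g, window, causal_pos = self._inputs()
        res = scan_cpgs("gene", e, {"cg1": mth}, g, window,
                        {"cg1": ("1", causal_pos)})
        direct = moloc(e, mth, g)
        assert res.best.cpg_id == "cg1"
        assert res.best.ppa_full == pytest.approx(direct.ppa_full)

    def test_cpg_beyond_100kb_excluded(self):
        _, e, mth, g, window, _ = self._inputs()
        far = window.end + 100_001
        res = scan_cpgs("gene", e, {"cg1": mth}, g, window, {"cg1": ("1", far)})
        assert res.best is None and res.reason

    def test_cpg_exactly_at_100kb_included(self):
        _, e, mth, g, window, _ = self._inputs()
        res = scan_cpgs("gene", e, {"cg1": mth}, g, window,
                        {"cg1": ("1", window.end + 100_000)})
        assert res.best is not None

    def test_signal_carrier_selected_among_decoys(self):
        # 5 CpGs, only one shares the causal variant with E and G
        hits, sel = 0, 0
        n_reps = 30
        for seed in range(n_reps):
            reg, e, mth, g, window, causal_pos = self._inputs(seed)
            cpgs = {"cg_signal": mth}
            positions = {"cg_signal": ("1", causal_pos)}
            rng = np.random.default_rng(1000 + seed)
            for i in range(4):
                decoy = mth.records.copy()
                z = rng.standard_normal(len(decoy))
                decoy["beta"] = z * decoy["se"]
                decoy["pval"] = 1.0
                from cismr.sumstats import AssocSet
                cpgs[f"cg_null{i}"] = AssocSet(f"cg_null{i}", decoy)
                positions[f"cg_null{i}"] = ("1", causal_pos + 1000 * (i + 1))
            res = scan_cpgs("gene", e, cpgs, g, window, positions)
            sel += res.best.cpg_id == "cg_signal"
            hits += res.best.ppa_full > 0.8
        assert sel / n_reps >= 0.8
        assert hits / n_reps >= 0.8
        assert len(res.per_cpg) == 5


class TestDecompose:
    def test_single_signal_reduces_to_plain_scan(self):
        reg = simulate_summary_stats(scenario_library(0)["three-way-shared"])
        e, mth, g = (reg.assoc["expression"], reg.assoc["methylation"],
                     reg.assoc["trait"])
        causal_pos = reg.ld.positions[reg.ld.variant_ids[100]]
        window = GenomicWindow("1", causal_pos - 2000, causal_pos + 2000)
        cpg_pos = {"cg1": ("1", causal_pos)}
        out = decompose_and_moloc("gene", e, {"cg1": mth}, g, reg.ld, window,
                                  cpg_pos)
        direct = scan_cpgs("gene", e, {"cg1": mth}, g, window, cpg_pos)
        assert len(out) == 1
        assert out[0].best.ppa_full == pytest.approx(direct.best.ppa_full)

    def test_two_signal_locus_isolates_the_shared_signal(self):
        # E has independent eQTLs at variants 61 and 141; only the first is
        # shared with M and G -> its conditional signal should colocalize
        better = 0
        n_reps = 25
        for seed in range(n_reps):
            reg = simulate_summary_stats(
                scenario_library(seed)["two-independent-eQTL-signals"])
            e, mth, g = (reg.assoc["expression"], reg.assoc["methylation"],
                         reg.assoc["trait"])
            shared_pos = reg.ld.positions[reg.ld.variant_ids[60]]
            window = GenomicWindow("1", shared_pos - 2000, shared_pos + 2000)
            cpg_pos = {"cg1": ("1", shared_pos)}
            out = decompose_and_moloc("gene", e, {"cg1": mth}, g, reg.ld,
                                      window, cpg_pos)
            shared_variant = reg.ld.variant_ids[60]
            shared_ppa, other_ppa = [], []
            for res in out:
                if res.best is None:
                    continue
                is_shared = reg.ld.r2(res.index_variant, shared_variant) > 0.5
                (shared_ppa if is_shared else other_ppa).append(
                    res.best.ppa_full)
            assert shared_ppa, "shared eQTL signal lost by clumping"
            if other_ppa:
                better += max(shared_ppa) > max(other_ppa)
            else:
                better += 1
        assert better / n_reps >= 0.9

    def test_condition_variants_absent_from_decomposed_runs(self):
        reg = simulate_summary_stats(
            scenario_library(1)["two-independent-eQTL-signals"])
        e = reg.assoc["expression"]
        from cismr.ld_tools import clump, conditional_assoc
        cl = clump(e, reg.ld)
        assert len(cl.index_variants) >= 2
        cond = conditional_assoc(e, reg.ld, cl.index_variants[1:])
        for v in cl.index_variants[1:]:
            assert v not in cond.variant_ids
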