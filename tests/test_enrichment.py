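"""Hypergeometric/permutation enrichment, families, waves, module tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stressregulon.core_io import AnnotationMap, GeneSet, ValidationError
from stressregulon.enrichment import (
    detect_modules_simple,
    enrich_annotation,
    focus_modules,
    hypergeom_exceedance,
    hypergeom_tail,
    module_enrichment,
    permutation_enrich,
    summarize_families,
    wave_groups,
)
from stressregulon.preprocess import NormalizedMatrix


def brute_force_tail(x, K, n, N):
    """Enumerate all C(N, n) draws and count those with >= x successes."""
    hits = total = 0
    population = list(range(N))
    for draw in combinations(population, n):
        total += 1
        if sum(1 for g in draw if g < K) >= x:
            hits += 1
    return hits / total


class TestHypergeomTail:
    def test_x_zero_is_exactly_one(self):
        assert hypergeom_tail(0, 5, 5, 10) == 1.0

    def test_known_value_1_over_252(self):
        assert hypergeom_tail(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    @pytest.mark.parametrize("N,K,n,x", [
        (8, 3, 4, 2), (10, 5, 5, 3), (12, 6, 4, 4), (9, 2, 7, 1), (7, 7, 3, 3),
    ])
    def test_matches_enumeration(self, N, K, n, x):
        assert hypergeom_tail(x, K, n, N) == pytest.approx(
            brute_force_tail(x, K, n, N), abs=1e-12)

    def test_monotone_nonincreasing_in_x(self):
        ps = [hypergeom_tail(x, 20, 30, 100) for x in range(0, 21)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_pmf_partition(self):
        # P(X>=x) - P(X>=x+1) sums to 1 over the support
        total = sum(hypergeom_tail(x, 6, 5, 12) - hypergeom_tail(x + 1, 6, 5, 12)
                    if x < 5 else hypergeom_tail(x, 6, 5, 12)
                    for x in range(0, 6))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_exceedance_is_shifted_tail(self):
        assert hypergeom_exceedance(3, 20, 30, 100) == pytest.approx(
            hypergeom_tail(4, 20, 30, 100), rel=1e-12)

    def test_infeasible_arguments_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_tail(6, 5, 5, 10)
        with pytest.raises(ValidationError):
            hypergeom_tail(1, 11, 5, 10)


def _universe(n):
    return [f"g{i:04d}" for i in range(n)]


class TestEnrichAnnotation:
    def test_query_equals_targets_is_top_hit(self):
        genes = _universe(500)
        query = GeneSet("q", frozenset(genes[:20]))
        background = GeneSet("bg", frozenset(genes))
        amap = AnnotationMap(targets={
            "hit": frozenset(genes[:20]),
            "other": frozenset(genes[100:160]),
        })
        res = enrich_annotation(query, background, amap).set_index("term")
        assert res.loc["hit", "p_raw"] == res["p_raw"].min()
        assert res.loc["hit", "significant"]

    def test_query_outside_background_rejected(self):
        genes = _universe(10)
        with pytest.raises(ValidationError, match="outside background"):
            enrich_annotation(GeneSet("q", frozenset({"zzz"})),
                              GeneSet("bg", frozenset(genes)),
                              AnnotationMap(targets={"t": frozenset(genes[:2])}))

    def test_planted_concentration_flagged(self, sim_small):
        truth = sim_small["truth"]
        binding = sim_small["binding"]
        genes = sorted(truth.baseline_mean)
        background = GeneSet("bg", frozenset(genes))
        query = GeneSet("early_up", truth.regulon_genes("early_up"))
        res = enrich_annotation(query, background, binding,
                                correction="none").set_index("term")
        eu_tfs = [tf for tf, reg in truth.tf_regulon.items()
                  if reg == "early_up"]
        assert res.loc[eu_tfs, "significant"].mean() >= 0.95

    def test_null_map_calibrated(self):
        """Uniform maps: significant fraction <= 1.5x nominal over 20 seeds."""
        genes = _universe(400)
        background = GeneSet("bg", frozenset(genes))
        flags = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            query = GeneSet("q", frozenset(
                rng.choice(genes, 50, replace=False)))
            amap = AnnotationMap(targets={
                f"t{j}": frozenset(rng.choice(genes, 30, replace=False))
                for j in range(25)})
            res = enrich_annotation(query, background, amap, alpha=0.05,
                                    correction="none")
            flags.append(res["significant"].to_numpy())
        assert np.concatenate(flags).mean() <= 1.5 * 0.05

    def test_corrections_dominate_raw(self):
        genes = _universe(300)
        rng = np.random.default_rng(1)
        query = GeneSet("q", frozenset(rng.choice(genes, 40, replace=False)))
        background = GeneSet("bg", frozenset(genes))
        amap = AnnotationMap(targets={
            f"t{j}": frozenset(rng.choice(genes, 25, replace=False))
            for j in range(12)})
        raw = enrich_annotation(query, background, amap, correction="none")
        bh = enrich_annotation(query, background, amap, correction="bh")
        bonf = enrich_annotation(query, background, amap,
                                 correction="bonferroni")
        assert np.all(bh["p_adj"] >= raw["p_raw"] - 1e-15)
        assert np.all(bonf["p_adj"] >= bh["p_adj"] - 1e-15)


class TestPermutation:
    def _setup(self, seed=0, n_bg=300, n_query=40, n_terms=10):
        rng = np.random.default_rng(seed)
        genes = _universe(n_bg)
        query = GeneSet("q", frozenset(rng.choice(genes, n_query,
                                                  replace=False)))
        amap = AnnotationMap(targets={
            f"t{j}": frozenset(rng.choice(genes, 30, replace=False))
            for j in range(n_terms)})
        return query, GeneSet("bg", frozenset(genes)), amap

    def test_zero_overlap_is_p_one(self):
        genes = _universe(100)
        query = GeneSet("q", frozenset(genes[:10]))
        amap = AnnotationMap(targets={"t": frozenset(genes[50:60])})
        res = permutation_enrich(query, GeneSet("bg", frozenset(genes)),
                                 amap, n_perm=500, seed=1)
        assert res["p_raw"].iloc[0] >= 1.0 - 1.0 / 501

    def test_same_seed_identical(self):
        query, background, amap = self._setup()
        a = permutation_enrich(query, background, amap, n_perm=1000, seed=7)
        b = permutation_enrich(query, background, amap, n_perm=1000, seed=7)
        assert np.array_equal(a["p_raw"], b["p_raw"])

    def test_agrees_with_closed_form_under_null(self):
        query, background, amap = self._setup(seed=3, n_terms=15)
        n_perm = 20_000
        res = permutation_enrich(query, background, amap, n_perm=n_perm,
                                 seed=5)
        ok = 0
        for row in res.itertuples():
            p_h = hypergeom_tail(row.x, row.K, row.n, row.N)
            mc_se = np.sqrt(p_h * (1 - p_h) / n_perm)
            ok += abs(row.p_raw - p_h) <= 3 * mc_se + 2 / n_perm
        assert ok / len(res) >= 0.95

    def test_query_larger_than_background_rejected(self):
        genes = _universe(5)
        with pytest.raises(ValidationError):
            permutation_enrich(
                GeneSet("q", frozenset(genes)),
                GeneSet("bg", frozenset(genes[:3])),
                AnnotationMap(targets={"t": frozenset(genes[:2])}))


class TestFamilies:
    def _results(self):
        return pd.DataFrame({
            "term": [f"HSF{i}" for i in range(21)] + ["WRKY1", "WRKY2"],
            "significant": [True] * 9 + [False] * 12 + [True, False],
        })

    def test_counts_sizes_proportion(self):
        fam = {f"HSF{i}": "HSF" for i in range(21)}
        fam.update({"WRKY1": "WRKY", "WRKY2": "WRKY"})
        out = summarize_families(self._results(), family=fam).set_index("family")
        assert out.loc["HSF", "n_significant"] == 9
        assert out.loc["HSF", "family_size"] == 21
        assert out.loc["HSF", "proportion"] == pytest.approx(9 / 21)

    def test_conservation_of_significant_terms(self):
        fam = {f"HSF{i}": "HSF" for i in range(21)}
        fam.update({"WRKY1": "WRKY", "WRKY2": "WRKY"})
        out = summarize_families(self._results(), family=fam)
        assert out["n_significant"].sum() == 10

    def test_missing_family_raises_unless_allowed(self):
        results = pd.DataFrame({"term": ["a"], "significant": [True]})
        with pytest.raises(ValidationError):
            summarize_families(results, family={})
        out = summarize_families(results, family={}, allow_unassigned=True)
        assert out["family"].tolist() == ["unassigned"]


class TestWaves:
    def _summary(self, families, sig):
        return pd.DataFrame({"family": families, "n_significant": sig,
                             "family_size": [10] * len(families),
                             "proportion": [s / 10 for s in sig]})

    def test_up_wave_labels(self):
        summaries = {
            "early_up": self._summary(["HSF", "ERF", "NAC"], [9, 3, 0]),
            "late_up": self._summary(["HSF", "ERF", "NAC"], [0, 2, 5]),
        }
        out = wave_groups(summaries).set_index("family")
        assert out.loc["HSF", "up_group"] == "early-only"
        assert out.loc["ERF", "up_group"] == "early-and-late"
        assert out.loc["NAC", "up_group"] == "late-only"

    def test_down_independent_of_up(self):
        summaries = {
            "early_up": self._summary(["MYB"], [1]),
            "late_down": self._summary(["MYB"], [2]),
        }
        out = wave_groups(summaries).set_index("family")
        assert out.loc["MYB", "up_group"] == "early-only"
        assert out.loc["MYB", "down_group"] == "late-only"

    def test_silent_families_omitted_and_labels_unique(self):
        summaries = {"early_up": self._summary(["A", "B"], [0, 1])}
        out = wave_groups(summaries)
        assert out["family"].tolist() == ["B"]
        assert out["family"].is_unique


class TestModuleEnrichment:
    def _map(self, genes, module_genes):
        return AnnotationMap(targets={"M1": frozenset(module_genes)})

    def test_zero_overlap_capped_to_one(self):
        genes = _universe(281)
        modules = self._map(genes, genes[:56])
        query = GeneSet("q", frozenset(genes[200:213]))  # 13 genes, x varies
        out = module_enrichment(GeneSet("q", frozenset(genes[260:273])),
                                modules, GeneSet("pop", frozenset(genes)),
                                m_tests=36, tail="exceedance")
        assert out["p_adj"].iloc[0] == 1.0

    def test_inclusive_default_x0_is_one(self):
        genes = _universe(100)
        modules = self._map(genes, genes[:10])
        out = module_enrichment(GeneSet("q", frozenset(genes[50:60])),
                                modules, GeneSet("pop", frozenset(genes)),
                                m_tests=1)
        assert out["p_adj"].iloc[0] == 1.0

    def test_focus_filters_by_p_and_size(self):
        table = pd.DataFrame({
            "module": ["big_sig", "small_sig", "big_ns"],
            "p_adj": [1e-6, 1e-6, 0.5],
        })
        sizes = {"big_sig": 390, "small_sig": 40, "big_ns": 400}
        out = focus_modules(table, sizes)
        assert out["module"].tolist() == ["big_sig"]

    def test_retained_subset_of_input(self):
        table = pd.DataFrame({"module": ["a", "b"], "p_adj": [1e-7, 1e-9]})
        out = focus_modules(table, {"a": 100, "b": 100})
        assert set(out["module"]) <= {"a", "b"}


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=12)
        block_a = t[None, :] * 1.0 + rng.normal(0, 0.2, (15, 12))
        u = rng.normal(size=12)
        block_b = u[None, :] * 1.0 + rng.normal(0, 0.2, (15, 12))
        values = np.vstack([block_a, block_b])
        genes = [f"g{i:02d}" for i in range(30)]
        m = NormalizedMatrix(genes, [f"s{i}" for i in range(12)], values, "vst")
        modules = detect_modules_simple(m, corr_cut=0.7)
        assert len(modules) == 2
        sizes = sorted(len(v) for v in modules.targets.values())
        assert sizes == [15, 15]

    def test_impossible_cut_gives_no_modules(self):
        rng = np.random.default_rng(5)
        m = NormalizedMatrix([f"g{i}" for i in range(6)],
                             [f"s{i}" for i in range(5)],
                             rng.normal(size=(6, 5)), "vst")
        assert len(detect_modules_simple(m, corr_cut=1.01)) == 0

    def test_output_is_partition(self):
        rng = np.random.default_rng(6)
        m = NormalizedMatrix([f"g{i}" for i in range(20)],
                             [f"s{i}" for i in range(8)],
                             rng.normal(size=(20, 8)), "vst")
        modules = detect_modules_simple(m, corr_cut=0.6)
        seen: set[str] = set()
        for members in modules.targets.values():
            assert not (seen & members)
            seen |= members
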