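import numpy as np
import pytest

from dpgkit import simulate as sim
from dpgkit.pairs import (
    DPGPair,
    DPGSet,
    classify_all_spacing,
    classify_spacing,
    classify_spacing_by_peaks,
    compare_reference_sets,
    identify_dpgs,
    inter_tss_distance,
    sample_random_pairs,
)
from tests.conftest import catalog_of, make_gene


def brute_force_dpgs(catalog, max_dist=1000):
    """Independent oracle: exhaustive double loop + re-derived greedy rule."""
    candidates = []
    for m in catalog.genes:
        if m.strand != "-":
            continue
        for p in catalog.genes:
            if p.strand != "+" or p.chrom != m.chrom:
                continue
            if abs(p.tss - m.tss) < max_dist:
                candidates.append((m, p))
    candidates.sort(
        key=lambda mp: (
            abs(mp[1].tss - mp[0].tss),
            mp[0].tss + mp[1].tss,
            mp[0].gene_id,
            mp[1].gene_id,
        )
    )
    used, chosen = set(), []
    for m, p in candidates:
        if m.gene_id in used or p.gene_id in used:
            continue
        used.update((m.gene_id, p.gene_id))
        chosen.append((m.gene_id, p.gene_id))
    return sorted(chosen)


class TestInterTssDistance:
    @pytest.mark.parametrize(
        "minus_tss,plus_tss,expected", [(1000, 1500, 500), (1000, 800, -200), (1000, 1000, 0)]
    )
    def test_signed_distance(self, minus_tss, plus_tss, expected):
        m = make_gene("m", strand="-", tss=minus_tss)
        p = make_gene("p", strand="+", tss=plus_tss)
        assert inter_tss_distance(m, p) == expected

    def test_same_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            inter_tss_distance(make_gene("a", strand="+"), make_gene("b", strand="+", tss=2000))

    def test_antisymmetric_under_tss_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t1, t2 = (int(x) for x in rng.integers(5_000, 50_000, 2))
            d = inter_tss_distance(
                make_gene("m", strand="-", tss=t1), make_gene("p", strand="+", tss=t2)
            )
            d_swapped = inter_tss_distance(
                make_gene("m", strand="-", tss=t2), make_gene("p", strand="+", tss=t1)
            )
            assert d == -d_swapped


class TestIdentifyDpgs:
    def test_single_pair_within_window(self):
        cat = catalog_of(
            make_gene("m", strand="-", tss=10_000),
            make_gene("p1", strand="+", tss=10_500),
            make_gene("p2", strand="+", tss=11_600),
        )
        ds = identify_dpgs(cat)
        assert len(ds) == 1
        assert ds.pairs[0].inter_tss_distance == 500

    def test_tie_resolved_to_smaller_partner_tss(self):
        cat = catalog_of(
            make_gene("m", strand="-", tss=10_000, length=500),
            make_gene("pA", strand="+", tss=10_100),
            make_gene("pB", strand="+", tss=9_900),
        )
        ds = identify_dpgs(cat)
        assert len(ds) == 1
        assert ds.pairs[0].plus_gene.gene_id == "pB"
        assert any("eligible for 2" in line for line in ds.ambiguity_log)

    def test_empty_catalog(self):
        assert len(identify_dpgs(catalog_of())) == 0

    def test_one_gene_one_pair(self):
        for seed in range(10):
            ds = identify_dpgs(sim.random_catalog(300, seed=seed))
            ids = [g for p in ds.pairs for g in (p.minus_gene.gene_id, p.plus_gene.gene_id)]
            assert len(ids) == len(set(ids))

    def test_matches_brute_force_oracle(self):
        for seed in range(20):
            cat = sim.random_catalog(int(np.random.default_rng(seed).integers(50, 400)), seed=seed)
            ds = identify_dpgs(cat)
            found = sorted((p.minus_gene.gene_id, p.plus_gene.gene_id) for p in ds.pairs)
            assert found == brute_force_dpgs(cat)


class TestSpacingClass:
    @pytest.mark.parametrize(
        "d,expected",
        [(-469, "overlapping"), (95, "optimal"), (976, "distant"), (0, "optimal"),
         (500, "optimal"), (501, "distant"), (-1, "overlapping")],
    )
    def test_distance_rule(self, d, expected):
        pair = DPGPair(
            make_gene("m", strand="-", tss=10_000, length=2000),
            make_gene("p", strand="+", tss=10_000 + d, length=2000),
        )
        assert classify_spacing(pair) == expected

    def test_out_of_window_is_contract_violation(self):
        pair = DPGPair(
            make_gene("m", strand="-", tss=10_000, length=3000),
            make_gene("p", strand="+", tss=11_000),
        )
        with pytest.raises(ValueError, match="window"):
            classify_spacing(pair)

    def test_partition_over_cohort(self, cohort30):
        """Every pair gets exactly one class; class counts sum to the set size."""
        _, dpgset, _ = cohort30
        classified = classify_all_spacing(dpgset)
        counts = classified.to_frame()["spacing_class"].value_counts()
        assert set(counts.index) <= {"overlapping", "optimal", "distant"}
        assert counts.sum() == len(dpgset)

    def test_peak_based_modes(self):
        pair = DPGPair(
            make_gene("m", strand="-", tss=10_000, length=2000),
            make_gene("p", strand="+", tss=10_400, length=2000),
        )
        assert classify_spacing_by_peaks(pair, [10_200]) == "optimal"
        assert classify_spacing_by_peaks(pair, [9_500]) == "overlapping"
        assert classify_spacing_by_peaks(pair, [9_800, 10_600]) == "distant"
        assert classify_spacing_by_peaks(pair, []) == "unclassified"


class TestRandomPairs:
    @pytest.fixture()
    def catalog(self):
        return catalog_of(*(make_gene(f"g{i}", tss=20_000 * (i + 1)) for i in range(20)))

    def test_zero_draws(self, catalog):
        assert sample_random_pairs(catalog, 0, seed=1) == []

    def test_deterministic_per_seed(self, catalog):
        a = sample_random_pairs(catalog, 5, seed=42)
        b = sample_random_pairs(catalog, 5, seed=42)
        assert [(x.gene_id, y.gene_id) for x, y in a] == [(x.gene_id, y.gene_id) for x, y in b]

    def test_too_many_requested(self, catalog):
        with pytest.raises(ValueError, match="possible"):
            sample_random_pairs(catalog, 10_000, seed=1)

    def test_exclusion_respected(self, catalog):
        pairs = sample_random_pairs(catalog, 10, seed=3, exclude={"g0", "g1"})
        drawn = {g.gene_id for pair in pairs for g in pair}
        assert not drawn & {"g0", "g1"}

    def test_uniform_over_six_pairs(self):
        """10,000 single-pair draws from 4 genes hit each of the 6 pairs 1/6 +- 0.02."""
        cat = catalog_of(*(make_gene(f"g{i}", tss=20_000 * (i + 1)) for i in range(4)))
        freq = {}
        for seed in range(10_000):
            ((a, b),) = sample_random_pairs(cat, 1, seed=seed)
            freq[(a.gene_id, b.gene_id)] = freq.get((a.gene_id, b.gene_id), 0) + 1
        assert len(freq) == 6
        for count in freq.values():
            assert abs(count / 10_000 - 1 / 6) < 0.02


class TestCompareReferenceSets:
    def pairset(self, *sym_pairs, start=0):
        pairs = []
        for i, (sa, sb) in enumerate(sym_pairs):
            m = make_gene(f"m{start + i}", strand="-", tss=50_000 * (i + 1), symbol=sa)
            p = make_gene(f"p{start + i}", strand="+", tss=50_000 * (i + 1) + 200, symbol=sb)
            pairs.append(DPGPair(m, p))
        return DPGSet(pairs=pairs)

    def test_identical_sets(self):
        a = self.pairset(("A", "B"), ("C", "D"))
        b = self.pairset(("A", "B"), ("C", "D"), start=10)
        shared, ua, ub = compare_reference_sets(a, b)
        assert len(shared) == 2 and not ua and not ub

    def test_unique_pairs_are_population_specific(self):
        a = self.pairset(("A", "B"), ("E", "F"))
        b = self.pairset(("A", "B"), start=10)
        shared, ua, ub = compare_reference_sets(a, b)
        assert len(shared) == 1
        assert [p.symbols for p, _ in ua] == [("E", "F")]
        assert not ub

    def test_symbol_order_insensitive(self):
        a = self.pairset(("A", "B"))
        b = self.pairset(("B", "A"), start=10)
        shared, ua, ub = compare_reference_sets(a, b)
        assert len(shared) == 1 and not ua and not ub

    def test_case_sensitivity_default_and_optional(self):
        a = self.pairset(("Abc", "Def"))
        b = self.pairset(("ABC", "DEF"), start=10)
        _, ua, _ = compare_reference_sets(a, b)
        assert len(ua) == 1  # exact matching: no match
        shared, _, _ = compare_reference_sets(a, b, case_insensitive=True)
        assert len(shared) == 1

    def test_missing_symbol_routed_unmappable(self):
        m = make_gene("m0", strand="-", tss=50_000)
        p = make_gene("p0", strand="+", tss=50_200)
        a = DPGSet(pairs=[DPGPair(m, p)])
        _, ua, _ = compare_reference_sets(a, self.pairset(("A", "B"), start=10))
        assert ua == [(a.pairs[0], True)]
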