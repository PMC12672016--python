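import numpy as np
import pandas as pd
import pytest

from dpgkit import simulate as sim
from dpgkit.conservation import (
    ConservationMatrix,
    OrthologMap,
    build_conservation_matrix,
    classify_conservation,
    cluster_species,
    find_osdpgs,
    find_vcdpgs,
    tag_hk_dpgs,
)
from dpgkit.pairs import DPGPair, DPGSet, identify_dpgs
from tests.conftest import catalog_of, make_gene


@pytest.fixture()
def human_pair():
    return DPGPair(
        make_gene("hm", strand="-", tss=10_000, length=2000, symbol="HM"),
        make_gene("hp", strand="+", tss=10_300, length=2000, symbol="HP"),
    )


def target_fixture(d_target):
    """Target-species catalog with the two ortholog genes ``d_target`` apart."""
    tm = make_gene("tm", strand="-", tss=50_000, length=2000)
    tp = make_gene("tp", strand="+", tss=50_000 + d_target, length=2000)
    cat = catalog_of(tm, tp)
    return cat, identify_dpgs(cat)


class TestClassifyConservation:
    def test_preserved_pair_scores_two(self, human_pair):
        cat, ds = target_fixture(400)
        omap = OrthologMap(("h", "t"), {"hm": {"tm"}, "hp": {"tp"}})
        assert classify_conservation(human_pair, omap, cat, ds) == 2

    def test_lost_arrangement_scores_one(self, human_pair):
        cat, ds = target_fixture(5_000)
        omap = OrthologMap(("h", "t"), {"hm": {"tm"}, "hp": {"tp"}})
        assert len(ds) == 0
        assert classify_conservation(human_pair, omap, cat, ds) == 1

    def test_lost_single_and_lost_both(self, human_pair):
        cat, ds = target_fixture(400)
        one = OrthologMap(("h", "t"), {"hm": {"tm"}})
        assert classify_conservation(human_pair, one, cat, ds) == 0
        empty = OrthologMap(("h", "t"), {})
        assert classify_conservation(human_pair, empty, cat, ds) == -1

    def test_many_to_many_needs_only_one_combination(self, human_pair):
        cat, ds = target_fixture(400)
        far = make_gene("tm2", strand="-", tss=200_000, length=2000)
        cat2 = catalog_of(*cat.genes, far)
        omap = OrthologMap(("h", "t"), {"hm": {"tm", "tm2"}, "hp": {"tp"}})
        assert classify_conservation(human_pair, omap, cat2, identify_dpgs(cat2)) == 2

    def test_ortholog_absent_from_target_annotation_ignored(self, human_pair):
        cat, ds = target_fixture(400)
        omap = OrthologMap(("h", "t"), {"hm": {"ghost"}, "hp": {"tp"}})
        assert classify_conservation(human_pair, omap, cat, ds) == 0

    def test_code_monotone_under_ortholog_deletion(self, human_pair):
        """Removing one member's ortholog can never raise the code."""
        cat, ds = target_fixture(400)
        full = {"hm": {"tm"}, "hp": {"tp"}}
        code_full = classify_conservation(human_pair, OrthologMap(("h", "t"), dict(full)), cat, ds)
        for drop in ("hm", "hp"):
            reduced = {k: v for k, v in full.items() if k != drop}
            code = classify_conservation(human_pair, OrthologMap(("h", "t"), reduced), cat, ds)
            assert code <= code_full


class TestConservationMatrix:
    def test_planted_two_species_codes(self, human_pair):
        cat2, ds2 = target_fixture(400)
        maps = {
            "spA": OrthologMap(("h", "spA"), {"hm": {"tm"}, "hp": {"tp"}}),
            "spB": OrthologMap(("h", "spB"), {"hm": {"tm"}}),
        }
        mat = build_conservation_matrix(
            DPGSet(pairs=[human_pair]),
            ["spA", "spB"],
            maps,
            {"spA": cat2, "spB": cat2},
            {"spA": ds2, "spB": ds2},
        )
        assert mat.data.values.tolist() == [[2, 0]]

    def test_species_order_invariance(self, cohort30, spec30):
        _, dpgset, _ = cohort30
        fx = sim.simulate_orthologs(spec30, dpgset, ["s1", "s2", "s3"])
        args = (
            {s: f.ortholog_map for s, f in fx.items()},
            {s: f.catalog for s, f in fx.items()},
            {s: f.dpgset for s, f in fx.items()},
        )
        m1 = build_conservation_matrix(dpgset, ["s1", "s2", "s3"], *args)
        m2 = build_conservation_matrix(dpgset, ["s3", "s1", "s2"], *args)
        assert m1.data.equals(m2.data[["s1", "s2", "s3"]])

    def test_missing_species_inputs_named(self, cohort30):
        _, dpgset, _ = cohort30
        with pytest.raises(ValueError, match="spX"):
            build_conservation_matrix(dpgset, ["spX"], {}, {})

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="codes"):
            ConservationMatrix(pd.DataFrame({"s": [3]}, index=["p"]))

    def test_planted_recovery(self, cohort30, spec30):
        _, dpgset, _ = cohort30
        fx = sim.simulate_orthologs(spec30, dpgset, ["s1", "s2"])
        mat = build_conservation_matrix(
            dpgset,
            ["s1", "s2"],
            {s: f.ortholog_map for s, f in fx.items()},
            {s: f.catalog for s, f in fx.items()},
            {s: f.dpgset for s, f in fx.items()},
        )
        for sp, f in fx.items():
            for pid, code in f.codes.items():
                assert mat.data.loc[pid, sp] == code


class TestDerivedSets:
    def random_matrix(self, seed, n_pairs=40, n_species=5):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.choice([2, 1, 0, -1], size=(n_pairs, n_species)),
            index=[f"p{i}" for i in range(n_pairs)],
            columns=[f"s{j}" for j in range(n_species)],
        )
        return ConservationMatrix(data)

    def test_vcdpg_rule_boundaries(self):
        mat = ConservationMatrix(
            pd.DataFrame({"sA": [2, 2], "sB": [2, 1]}, index=["all2", "one1"])
        )
        assert find_vcdpgs(mat) == ["all2"]
        assert find_vcdpgs(mat, min_code=1) == ["all2", "one1"]

    def test_vcdpg_equals_row_scan(self):
        for seed in range(5):
            mat = self.random_matrix(seed)
            expected = [
                pid for pid, row in mat.data.iterrows() if all(c >= 2 for c in row)
            ]
            assert find_vcdpgs(mat) == expected

    def test_osdpg_rule(self):
        mat = ConservationMatrix(
            pd.DataFrame(
                {"s1": [2, 2], "s2": [1, 2], "s3": [2, 2], "s4": [2, 2]},
                index=["lost_orient", "all2"],
            )
        )
        assert find_osdpgs(mat) == ["lost_orient"]
        assert find_osdpgs(mat, species_subset=["s1", "s3"]) == []


class TestHousekeeping:
    def pairset(self):
        pairs = []
        for i, (sa, sb) in enumerate([("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")]):
            pairs.append(
                DPGPair(
                    make_gene(f"m{i}", strand="-", tss=50_000 * (i + 1), symbol=sa),
                    make_gene(f"p{i}", strand="+", tss=50_000 * (i + 1) + 300, symbol=sb),
                )
            )
        return DPGSet(pairs=pairs)

    def test_one_hk_member_flags_pair(self):
        flags, prop = tag_hk_dpgs(self.pairset(), ["A", "D", "E", "F"])
        assert list(flags.values()) == [True, True, True, False]
        assert prop == 0.75

    def test_empty_hk_list_warns_all_false(self):
        with pytest.warns(UserWarning, match="empty"):
            flags, prop = tag_hk_dpgs(self.pairset(), [])
        assert not any(flags.values()) and prop == 0.0


def naive_complete_linkage(points):
    """O(n^3) agglomeration oracle returning sorted merge heights."""
    clusters = [[i] for i in range(len(points))]
    dist = lambda a, b: float(np.linalg.norm(points[a] - points[b]))
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist(a, b) for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


class TestClusterSpecies:
    def test_identical_rows_merge_first(self):
        mat = ConservationMatrix(
            pd.DataFrame(
                {"sA": [2, 1, 0], "sB": [2, 1, 0], "sC": [-1, -1, 2]},
                index=["p1", "p2", "p3"],
            )
        )
        order, link = cluster_species(mat)
        assert link[0, 2] == 0.0  # first merge at distance zero
        assert set(order[:2]) == {"sA", "sB"} or set(order[-2:]) == {"sA", "sB"}

    def test_forced_topology(self):
        mat = ConservationMatrix(
            pd.DataFrame(
                {"A": [2, 2, 2], "B": [2, 2, 2], "C": [-1, -1, -1]},
                index=["p1", "p2", "p3"],
            )
        )
        order, link = cluster_species(mat)
        # A and B merge first, C joins last
        assert {order.index("A"), order.index("B")} in ({0, 1}, {1, 2})
        assert abs(order.index("C") - order.index("A")) >= 1
        assert link[0, 2] == 0.0 and link[1, 2] > 0

    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            rng.choice([2, 1, 0, -1], size=(20, 5)).T.astype(int),
            index=[f"s{j}" for j in range(5)],
            columns=[f"p{i}" for i in range(20)],
        )
        mat = ConservationMatrix(data.T)
        _, link = cluster_species(mat)
        expected = naive_complete_linkage(data.to_numpy(dtype=float))
        assert np.allclose(sorted(link[:, 2]), expected)

    def test_single_species_rejected(self):
        mat = ConservationMatrix(pd.DataFrame({"s": [2]}, index=["p"]))
        with pytest.raises(ValueError, match="two species"):
            cluster_species(mat)
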