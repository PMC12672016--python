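import numpy as np
import pandas as pd
import pytest

from dpgkit import simulate as sim
from dpgkit.pairs import DPGPair
from dpgkit.signals import (
    SignalTrack,
    average_tracks,
    detect_signal_peaks,
    extract_scaled_profile,
    gc_profile,
    group_average_profiles,
    promoter_signal_fc,
    reverse_complement,
    select_core_tfs,
    shared_tfs,
)
from tests.conftest import make_gene


def pair_at(d, tss_minus=50_000, length=3000):
    return DPGPair(
        make_gene("m", strand="-", tss=tss_minus, length=length),
        make_gene("p", strand="+", tss=tss_minus + d, length=length),
    )


def constant_track(chrom="chr1", start=1, end=200_000, value=3.0):
    t = SignalTrack(label="const")
    t.add_intervals(chrom, [start], [end], [value])
    return t


class TestGcProfile:
    @pytest.mark.parametrize(
        "seq,expected",
        [("G" * 50, 1.0), ("AT" * 25, 0.0), ("ATGC" * 13, 0.5)],
    )
    def test_single_window_values(self, seq, expected):
        prof = gc_profile(seq, window=len(seq))
        assert prof[0] == expected

    def test_uniform_sequence_uniform_profile(self):
        # window a multiple of the repeat period: every window sees equal GC
        prof = gc_profile("ATGC" * 40, window=48, step=4)
        assert np.allclose(prof, 0.5)

    def test_all_n_window_is_nan(self):
        prof = gc_profile("N" * 50)
        assert np.isnan(prof[0])

    def test_n_bases_excluded_from_denominator(self):
        prof = gc_profile("G" * 25 + "N" * 25)
        assert prof[0] == 1.0

    def test_short_sequence_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert len(gc_profile("ACGT")) == 0

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 200))
        fwd = gc_profile(seq, window=50, step=1)
        rev = gc_profile(reverse_complement(seq), window=50, step=1)
        assert np.allclose(fwd, rev[::-1])


class TestScaledProfile:
    def test_constant_track_preserved_exactly(self):
        for d in (100, 400, 900, 7):
            prof = extract_scaled_profile(constant_track(), pair_at(d))
            assert prof.shape == (2000,)
            assert np.allclose(prof, 3.0)

    def test_step_edge_lands_mid_profile(self):
        pair = pair_at(500)
        lo, hi = pair.region
        t = SignalTrack()
        mid = (lo + hi) // 2
        t.add_intervals("chr1", [lo - 600, mid + 1], [mid, hi + 600], [0.0, 10.0])
        prof = extract_scaled_profile(t, pair)
        core = prof[500:1500]
        edge = int(np.argmax(np.diff(core)))
        assert abs(edge - 500) <= 1

    @pytest.mark.parametrize("d", [100, 400, 900])
    def test_triangle_apex_maps_to_bin_500(self, d):
        pair = pair_at(d)
        lo, hi = pair.region
        xs = np.arange(lo, hi + 1)
        apex = (lo + hi) / 2
        vals = 100 - np.abs(xs - apex)  # triangular peak at the midpoint
        t = SignalTrack()
        t.add_intervals("chr1", xs, xs, vals)
        core = extract_scaled_profile(t, pair)[500:1500]
        assert abs(int(np.argmax(core)) - 500) <= 1

    def test_orientation_minus_to_plus(self):
        """With overlapping TSSs the profile still runs minus -> plus."""
        pair = pair_at(-300)  # plus TSS left of minus TSS
        lo, hi = pair.region
        t = SignalTrack()
        xs = np.arange(lo, hi + 1)
        t.add_intervals("chr1", xs, xs, np.linspace(0, 10, len(xs)))  # rises left->right
        core = extract_scaled_profile(t, pair)[500:1500]
        # genomic left is the plus TSS; profile starts at the minus TSS (right)
        assert core[0] > core[-1]

    def test_zero_length_interval_replicates_single_base(self):
        pair = pair_at(0)
        t = SignalTrack()
        t.add_intervals("chr1", [pair.minus_gene.tss], [pair.minus_gene.tss], [7.0])
        prof = extract_scaled_profile(t, pair)
        assert np.allclose(prof[500:1500], 7.0)
        assert np.allclose(prof[:500], 0.0)

    def test_dilation_equivariance(self):
        """Dilating interval and track by an integer factor shifts the scaled
        profile by at most one bin."""
        rng = np.random.default_rng(9)
        base = rng.random(100)
        t1 = SignalTrack()
        p1 = pair_at(99)
        lo1, _ = p1.region
        xs = np.arange(lo1, lo1 + 100)
        t1.add_intervals("chr1", xs, xs, base)
        prof1 = extract_scaled_profile(t1, p1, flank=0)
        factor = 4
        t2 = SignalTrack()
        p2 = pair_at(99 * factor + factor - 1)
        lo2, _ = p2.region
        xs2 = np.arange(lo2, lo2 + 400)
        t2.add_intervals("chr1", xs2, xs2, np.repeat(base, factor))
        prof2 = extract_scaled_profile(t2, p2, flank=0)
        assert np.max(np.abs(prof1 - prof2)) < np.ptp(base) * 0.51
        assert abs(int(np.argmax(prof1)) - int(np.argmax(prof2))) <= 1


class TestGroupAverages:
    def test_mean_of_identical_profiles(self):
        v = np.arange(10.0)
        out = group_average_profiles({"a": v, "b": v.copy()}, {"a": "high", "b": "high"})
        assert np.allclose(out["high"].values, v)
        assert out["high"].n_pairs == 2

    def test_opposite_profiles_cancel(self):
        v = np.arange(10.0) - 5
        out = group_average_profiles({"a": v, "b": -v}, {"a": "m", "b": "m"})
        assert np.allclose(out["m"].values, 0)

    def test_matches_naive_positionwise_mean(self, rng):
        profiles = {f"p{i}": rng.random(50) for i in range(50)}
        levels = {f"p{i}": ("high", "medium")[i % 2] for i in range(50)}
        out = group_average_profiles(profiles, levels)
        for level in ("high", "medium"):
            expected = np.mean([profiles[k] for k in profiles if levels[k] == level], axis=0)
            assert np.allclose(out[level].values, expected)

    def test_unlabelled_pairs_skipped(self):
        out = group_average_profiles({"a": np.ones(3)}, {})
        assert out == {}


class TestPeaks:
    def test_single_triangle_apex(self):
        prof = np.concatenate([np.arange(50.0), np.arange(50.0)[::-1]])
        assert detect_signal_peaks(prof) == [49]

    def test_two_gaussians(self):
        x = np.arange(1000.0)
        prof = np.exp(-((x - 250) ** 2) / 500) + np.exp(-((x - 750) ** 2) / 500)
        peaks = detect_signal_peaks(prof)
        assert len(peaks) == 2
        assert abs(peaks[0] - 250) <= 1 and abs(peaks[1] - 750) <= 1

    def test_monotone_ramp_no_peaks(self):
        assert detect_signal_peaks(np.arange(100.0)) == []

    def test_flat_profile_no_peaks(self):
        assert detect_signal_peaks(np.full(100, 2.0)) == []

    def test_plateau_reports_leftmost_index(self):
        prof = np.array([0, 0, 5, 5, 5, 0, 0], dtype=float)
        assert detect_signal_peaks(prof) == [2]


class TestPromoterFc:
    def test_ratio_and_identity(self):
        pair = pair_at(900)
        t = SignalTrack()
        m, p = pair.minus_gene.tss, pair.plus_gene.tss
        t.add_intervals("chr1", [m - 250, p - 250], [m + 250, p + 250], [10.0, 5.0])
        assert promoter_signal_fc(t, pair) == pytest.approx(2.0)
        t2 = constant_track(value=4.0)
        assert promoter_signal_fc(t2, pair) == pytest.approx(1.0)

    def test_zero_signal_side_undefined(self):
        pair = pair_at(900)
        t = SignalTrack()
        m = pair.minus_gene.tss
        t.add_intervals("chr1", [m - 250], [m + 250], [10.0])
        assert promoter_signal_fc(t, pair) is None


class TestSharedTfs:
    def hit_table(self, rows):
        return pd.DataFrame(rows, columns=["region_id", "tf_id", "start", "stop", "score", "strand"])

    def test_both_sides_required(self):
        pair = pair_at(300)
        table = self.hit_table(
            [("m", "TF1", 1, 10, 9.0, "+"), ("p", "TF1", 5, 14, 8.0, "-"), ("m", "TF2", 1, 10, 7.0, "+")]
        )
        assert shared_tfs(table, pair) == {"TF1"}

    def test_empty_table(self):
        assert shared_tfs(self.hit_table([]), pair_at(300)) == set()

    def test_core_tf_ranking_recovers_planted_coexpressed_tf(self, rng):
        pair = pair_at(300)
        n = 60
        driver = rng.lognormal(2, 1, n)
        tpm = pd.DataFrame(
            {
                f"s{i}": {
                    "m": driver[i] * rng.lognormal(0, 0.05),
                    "p": driver[i] * rng.lognormal(0, 0.05),
                    "TFgood": driver[i] * rng.lognormal(0, 0.05),
                    "TFnoise1": rng.lognormal(2, 1),
                    "TFnoise2": rng.lognormal(2, 1),
                }
                for i in range(n)
            }
        )
        meta = pd.DataFrame(
            {"tissue": ["T1"] * n, "rin": [8.0] * n}, index=[f"s{i}" for i in range(n)]
        )
        from dpgkit.coexpression import ExpressionStore

        store = ExpressionStore(tpm=tpm, sample_meta=meta)
        ranked = select_core_tfs(["TFgood", "TFnoise1", "TFnoise2", "TFabsent"], store, pair, k=3)
        assert ranked[0][0] == "TFgood"
        assert len(ranked) == 3

    def test_k_zero(self, expression30, cohort30):
        _, dpgset, _ = cohort30
        assert select_core_tfs([], expression30.store, dpgset.pairs[0], k=0) == []


class TestTrackIo:
    def test_bedgraph_round_trip(self, tmp_path, spec30, cohort30):
        _, dpgset, _ = cohort30
        levels = {p.pair_id: "high" for p in dpgset.pairs}
        path = str(tmp_path / "sig.bedgraph")
        track = sim.simulate_signal_track(spec30, dpgset, levels, bedgraph_path=path)
        read_back = SignalTrack.from_bedgraph(path)
        pair = dpgset.pairs[0]
        lo, hi = pair.region
        assert np.allclose(
            track.per_base(pair.chrom, lo - 100, hi + 100),
            read_back.per_base(pair.chrom, lo - 100, hi + 100),
        )

    def test_average_tracks_positionwise_mean(self):
        t1 = SignalTrack()
        t1.add_intervals("chr1", [10], [19], [4.0])
        t2 = SignalTrack()
        t2.add_intervals("chr1", [15], [24], [2.0])
        avg = average_tracks([t1, t2])
        assert np.allclose(avg.per_base("chr1", 10, 14), 2.0)
        assert np.allclose(avg.per_base("chr1", 15, 19), 3.0)
        assert np.allclose(avg.per_base("chr1", 20, 24), 1.0)
        assert np.allclose(avg.per_base("chr1", 25, 30), 0.0)

    def test_overlapping_intervals_rejected(self):
        t = SignalTrack()
        with pytest.raises(ValueError, match="overlap"):
            t.add_intervals("chr1", [1, 5], [6, 9], [1.0, 2.0])
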