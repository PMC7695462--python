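"""Sample summaries, binning, clustering and footprint maps."""

import numpy as np
import pytest

from dloopmap.convert import CONVERTED, UNCONVERTED
from dloopmap.peaks import Footprint, PeakThreshold, call_peaks_all
from dloopmap.profile import (
    bin_distribution,
    cluster_footprints,
    export_footprint_map,
    length_stats,
    parse_footprint_map,
    percent_peak,
    summarize_sample,
)
from dloopmap.refmodel import DonorReference
from dloopmap.simulate import LengthModel, SimulationConfig, simulate_dataset
from dloopmap.convert import process_reads

from _oracles import make_track


def fp(read_id, start, end, strand="top", n_cyt=10, n_conv=8):
    return Footprint(read_id, strand, start, end, end - start, n_cyt, n_conv)


class TestPercentPeak:
    def test_zero_peaks(self):
        assert percent_peak(0, 100) == 0.0

    def test_published_style_counts(self):
        assert round(percent_peak(485, 3621), 1) == 13.4
        assert percent_peak(310, 2673) == pytest.approx(11.5974, abs=1e-3)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_peak(0, 0)

    def test_complement_sums_to_100(self):
        for n_peak, n_total in [(0, 7), (3, 7), (7, 7), (485, 3621)]:
            assert percent_peak(n_peak, n_total) + percent_peak(n_total - n_peak, n_total) == 100.0


class TestLengthStats:
    def test_single_footprint_flags_sd(self):
        s = length_stats([fp("a", 100, 300)])
        assert s.mean == 200 and s.sd is None and s.n == 1

    def test_hand_arithmetic(self):
        s = length_stats([fp("a", 0, 100), fp("b", 0, 300)])
        assert s.mean == 200
        assert s.sd == pytest.approx(141.42, abs=0.01)

    def test_empty_is_empty_not_zero(self):
        s = length_stats([])
        assert s.n == 0 and s.mean is None and s.fraction_over_cutoff is None

    def test_cutoff_fraction(self):
        s = length_stats([fp("a", 0, 300), fp("b", 0, 500)], cutoff=400)
        assert s.fraction_over_cutoff == 0.5


class TestBinDistribution:
    def ref(self):
        return DonorReference("r", "A" * 600, 100, 600)

    def test_overlap_rule(self):
        # footprint [150, 370] overlaps bins [100,200), [200,300), [300,400)
        dist = bin_distribution([fp("a", 150, 370)], self.ref(), 100)
        assert [b for b, v in zip(dist.bins, dist.values) if v] == [
            (100, 200), (200, 300), (300, 400)
        ]
        assert set(dist.values) <= {0.0, 1.0}

    def test_duplicates_normalize_away(self):
        one = bin_distribution([fp("a", 150, 370)], self.ref(), 100)
        two = bin_distribution([fp("a", 150, 370), fp("b", 150, 370)], self.ref(), 100)
        assert np.allclose(one.values, two.values)

    def test_footprint_in_one_bin_hits_one_bin(self):
        dist = bin_distribution([fp("a", 210, 280)], self.ref(), 100)
        assert np.count_nonzero(dist.values) == 1

    def test_partial_final_bin_kept(self):
        ref = DonorReference("r", "A" * 550, 100, 550)
        dist = bin_distribution([fp("a", 120, 130)], ref, 100)
        assert dist.bins[-1] == (500, 550)

    def test_zero_footprints_warns_all_zero(self):
        with pytest.warns(UserWarning):
            dist = bin_distribution([], self.ref(), 100)
        assert not dist.values.any()

    def test_three_prime_bias_visible_in_bins(self, donor_931):
        cfg = SimulationConfig(
            n_molecules=600, dloop_fraction=1.0, bottom_to_top_read_ratio=0.0,
            indel_rate=0.0, truncation_fraction=0.0, breathing_rate=0.0,
            position_model="three_prime_biased",
            length_model=LengthModel(kind="fixed", length=210), seed=77,
        )
        reads, _ = simulate_dataset(cfg, donor_931)
        tracks, _ = process_reads(reads, donor_931)
        fps = [f for v in call_peaks_all(tracks).values() for f in v]
        dist = bin_distribution(fps, donor_931, 100)
        v = dist.values
        # 3'-enriched: rising over the 5' half, mode in the 3' half, and more
        # mass near the 3' end than the 5' end (a terminal dip is expected —
        # bins within one footprint length of the homology end see only the
        # tail of the 3'-edge distribution)
        half = len(v) // 2
        assert np.all(np.diff(v[:half]) >= -0.02)
        assert int(np.argmax(v)) >= half
        assert v[-3:].mean() > v[:3].mean()


class TestClustering:
    def test_orders_by_start(self):
        fbr = {"a": [fp("a", 300, 400)], "b": [fp("b", 100, 200)], "c": [fp("c", 200, 300)]}
        assert cluster_footprints(fbr) == ["b", "c", "a"]

    def test_tie_break_on_end_then_id(self):
        fbr = {"x": [fp("x", 100, 250)], "y": [fp("y", 100, 200)]}
        assert cluster_footprints(fbr) == ["y", "x"]
        fbr = {"x": [fp("x", 100, 200)], "y": [fp("y", 100, 200)]}
        assert cluster_footprints(fbr) == ["x", "y"]

    def test_empty_and_permutation(self):
        assert cluster_footprints({}) == []
        fbr = {f"r{i}": [fp(f"r{i}", 500 - i, 600 - i)] for i in range(20)}
        out = cluster_footprints(fbr)
        assert sorted(out) == sorted(fbr)  # permutation, nothing gained or lost
        assert cluster_footprints({k: fbr[k] for k in out}) == out  # idempotent


class TestSummarize:
    def test_multi_footprint_read_counts_once(self):
        tracks = [make_track(range(0, 100, 2), [UNCONVERTED] * 50, read_id=f"r{i}")
                  for i in range(4)]
        fbr = {"r0": [fp("r0", 0, 50), fp("r0", 60, 90)], "r1": [fp("r1", 0, 50)]}
        s = summarize_sample(tracks, fbr)["top"]
        assert s.n_total_reads == 4
        assert s.n_peak_reads == 2
        assert s.n_footprints == 3
        assert s.n_multi_footprint_reads == 1
        assert s.percent_peak == 50.0


class TestFootprintMap:
    def make_inputs(self):
        ref = DonorReference("r", "CA" * 100, 0, 200)  # cytosines at even positions
        t1 = make_track(range(0, 200, 2), [CONVERTED] * 60 + [UNCONVERTED] * 40, read_id="r1")
        t2 = make_track(range(0, 200, 2), [UNCONVERTED] * 100, read_id="r2")
        fbr = {"r1": [fp("r1", 0, 118)], "r2": []}
        return ref, [t1, t2], fbr

    def test_round_trip_recovers_intervals(self, tmp_path):
        ref, tracks, fbr = self.make_inputs()
        path = export_footprint_map(tracks, fbr, ref, tmp_path / "map_top", png=False)
        intervals = parse_footprint_map(path)
        assert intervals["r1"] == [(0, 118)]
        assert intervals["r2"] == []

    def test_zero_conversion_row_all_unconverted(self, tmp_path):
        ref, tracks, fbr = self.make_inputs()
        path = export_footprint_map(tracks, fbr, ref, tmp_path / "m", png=False)
        rows = {l.split("\t")[0]: l.split("\t")[1].rstrip()
                for l in path.read_text().splitlines() if not l.startswith("#")}
        assert set(rows["r2"]) == {"u"}

    def test_mixed_strands_rejected(self, tmp_path):
        ref, tracks, fbr = self.make_inputs()
        bad = make_track(range(1, 201, 2), [UNCONVERTED] * 100, read_id="rb", strand="bottom")
        with pytest.raises(ValueError, match="mixed"):
            export_footprint_map(tracks + [bad], fbr, ref, tmp_path / "m", png=False)

    def test_png_written(self, tmp_path):
        ref, tracks, fbr = self.make_inputs()
        export_footprint_map(tracks, fbr, ref, tmp_path / "m", png=True)
        assert (tmp_path / "m.png").stat().st_size > 0
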