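"""Simulator: determinism, conservation, conversion laws, artefact injection."""

import math

import numpy as np
import pytest

from dloopmap.convert import CONVERTED, call_conversions
from dloopmap.refmodel import TopologyModel, supercoil_capacity
from dloopmap.simulate import (
    LengthModel,
    SimulationConfig,
    simulate_dataset,
    simulate_ssdna_control,
    write_sam,
)
from dloopmap.substrates import make_ssdna_control


def clean_config(**kw):
    """Config without read artefacts unless overridden."""
    base = dict(indel_rate=0.0, truncation_fraction=0.0, seed=42)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminismAndConservation:
    def test_identical_seed_identical_sam(self, donor_931, tmp_path):
        cfg = SimulationConfig(n_molecules=40, seed=11)
        for tag in ("a", "b"):
            reads, _ = simulate_dataset(cfg, donor_931)
            write_sam(reads, donor_931, tmp_path / f"{tag}.sam")
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()

    def test_different_seed_differs(self, donor_931):
        r1, _ = simulate_dataset(SimulationConfig(n_molecules=40, seed=1), donor_931)
        r2, _ = simulate_dataset(SimulationConfig(n_molecules=40, seed=2), donor_931)
        assert any(a.query_sequence != b.query_sequence for a, b in zip(r1, r2))

    def test_one_read_per_molecule(self, donor_931):
        cfg = SimulationConfig(n_molecules=75, seed=3)
        reads, truth = simulate_dataset(cfg, donor_931)
        assert len(reads) == len(truth) == 75
        assert [r.query_name for r in reads] == [t.molecule_id for t in truth]

    def test_zero_molecules(self, donor_931):
        reads, truth = simulate_dataset(SimulationConfig(n_molecules=0), donor_931)
        assert reads == [] and truth == []


class TestTruthIntervals:
    def test_intervals_inside_homology_and_capped(self, donor_931):
        cfg = clean_config(n_molecules=300, dloop_fraction=1.0)
        _, truth = simulate_dataset(cfg, donor_931)
        cap = supercoil_capacity(cfg.topology, donor_931.homology_length)
        for t in truth:
            assert donor_931.homology_start <= t.dloop_start < t.dloop_end <= donor_931.homology_end
            assert t.dloop_end - t.dloop_start <= cap

    def test_linear_mode_reaches_past_supercoil_cap(self, donor_931):
        cfg = clean_config(
            n_molecules=300,
            dloop_fraction=1.0,
            topology=TopologyModel(mode="linear"),
            length_model=LengthModel(kind="uniform_to_cap", min_length=100),
        )
        _, truth = simulate_dataset(cfg, donor_931)
        lengths = [t.dloop_end - t.dloop_start for t in truth]
        assert max(lengths) > 260  # beyond any supercoiled cap
        assert max(lengths) <= donor_931.homology_length

    def test_capacity_below_min_length_errors(self, donor_931):
        cfg = clean_config(
            dloop_fraction=1.0,
            topology=TopologyModel(sigma=-0.01),  # cap = 30 nt
            length_model=LengthModel(kind="fixed", length=100),
        )
        with pytest.raises(ValueError, match="below the minimum"):
            simulate_dataset(cfg, donor_931)

    def test_three_prime_bias_shifts_midpoints(self, donor_931):
        kw = dict(
            n_molecules=400, dloop_fraction=1.0,
            length_model=LengthModel(kind="fixed", length=200),
        )
        _, t_uni = simulate_dataset(clean_config(position_model="uniform", **kw), donor_931)
        _, t_bias = simulate_dataset(
            clean_config(position_model="three_prime_biased", **kw), donor_931
        )
        mid = lambda ts: np.mean([(t.dloop_start + t.dloop_end) / 2 for t in ts])
        assert mid(t_bias) > mid(t_uni)


class TestConversionChemistry:
    def test_degenerate_parameters_are_exact(self, donor_931):
        """eff=1, breathing=0, top-only: converted set == truth cytosines."""
        cfg = clean_config(
            n_molecules=20, dloop_fraction=1.0, conversion_efficiency=1.0,
            breathing_rate=0.0, bottom_to_top_read_ratio=0.0,
            length_model=LengthModel(kind="fixed", length=210),
        )
        reads, truth = simulate_dataset(cfg, donor_931)
        for read, t in zip(reads, truth):
            assert t.sampled_strand == "top"
            track = call_conversions(read, donor_931)
            conv = track.top_positions[track.top_status == CONVERTED]
            expected = donor_931.top_cytosine_positions
            expected = expected[(expected >= t.dloop_start) & (expected < t.dloop_end)]
            assert conv.tolist() == expected.tolist()

    def test_no_breathing_means_silent_bottom_reads(self, donor_931):
        cfg = clean_config(n_molecules=120, breathing_rate=0.0)
        reads, truth = simulate_dataset(cfg, donor_931)
        for read, t in zip(reads, truth):
            if t.sampled_strand == "bottom":
                track = call_conversions(read, donor_931)
                assert track.n_GA == 0 and track.n_CT == 0

    def test_strand_ratio(self, donor_931):
        cfg = clean_config(n_molecules=3000, bottom_to_top_read_ratio=2.0)
        _, truth = simulate_dataset(cfg, donor_931)
        frac_top = np.mean([t.sampled_strand == "top" for t in truth])
        assert abs(frac_top - 1 / 3) < 0.03


class TestReadArtefacts:
    def test_truncation_fraction(self, donor_931):
        cfg = SimulationConfig(
            n_molecules=800, truncation_fraction=0.3, indel_rate=0.0, seed=5
        )
        reads, _ = simulate_dataset(cfg, donor_931)
        short = [r for r in reads if r.reference_end < 0.5 * len(donor_931)]
        assert 0.25 < len(short) / len(reads) < 0.35
        for r in short:
            assert r.reference_end - r.reference_start < 0.5 * len(donor_931)

    def test_indels_recorded_in_cigar(self, donor_931):
        cfg = SimulationConfig(n_molecules=30, indel_rate=0.01, truncation_fraction=0.0, seed=6)
        reads, _ = simulate_dataset(cfg, donor_931)
        ops = {op for r in reads for op, _ in r.cigartuples}
        assert 1 in ops and 2 in ops  # insertions and deletions both occur
        for r in reads:  # CIGAR consumes the whole query
            q = sum(ln for op, ln in r.cigartuples if op in (0, 1))
            assert q == len(r.query_sequence)


class TestSsdnaControl:
    def test_full_and_zero_efficiency(self):
        seq = make_ssdna_control(n_cytosines=50)
        full = simulate_ssdna_control(clean_config(conversion_efficiency=1.0), seq, 3)
        none = simulate_ssdna_control(clean_config(conversion_efficiency=0.0), seq, 3)
        assert all("C" not in r.query_sequence for r in full)
        assert all(r.query_sequence == seq for r in none)

    def test_every_read_converts_at_58_percent(self):
        """P(zero conversions over 420 cytosines) = 0.42^420 ~ 1e-158."""
        seq = make_ssdna_control(n_cytosines=420)
        reads = simulate_ssdna_control(clean_config(), seq, 21)
        assert len(reads) == 21
        n_c = seq.count("C")
        for r in reads:
            assert r.query_sequence.count("C") < n_c  # >=1 conversion on every read

    def test_mean_conversion_matches_binomial_law(self):
        """Mean converted fraction over 1000 reads within 3 SE of 0.58."""
        seq = make_ssdna_control(n_cytosines=420)
        n_c = seq.count("C")
        reads = simulate_ssdna_control(clean_config(conversion_efficiency=0.58), seq, 1000)
        fracs = [(n_c - r.query_sequence.count("C")) / n_c for r in reads]
        se = math.sqrt(0.58 * 0.42 / n_c) / math.sqrt(1000)
        assert abs(np.mean(fracs) - 0.58) < 3 * se
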