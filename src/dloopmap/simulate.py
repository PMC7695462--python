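"""Synthetic bisulfite-footprinting data with known ground truth.

The generator emulates the data-generating process of the mapping assay
on a donor amplicon:

* a fraction of donor molecules carry one D-loop inside the homology
  window, with length capped by donor topology (|sigma|*L on supercoiled
  donors) and a 3'-biased position law;
* non-denaturing bisulfite converts cytosines on the displaced (top)
  strand inside the D-loop with ~58% per-cytosine efficiency, while
  duplex cytosines on either strand convert only at a small "breathing"
  background rate;
* each molecule is sequenced from one strand, with bottom-strand reads
  over-represented ~2:1; bottom-strand conversions appear as G->A in
  reference orientation;
* long-read artefacts: sporadic 1-nt indels and a fraction of reads
  truncated below half the expected amplicon length.

Reads are emitted pre-aligned (reference orientation, CIGAR reflecting
the injected indels); read mapping is upstream of this package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
import yaml

from .refmodel import DonorReference, TopologyModel, supercoil_capacity

__all__ = [
    "LengthModel",
    "SimulationConfig",
    "GroundTruthRecord",
    "AlignedRead",
    "simulate_dataset",
    "simulate_ssdna_control",
    "write_sam",
    "read_sam",
    "write_truth_bed",
    "write_manifest",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class LengthModel:
    """Law for drawing the true D-loop length (nt), before the topology cap.

    kind:
      ``fixed``            — always ``length`` nt.
      ``uniform_to_cap``   — uniform integer in [min_length, cap].
      ``truncated_normal`` — Normal(mean, sd) truncated to [min_length, cap].

    ``min_length`` defaults to 100 nt, the detection floor of the default
    t40w50 peak threshold.  ``max_length``, if set, tightens the cap
    (the topology/homology cap always applies as well).
    """

    kind: str = "truncated_normal"
    length: int | None = None
    mean: float = 210.0
    sd: float = 50.0
    min_length: int = 100
    max_length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "uniform_to_cap", "truncated_normal"):
            raise ValueError(f"unknown length model kind {self.kind!r}")
        if self.kind == "fixed" and (self.length is None or self.length <= 0):
            raise ValueError("fixed length model requires a positive 'length'")

    def minimum(self) -> int:
        return int(self.length) if self.kind == "fixed" else int(self.min_length)

    def draw(self, rng: np.random.Generator, cap: int) -> int:
        if self.kind == "fixed":
            return int(self.length)
        if self.max_length is not None:
            cap = min(cap, self.max_length)
        lo = self.min_length
        if self.kind == "uniform_to_cap":
            return int(rng.integers(lo, cap + 1))
        while True:  # truncated normal via rejection; acceptance is high for sane params
            x = rng.normal(self.mean, self.sd)
            if lo <= x <= cap:
                return int(round(x))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults reflect the assay as characterised on real data: 58%
    per-cytosine conversion on the displaced strand, near-zero duplex
    background, ~2x bottom-strand read excess, a 13.4% D-loop incidence,
    and sparse long-read indels/truncations.
    """

    n_molecules: int = 1000
    dloop_fraction: float = 0.134
    topology: TopologyModel = field(default_factory=TopologyModel)
    position_model: str = "three_prime_biased"  # or "uniform"
    length_model: LengthModel = field(default_factory=LengthModel)
    conversion_efficiency: float = 0.58
    breathing_rate: float = 0.005
    bottom_to_top_read_ratio: float = 2.0
    indel_rate: float = 0.002
    truncation_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dloop_fraction",
            "conversion_efficiency",
            "breathing_rate",
            "indel_rate",
            "truncation_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if self.bottom_to_top_read_ratio < 0:
            raise ValueError("bottom_to_top_read_ratio must be >= 0")
        if self.position_model not in ("uniform", "three_prime_biased"):
            raise ValueError(f"unknown position model {self.position_model!r}")
        if isinstance(self.topology, dict):
            self.topology = TopologyModel.from_dict(self.topology)
        if isinstance(self.length_model, dict):
            self.length_model = LengthModel(**self.length_model)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["topology"]["mode"] = self.topology.mode.value
        return d


@dataclass(frozen=True)
class GroundTruthRecord:
    """True state of one simulated donor molecule."""

    molecule_id: str
    has_dloop: bool
    dloop_start: int  # 0-based half-open; -1 if no D-loop
    dloop_end: int
    sampled_strand: str  # 'top' or 'bottom'


@dataclass
class AlignedRead:
    """A pre-aligned read in reference orientation (pysam-compatible attributes)."""

    query_name: str
    reference_name: str
    reference_start: int
    query_sequence: str
    cigartuples: list[tuple[int, int]]  # pysam op codes: 0=M, 1=I, 2=D

    @property
    def reference_end(self) -> int:
        return self.reference_start + sum(
            ln for op, ln in self.cigartuples if op in (0, 2, 7, 8)
        )


def _draw_interval(
    rng: np.random.Generator,
    config: SimulationConfig,
    h0: int,
    h1: int,
    cap: int,
) -> tuple[int, int]:
    length = min(config.length_model.draw(rng, cap), h1 - h0)
    if config.position_model == "uniform":
        end = int(rng.integers(h0 + length, h1 + 1))
    else:
        # 3'-biased: linear-ramp density for the 3' edge toward the homology end
        lo, hi = h0 + length, h1
        end = int(round(lo + (hi - lo) * np.sqrt(rng.random())))
    return end - length, end


def _apply_indels_and_cigar(
    rng: np.random.Generator,
    bases: np.ndarray,
    indel_rate: float,
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """Inject 1-nt indels into an M-aligned base array.

    Returns (query sequence, cigartuples, indel events) where events are
    (reference position, op) with op 1=I (insertion anchored before that
    reference position) and 2=D (deletion of that reference base).
    """
    span = len(bases)
    n_indel = rng.binomial(span, indel_rate) if indel_rate > 0 else 0
    if n_indel == 0:
        return bases.tobytes().decode(), [(0, span)], []
    pos = np.sort(rng.choice(span, size=n_indel, replace=False))
    kinds = rng.integers(0, 2, size=n_indel)  # 0 -> deletion, 1 -> insertion
    cigar: list[tuple[int, int]] = []
    parts: list[bytes] = []
    events: list[tuple[int, int]] = []
    prev = 0
    for p, k in zip(pos.tolist(), kinds.tolist()):
        if p > prev:
            cigar.append((0, p - prev))
            parts.append(bases[prev:p].tobytes())
        if k == 0:
            cigar.append((2, 1))
            events.append((p, 2))
            prev = p + 1
        else:
            cigar.append((1, 1))
            parts.append(rng.choice(_BASES))
            events.append((p, 1))
            prev = p
    if prev < span:
        cigar.append((0, span - prev))
        parts.append(bases[prev:].tobytes())
    # merge adjacent same-op blocks (two insertions drawn at the same anchor etc.)
    merged: list[tuple[int, int]] = []
    for op, ln in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return b"".join(parts).decode(), merged, events


def simulate_dataset(
    config: SimulationConfig, reference: DonorReference
) -> tuple[list[AlignedRead], list[GroundTruthRecord]]:
    """Simulate one amplicon dataset; deterministic for a fixed config.seed.

    Every molecule yields exactly one read (truncated reads are emitted and
    left for the downstream length filter).  Read i corresponds to truth
    record i (read_id == molecule_id).
    """
    h0, h1 = reference.homology_start, reference.homology_end
    if h1 <= h0:
        raise ValueError("reference homology window is empty")
    cap = supercoil_capacity(config.topology, h1 - h0)
    if config.dloop_fraction > 0 and cap < config.length_model.minimum():
        raise ValueError(
            f"topology capacity {cap} nt is below the minimum representable "
            f"D-loop length {config.length_model.minimum()} nt"
        )
    rng = np.random.default_rng(config.seed)
    ref_arr = np.frombuffer(reference.sequence.encode(), dtype="S1")
    top_c = reference.top_cytosine_positions
    bot_c = reference.bottom_cytosine_positions
    p_top = 1.0 / (1.0 + config.bottom_to_top_read_ratio)
    L = len(reference)

    reads: list[AlignedRead] = []
    truth: list[GroundTruthRecord] = []
    for i in range(config.n_molecules):
        mol_id = f"mol{i:06d}"
        has_dloop = bool(rng.random() < config.dloop_fraction)
        if has_dloop:
            s, e = _draw_interval(rng, config, h0, h1, cap)
        else:
            s, e = -1, -1
        strand = "top" if rng.random() < p_top else "bottom"
        truth.append(GroundTruthRecord(mol_id, has_dloop, s, e, strand))

        # truncation decided first so conversions/indels are drawn on the
        # emitted span only (keeps the per-molecule RNG stream compact)
        span = L
        if config.truncation_fraction > 0 and rng.random() < config.truncation_fraction:
            span = max(1, int(L * rng.uniform(0.1, 0.5)))

        bases = ref_arr[:span].copy()
        if strand == "top":
            cs = top_c[top_c < span]
            p = np.full(cs.shape, config.breathing_rate)
            if has_dloop:
                p[(cs >= s) & (cs < e)] = config.conversion_efficiency
            hit = cs[rng.random(cs.shape) < p]
            bases[hit] = b"T"
        else:
            gs = bot_c[bot_c < span]
            hit = gs[rng.random(gs.shape) < config.breathing_rate]
            bases[hit] = b"A"

        query, cigar, _ = _apply_indels_and_cigar(rng, bases, config.indel_rate)
        reads.append(AlignedRead(mol_id, reference.name, 0, query, cigar))
    return reads, truth


def simulate_ssdna_control(
    config: SimulationConfig, sequence: str, n_reads: int
) -> list[AlignedRead]:
    """Reads from a fully single-stranded spike-in control.

    Every cytosine on every read converts independently with
    ``config.conversion_efficiency``; no duplex/breathing or strand logic
    and no indels — this is the conversion-efficiency yardstick.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(config.seed)
    arr = np.frombuffer(sequence.upper().encode(), dtype="S1")
    c_pos = np.flatnonzero(arr == b"C")
    reads = []
    for i in range(n_reads):
        bases = arr.copy()
        hit = c_pos[rng.random(c_pos.shape) < config.conversion_efficiency]
        bases[hit] = b"T"
        reads.append(
            AlignedRead(f"ctrl{i:04d}", "ssdna_control", 0, bases.tobytes().decode(), [(0, len(arr))])
        )
    return reads


# ---------------------------------------------------------------------------
# on-disk formats


def write_sam(reads: Iterable[AlignedRead], reference: DonorReference, path: str | Path) -> None:
    """Write reads as plain-text SAM against ``reference``."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference.name, "LN": len(reference)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.query_name
            a.reference_id = 0
            a.reference_start = r.reference_start
            a.mapping_quality = 60
            a.cigartuples = r.cigartuples
            a.query_sequence = r.query_sequence
            a.flag = 0
            out.write(a)


def read_sam(path: str | Path) -> list[pysam.AlignedSegment]:
    """Load alignments from SAM/BAM (header-complete; unmapped reads skipped)."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return [a for a in fh if not a.is_unmapped]


def write_truth_bed(
    truth: Sequence[GroundTruthRecord], path: str | Path, ref_name: str = "donor"
) -> None:
    """True D-loop intervals as BED (molecules without a D-loop are omitted)."""
    with open(path, "w") as fh:
        for t in truth:
            if t.has_dloop:
                fh.write(
                    f"{ref_name}\t{t.dloop_start}\t{t.dloop_end}\t{t.molecule_id}\t0\t+\n"
                )


def write_manifest(truth: Sequence[GroundTruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\thas_dloop\tdloop_start\tdloop_end\tsampled_strand\n")
        for t in truth:
            fh.write(
                f"{t.molecule_id}\t{int(t.has_dloop)}\t{t.dloop_start}\t{t.dloop_end}\t{t.sampled_strand}\n"
            )
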