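"""Donor reference model: sequences, cytosine indices, and DNA-topology limits.

The mapping assay reads out D-loops (displacement loops) as tracts of
C->T conversion on single reads.  Everything downstream is phrased in a
single reference coordinate system: the *top* strand is the donor strand
that is displaced on strand invasion (its cytosines are the reference C
positions), the *bottom* strand stays base-paired in the heteroduplex
(its cytosines appear as reference G positions, read out as G->A).

On a covalently closed, negatively supercoiled donor the heteroduplex
length is capped: every ~10.4 bp of heteroduplex absorbs one negative
supercoil, so a plasmid with supercoiling density sigma can accommodate
at most |sigma| * L nucleotides of heteroduplex.  ``supercoil_capacity``
implements that bound; linear donors are limited only by the homology.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "DonorReference",
    "TopologyMode",
    "TopologyModel",
    "count_cytosines",
    "load_reference",
    "supercoil_capacity",
]

_VALID = set("ACGTN")

BP_PER_SUPERCOIL = 10.4
"""Heteroduplex nucleotides absorbed per negative supercoil (B-DNA helical repeat)."""


def count_cytosines(seq: str) -> int:
    """Number of cytosines in ``seq`` (case-insensitive; empty string gives 0)."""
    return seq.upper().count("C")


@dataclass(frozen=True)
class DonorReference:
    """A donor sequence with an annotated homology window.

    Coordinates are 0-based, half-open.  ``top_cytosine_positions`` are the
    reference C positions (cytosines of the displaced/top strand);
    ``bottom_cytosine_positions`` are the reference G positions (cytosines
    of the template/bottom strand, reported in reference coordinates so
    both strands share one axis).
    """

    name: str
    sequence: str
    homology_start: int
    homology_end: int
    top_cytosine_positions: np.ndarray = field(repr=False, default=None)
    bottom_cytosine_positions: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        for i, b in enumerate(seq):
            if b not in _VALID:
                raise ValueError(
                    f"invalid base {self.sequence[i]!r} at position {i} in {self.name}"
                )
        if not (0 <= self.homology_start < self.homology_end <= len(seq)):
            raise ValueError(
                f"homology window [{self.homology_start}, {self.homology_end}) "
                f"out of bounds for sequence of length {len(seq)}"
            )
        arr = np.frombuffer(seq.encode(), dtype="S1")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(
            self, "top_cytosine_positions", np.flatnonzero(arr == b"C")
        )
        object.__setattr__(
            self, "bottom_cytosine_positions", np.flatnonzero(arr == b"G")
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def homology_length(self) -> int:
        return self.homology_end - self.homology_start

    @property
    def homology_sequence(self) -> str:
        return self.sequence[self.homology_start : self.homology_end]

    def cytosine_positions(self, strand: str) -> np.ndarray:
        """Reference positions of the cytosines of ``strand`` ('top' or 'bottom')."""
        if strand == "top":
            return self.top_cytosine_positions
        if strand == "bottom":
            return self.bottom_cytosine_positions
        raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")

    def homology_cytosine_count(self, strand: str = "top") -> int:
        pos = self.cytosine_positions(strand)
        return int(
            np.count_nonzero((pos >= self.homology_start) & (pos < self.homology_end))
        )


def load_reference(fasta_path: str | Path, homology_window: tuple[int, int]) -> DonorReference:
    """Load a single-record FASTA as a :class:`DonorReference`.

    ``homology_window`` is 0-based half-open.  Lower-case sequence is
    accepted (printed substrate sequences are lower-case).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    start, end = homology_window
    return DonorReference(
        name=rec.id,
        sequence=str(rec.seq),
        homology_start=int(start),
        homology_end=int(end),
    )


class TopologyMode(str, enum.Enum):
    SUPERCOILED = "supercoiled"
    LINEAR = "linear"


@dataclass(frozen=True)
class TopologyModel:
    """Topological state of the donor duplex.

    sigma: supercoiling density (supercoils per helical turn, signed;
        E. coli-purified plasmid is ~ -0.07).
    plasmid_length: donor length in nt.
    bp_per_supercoil: heteroduplex nt absorbed per supercoil (10.4).
    mode: supercoiled donors cap heteroduplex length at |sigma|*L;
        linear donors impose no topological cap.
    """

    sigma: float = -0.07
    plasmid_length: int = 3000
    bp_per_supercoil: float = BP_PER_SUPERCOIL
    mode: TopologyMode = TopologyMode.SUPERCOILED

    def __post_init__(self) -> None:
        if self.plasmid_length <= 0:
            raise ValueError("plasmid_length must be positive")
        if self.bp_per_supercoil <= 0:
            raise ValueError("bp_per_supercoil must be positive")
        object.__setattr__(self, "mode", TopologyMode(self.mode))

    @property
    def n_supercoils(self) -> float:
        """Number of (negative) supercoils, |sigma| * L / 10.4."""
        return abs(self.sigma) * self.plasmid_length / self.bp_per_supercoil

    @classmethod
    def from_dict(cls, d: dict) -> "TopologyModel":
        return cls(**{k: d[k] for k in ("sigma", "plasmid_length", "bp_per_supercoil", "mode") if k in d})


def supercoil_capacity(topology: TopologyModel, homology_length: int) -> int:
    """Maximum heteroduplex (footprint) length the donor can accommodate, in nt.

    Supercoiled mode: min(homology_length, |sigma| * plasmid_length), since
    each of the |sigma|*L/10.4 supercoils absorbs 10.4 nt of heteroduplex.
    Linear mode: the homology length itself.  The capacity is computed as a
    real number and rounded to the nearest nt.
    """
    if homology_length <= 0:
        raise ValueError("homology_length must be positive")
    if topology.mode is TopologyMode.LINEAR:
        return int(homology_length)
    if topology.sigma > 0:
        raise ValueError(
            "positively supercoiled donor: heteroduplex cap undefined for this assay"
        )
    cap = topology.n_supercoils * topology.bp_per_supercoil  # == |sigma| * L
    return int(round(min(float(homology_length), cap)))
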