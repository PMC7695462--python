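"""Packaged substrate homology sequences and synthetic donor construction.

Four invading-substrate homologies are shipped as FASTA fixtures, named
by their homology length: ds98-197 (43 cytosines), ds98-607, ds98-915
(192 cytosines) and ds98-931 (187 cytosines).  The real donor plasmid
sequence is not public, so donor references are synthetic: a packaged
homology embedded between two random non-homologous flanks of >= 1000 nt,
mirroring the amplicon design in which >1 kb of non-homologous duplex
flanks the homology window as an internal negative control.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .refmodel import DonorReference, load_reference

__all__ = ["SUBSTRATE_NAMES", "substrate_path", "load_substrate", "build_donor"]

SUBSTRATE_NAMES = ("ds98-197", "ds98-607", "ds98-915", "ds98-931")


def substrate_path(name: str) -> Path:
    """Filesystem path of a packaged substrate homology FASTA."""
    if name not in SUBSTRATE_NAMES:
        raise KeyError(f"unknown substrate {name!r}; choose from {SUBSTRATE_NAMES}")
    return Path(str(resources.files("dloopmap.data") / f"{name}.fasta"))


def load_substrate(name: str) -> DonorReference:
    """Load a packaged homology as a reference of its own (window = whole sequence)."""
    path = substrate_path(name)
    ref = load_reference(path, (0, _substrate_length(name)))
    return ref


def _substrate_length(name: str) -> int:
    return int(name.rsplit("-", 1)[1])


def build_donor(
    substrate: str = "ds98-931",
    flank: int = 1000,
    seed: int = 1715,
) -> DonorReference:
    """Build a synthetic donor embedding a packaged homology.

    The flanks are seeded uniform-random DNA (deterministic for a given
    seed), standing in for the donor's non-homologous duplex regions.
    Returns a :class:`DonorReference` whose homology window is exactly
    the embedded substrate sequence.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    homology = load_substrate(substrate).sequence
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, size=flank))
    right = "".join(rng.choice(bases, size=flank))
    return DonorReference(
        name=f"donor-{substrate}",
        sequence=left + homology + right,
        homology_start=flank,
        homology_end=flank + len(homology),
    )


def make_ssdna_control(n_cytosines: int = 420, spacing: int = 4, seed: int = 99) -> str:
    """Synthetic single-stranded control sequence with a fixed cytosine count.

    Emulates a spiked-in fully single-stranded circle used to measure
    bisulfite conversion efficiency: every cytosine is reactive.  The
    returned sequence has exactly ``n_cytosines`` C's placed every
    ``spacing`` nt among random A/G/T.
    """
    rng = np.random.default_rng(seed)
    length = n_cytosines * spacing
    seq = rng.choice(np.array(list("AGT")), size=length)
    seq[::spacing] = "C"
    return "".join(seq)
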