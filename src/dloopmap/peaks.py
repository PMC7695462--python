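"""Threshold-based sliding-window footprint (peak) calling.

A window of ``w`` consecutive *unmasked* cytosines slides along each
read one cytosine at a time; a window is positive when at least a
fraction ``t`` of its cytosines are converted.  Maximal runs of
consecutive positive windows form one peak each — a single negative
window terminates the peak — and peak boundaries are trimmed to the
outermost converted cytosines covered by the run.  The default
threshold is t40w50 (>= 40% conversion over 50 cytosines).

Because the window is defined in cytosines, not nucleotides, the
nucleotide span of a single window — hence the shortest detectable
footprint — depends on the local cytosine density of the reference;
``min_detectable_length`` reports that floor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .convert import CONVERTED, MASKED, ReadConversionTrack
from .refmodel import DonorReference

__all__ = [
    "PeakThreshold",
    "Footprint",
    "parse_threshold",
    "call_peaks",
    "call_peaks_all",
    "threshold_grid",
    "min_detectable_length",
    "write_footprints_bed",
    "write_footprints_tsv",
]

_EPS = 1e-9  # guards float comparison at exact-threshold windows (pass at equality)


@dataclass(frozen=True)
class PeakThreshold:
    """Peak threshold 'tXXwYY': fraction t over a window of w consecutive cytosines."""

    t: float = 0.40
    w: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.t <= 1.0:
            raise ValueError(f"t must be in (0, 1], got {self.t}")
        if self.w < 2:
            raise ValueError(f"w must be >= 2, got {self.w}")

    def __str__(self) -> str:
        return f"t{round(self.t * 100):g}w{self.w}"


def parse_threshold(text: str) -> PeakThreshold:
    """Parse 'tXXwYY' (e.g. 't40w50' -> t=0.40, w=50)."""
    m = re.fullmatch(r"t(\d+(?:\.\d+)?)w(\d+)", text.strip())
    if not m:
        raise ValueError(
            f"malformed threshold {text!r}: expected 'tXXwYY' with XX a percent "
            "and YY a window size in cytosines, e.g. 't40w50'"
        )
    return PeakThreshold(t=float(m.group(1)) / 100.0, w=int(m.group(2)))


@dataclass(frozen=True)
class Footprint:
    """One called peak on one read; start/end are converted boundary cytosines.

    ``length = end - start`` (the 3' boundary minus the 5' boundary, in nt).
    """

    read_id: str
    strand: str
    start: int
    end: int
    length: int
    n_cytosines_in_peak: int
    n_converted_in_peak: int

    @property
    def conversion_fraction(self) -> float:
        return self.n_converted_in_peak / self.n_cytosines_in_peak


def call_peaks(
    track: ReadConversionTrack,
    threshold: PeakThreshold = PeakThreshold(),
    strand: str | None = None,
) -> list[Footprint]:
    """Call footprints on one read's conversion track.

    Masked cytosines are removed from the consecutive-cytosine sequence
    before windowing (they count neither for nor against).  Windowing
    runs over the whole read, not only the homology window, so breathing
    artefacts outside homology remain visible.  Reads with fewer than
    ``w`` unmasked cytosines yield no peaks.
    """
    strand = strand or track.active_strand
    positions, status = track.as_strand(strand)
    unmasked = status != MASKED
    pos = positions[unmasked]
    conv = status[unmasked] == CONVERTED
    n, w = len(pos), threshold.w
    if n < w:
        return []
    counts = np.convolve(conv.astype(np.int32), np.ones(w, dtype=np.int32), "valid")
    positive = counts >= threshold.t * w - _EPS
    out: list[Footprint] = []
    i = 0
    n_win = len(positive)
    while i < n_win:
        if not positive[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_win and positive[j + 1]:
            j += 1
        lo, hi = i, j + w - 1  # cytosine indices covered by the run of windows
        conv_idx = np.flatnonzero(conv[lo : hi + 1])
        if len(conv_idx):  # always true for t > 0, kept for safety
            a, b = lo + conv_idx[0], lo + conv_idx[-1]
            out.append(
                Footprint(
                    read_id=track.read_id,
                    strand=strand,
                    start=int(pos[a]),
                    end=int(pos[b]),
                    length=int(pos[b] - pos[a]),
                    n_cytosines_in_peak=int(b - a + 1),
                    n_converted_in_peak=int(conv[a : b + 1].sum()),
                )
            )
        i = j + 1
    return out


def call_peaks_all(
    tracks: Iterable[ReadConversionTrack],
    threshold: PeakThreshold = PeakThreshold(),
) -> dict[str, list[Footprint]]:
    """Footprints per read id, on each read's assigned strand."""
    return {t.read_id: call_peaks(t, threshold) for t in tracks}


def threshold_grid(
    tracks: Sequence[ReadConversionTrack],
    thresholds: Sequence[PeakThreshold],
) -> pd.DataFrame:
    """Per-threshold, per-strand peak summary over a track set.

    Columns: threshold, t, w, strand, n_reads, n_peak_reads, percent_peak,
    n_footprints, length_mean, length_sd.
    """
    if not thresholds:
        raise ValueError("at least one threshold required")
    rows = []
    for th in thresholds:
        per_strand: dict[str, dict] = {
            s: {"n_reads": 0, "n_peak_reads": 0, "lengths": []} for s in ("top", "bottom")
        }
        for track in tracks:
            s = track.active_strand
            d = per_strand[s]
            d["n_reads"] += 1
            fps = call_peaks(track, th)
            if fps:
                d["n_peak_reads"] += 1
                d["lengths"].extend(fp.length for fp in fps)
        for s, d in per_strand.items():
            lengths = np.asarray(d["lengths"], dtype=float)
            rows.append(
                {
                    "threshold": str(th),
                    "t": th.t,
                    "w": th.w,
                    "strand": s,
                    "n_reads": d["n_reads"],
                    "n_peak_reads": d["n_peak_reads"],
                    "percent_peak": (
                        100.0 * d["n_peak_reads"] / d["n_reads"] if d["n_reads"] else np.nan
                    ),
                    "n_footprints": len(lengths),
                    "length_mean": lengths.mean() if len(lengths) else np.nan,
                    "length_sd": lengths.std(ddof=1) if len(lengths) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def min_detectable_length(
    reference: DonorReference, threshold: PeakThreshold = PeakThreshold()
) -> tuple[int, int]:
    """(min, max) nucleotide span of one w-cytosine window in the homology.

    This is the effective detection floor: no footprint shorter than the
    local window span can be called.  Computed over top-strand cytosines
    inside the homology window.
    """
    pos = reference.top_cytosine_positions
    pos = pos[(pos >= reference.homology_start) & (pos < reference.homology_end)]
    w = threshold.w
    if len(pos) < w:
        raise ValueError(
            f"homology window has {len(pos)} cytosines, fewer than the "
            f"window size {w}: no window fits"
        )
    spans = pos[w - 1 :] - pos[: len(pos) - w + 1]
    return int(spans.min()), int(spans.max())


# ---------------------------------------------------------------------------
# output formats


def write_footprints_bed(
    footprints: Iterable[Footprint], reference: DonorReference, path: str | Path
) -> None:
    """BED6: 0-based half-open [start, end+1), score = 1000 x conversion fraction."""
    with open(path, "w") as fh:
        for fp in footprints:
            score = round(1000 * fp.conversion_fraction)
            strand = "+" if fp.strand == "top" else "-"
            fh.write(
                f"{reference.name}\t{fp.start}\t{fp.end + 1}\t{fp.read_id}\t{score}\t{strand}\n"
            )


def write_footprints_tsv(footprints: Iterable[Footprint], path: str | Path) -> None:
    """TSV with both 0-based half-open and 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tstrand\tstart0\tend0\tstart1\tend1\tlength\t"
            "n_cytosines_in_peak\tn_converted_in_peak\n"
        )
        for fp in footprints:
            fh.write(
                f"{fp.read_id}\t{fp.strand}\t{fp.start}\t{fp.end + 1}\t"
                f"{fp.start + 1}\t{fp.end + 1}\t{fp.length}\t"
                f"{fp.n_cytosines_in_peak}\t{fp.n_converted_in_peak}\n"
            )
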