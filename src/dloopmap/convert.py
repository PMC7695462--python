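"""Per-read cytosine conversion tracks: calling, masking, filtering, strand assignment.

Each aligned read is reduced to two candidate tracks over reference
coordinates: the reference C positions scored as C->T conversion (top
strand candidate) and the reference G positions scored as G->A (bottom
strand candidate).  Regions around indels are masked with a 5 nt buffer
on both sides so sequencing artefacts do not distort conversion
frequencies; masked positions are excluded from all tallies and window
denominators.  Strand is then assigned from the asymmetry of the two
tallies, and reads shorter than half their expected amplicon length are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .refmodel import DonorReference

__all__ = [
    "UNCONVERTED",
    "CONVERTED",
    "MASKED",
    "INDEL_MASK_BUFFER",
    "ReadConversionTrack",
    "call_conversions",
    "assign_strand",
    "filter_read_length",
    "process_reads",
    "FilterCounts",
    "write_tracks_tsv",
    "read_tracks_tsv",
]

UNCONVERTED, CONVERTED, MASKED = 0, 1, 2
_STATUS_CHAR = {UNCONVERTED: "u", CONVERTED: "c", MASKED: "m"}
_CHAR_STATUS = {v: k for k, v in _STATUS_CHAR.items()}

INDEL_MASK_BUFFER = 5  # nt masked on each side of an indel's reference footprint

MIN_CONVERSIONS_FOR_CALL = 6  # below this on both tallies a read is unassignable
STRAND_AMBIGUITY_FRACTION = 0.10  # |n_CT - n_GA| within 10% of the max -> unknown


@dataclass
class ReadConversionTrack:
    """One read's cytosine statuses on both candidate strands.

    ``positions``/``status`` expose the assigned strand's track (top when
    the call is 'unknown').  Status codes: 0 unconverted, 1 converted,
    2 masked.  ``n_CT``/``n_GA`` count conversions at unmasked positions
    only, and are computed after indel masking.
    """

    read_id: str
    strand_call: str
    top_positions: np.ndarray = field(repr=False)
    top_status: np.ndarray = field(repr=False)
    bottom_positions: np.ndarray = field(repr=False)
    bottom_status: np.ndarray = field(repr=False)
    n_CT: int
    n_GA: int
    expected_length: int
    observed_length: int
    reference_name: str = ""
    aln_start: int = 0
    aln_end: int = 0

    def as_strand(self, strand: str) -> tuple[np.ndarray, np.ndarray]:
        if strand == "top":
            return self.top_positions, self.top_status
        if strand == "bottom":
            return self.bottom_positions, self.bottom_status
        raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")

    @property
    def active_strand(self) -> str:
        return "bottom" if self.strand_call == "bottom" else "top"

    @property
    def positions(self) -> np.ndarray:
        return self.as_strand(self.active_strand)[0]

    @property
    def status(self) -> np.ndarray:
        return self.as_strand(self.active_strand)[1]

    @property
    def masked_count(self) -> int:
        return int(np.count_nonzero(self.top_status == MASKED)) + int(
            np.count_nonzero(self.bottom_status == MASKED)
        )


def assign_strand(n_CT: int, n_GA: int) -> str:
    """Assign read strand from conversion asymmetry.

    'unknown' when both tallies are below 6 (too little signal), or when
    they differ by no more than 10% of the larger tally (ambiguous);
    otherwise 'top' if C->T predominates, 'bottom' if G->A does.
    """
    if n_CT < MIN_CONVERSIONS_FOR_CALL and n_GA < MIN_CONVERSIONS_FOR_CALL:
        return "unknown"
    if abs(n_CT - n_GA) <= STRAND_AMBIGUITY_FRACTION * max(n_CT, n_GA):
        return "unknown"
    return "top" if n_CT > n_GA else "bottom"


def _indel_mask(read, span_start: int, span_end: int) -> np.ndarray:
    """Boolean mask (over [span_start, span_end)) of positions near indels."""
    mask = np.zeros(span_end - span_start, dtype=bool)
    rpos = read.reference_start
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):
            rpos += ln
        elif op == 1:  # insertion anchored before reference position rpos
            lo = max(span_start, rpos - INDEL_MASK_BUFFER)
            hi = min(span_end, rpos + INDEL_MASK_BUFFER + 1)
            mask[lo - span_start : hi - span_start] = True
        elif op == 2:  # deletion of reference bases [rpos, rpos+ln)
            lo = max(span_start, rpos - INDEL_MASK_BUFFER)
            hi = min(span_end, rpos + ln + INDEL_MASK_BUFFER)
            mask[lo - span_start : hi - span_start] = True
            rpos += ln
        # soft clips / others consume no reference
    return mask


def _read_bases_on_reference(read, span_start: int, span_end: int) -> np.ndarray:
    """Read base at each covered reference position ('-' where deleted)."""
    out = np.full(span_end - span_start, b"-", dtype="S1")
    query = np.frombuffer(read.query_sequence.encode(), dtype="S1")
    qpos = 0
    rpos = read.reference_start
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):
            out[rpos - span_start : rpos + ln - span_start] = query[qpos : qpos + ln]
            qpos += ln
            rpos += ln
        elif op in (1, 4):  # insertion / soft clip consume query only
            qpos += ln
        elif op == 2:
            rpos += ln
    return out


def _score_strand(
    positions: np.ndarray,
    bases: np.ndarray,
    mask: np.ndarray,
    span_start: int,
    unconverted_base: bytes,
    converted_base: bytes,
) -> tuple[np.ndarray, int]:
    rel = positions - span_start
    b = bases[rel]
    status = np.full(positions.shape, MASKED, dtype=np.int8)
    status[b == unconverted_base] = UNCONVERTED
    status[b == converted_base] = CONVERTED
    status[mask[rel]] = MASKED
    return status, int(np.count_nonzero(status == CONVERTED))


def call_conversions(
    read,
    reference: DonorReference,
    expected_length: int | None = None,
) -> ReadConversionTrack:
    """Score one aligned read against the donor reference.

    ``read`` needs pysam ``AlignedSegment``-style attributes (query_name,
    reference_start, cigartuples, query_sequence, and reference_name if
    set).  For every covered reference C: status is converted if the read
    shows T, unconverted if C, masked otherwise (non-T mismatches are
    treated as sequencing noise); symmetrically G->A for the bottom-strand
    candidate.  Both tallies are computed after indel masking, then the
    strand is assigned.
    """
    if read.cigartuples is None or read.query_sequence is None:
        raise ValueError(f"read {read.query_name!r} is unaligned or sequence-less")
    ref_name = getattr(read, "reference_name", None)
    if ref_name not in (None, "", reference.name):
        raise ValueError(
            f"read {read.query_name!r} is aligned to {ref_name!r}, not {reference.name!r}"
        )
    span_start = read.reference_start
    span_end = read.reference_end
    if span_end > len(reference):
        raise ValueError(f"read {read.query_name!r} extends past the reference end")

    bases = _read_bases_on_reference(read, span_start, span_end)
    mask = _indel_mask(read, span_start, span_end)

    tp = reference.top_cytosine_positions
    tp = tp[(tp >= span_start) & (tp < span_end)]
    bp = reference.bottom_cytosine_positions
    bp = bp[(bp >= span_start) & (bp < span_end)]

    top_status, n_ct = _score_strand(tp, bases, mask, span_start, b"C", b"T")
    bottom_status, n_ga = _score_strand(bp, bases, mask, span_start, b"G", b"A")

    return ReadConversionTrack(
        read_id=read.query_name,
        strand_call=assign_strand(n_ct, n_ga),
        top_positions=tp,
        top_status=top_status,
        bottom_positions=bp,
        bottom_status=bottom_status,
        n_CT=n_ct,
        n_GA=n_ga,
        expected_length=int(expected_length or len(reference)),
        observed_length=span_end - span_start,
        reference_name=reference.name,
        aln_start=span_start,
        aln_end=span_end,
    )


def filter_read_length(track: ReadConversionTrack) -> bool:
    """Keep a read iff it covers at least half its expected amplicon length."""
    if track.expected_length <= 0:
        raise ValueError("expected_length must be positive")
    return track.observed_length >= 0.5 * track.expected_length


@dataclass
class FilterCounts:
    """Per-stage read accounting; n_input == length_filtered + unknown + kept."""

    n_input: int = 0
    n_length_filtered: int = 0
    n_unknown_strand: int = 0
    n_kept_top: int = 0
    n_kept_bottom: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_kept_top + self.n_kept_bottom


def process_reads(
    reads: Iterable,
    reference: DonorReference,
    expected_length: int | None = None,
    keep_unknown: bool = False,
) -> tuple[list[ReadConversionTrack], FilterCounts]:
    """Convert, length-filter and strand-assign a read set.

    Unknown-strand reads are excluded from the returned tracks unless
    ``keep_unknown``; they are always counted.
    """
    counts = FilterCounts()
    kept: list[ReadConversionTrack] = []
    for read in reads:
        counts.n_input += 1
        track = call_conversions(read, reference, expected_length)
        if not filter_read_length(track):
            counts.n_length_filtered += 1
            continue
        if track.strand_call == "unknown":
            counts.n_unknown_strand += 1
            if keep_unknown:
                kept.append(track)
            continue
        if track.strand_call == "top":
            counts.n_kept_top += 1
        else:
            counts.n_kept_bottom += 1
        kept.append(track)
    return kept, counts


# ---------------------------------------------------------------------------
# TSV round trip


def _rle(status: np.ndarray) -> str:
    if len(status) == 0:
        return "."
    out = []
    prev, run = int(status[0]), 0
    for s in status:
        if int(s) == prev:
            run += 1
        else:
            out.append(f"{run}{_STATUS_CHAR[prev]}")
            prev, run = int(s), 1
    out.append(f"{run}{_STATUS_CHAR[prev]}")
    return "".join(out)


def _unrle(text: str) -> np.ndarray:
    if text == ".":
        return np.zeros(0, dtype=np.int8)
    vals: list[int] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            vals.extend([_CHAR_STATUS[ch]] * int(num))
            num = ""
    return np.asarray(vals, dtype=np.int8)


_TSV_COLUMNS = (
    "read_id\tstrand_call\tn_CT\tn_GA\tmasked_count\taln_start\taln_end\t"
    "expected_length\tobserved_length\tstatus_rle\n"
)


def write_tracks_tsv(tracks: Sequence[ReadConversionTrack], path: str | Path) -> None:
    """Per-read track table; status_rle encodes the assigned strand's track."""
    with open(path, "w") as fh:
        fh.write(_TSV_COLUMNS)
        for t in tracks:
            fh.write(
                f"{t.read_id}\t{t.strand_call}\t{t.n_CT}\t{t.n_GA}\t{t.masked_count}\t"
                f"{t.aln_start}\t{t.aln_end}\t{t.expected_length}\t{t.observed_length}\t"
                f"{_rle(t.status)}\n"
            )


def read_tracks_tsv(path: str | Path, reference: DonorReference) -> list[ReadConversionTrack]:
    """Rebuild tracks from a TSV; only the assigned strand's track is populated."""
    tracks = []
    with open(path) as fh:
        header = fh.readline()
        if header != _TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected track TSV header")
        empty_pos = np.zeros(0, dtype=np.int64)
        empty_status = np.zeros(0, dtype=np.int8)
        for line in fh:
            (rid, strand, n_ct, n_ga, _masked, a0, a1, exp, obs, rle) = line.rstrip("\n").split("\t")
            a0, a1 = int(a0), int(a1)
            active = "bottom" if strand == "bottom" else "top"
            pos = reference.cytosine_positions(active)
            pos = pos[(pos >= a0) & (pos < a1)]
            status = _unrle(rle)
            if len(status) != len(pos):
                raise ValueError(f"{path}: status length mismatch for read {rid}")
            kw = dict(
                top_positions=empty_pos, top_status=empty_status,
                bottom_positions=empty_pos, bottom_status=empty_status,
            )
            kw[f"{active}_positions"] = pos
            kw[f"{active}_status"] = status
            tracks.append(
                ReadConversionTrack(
                    read_id=rid, strand_call=strand, n_CT=int(n_ct), n_GA=int(n_ga),
                    expected_length=int(exp), observed_length=int(obs),
                    reference_name=reference.name, aln_start=a0, aln_end=a1, **kw,
                )
            )
    return tracks
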