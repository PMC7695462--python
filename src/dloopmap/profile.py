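"""Sample-level footprint summaries, positional binning, clustering and maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .convert import CONVERTED, MASKED, UNCONVERTED, ReadConversionTrack
from .peaks import Footprint
from .refmodel import DonorReference

__all__ = [
    "percent_peak",
    "LengthStats",
    "length_stats",
    "BinnedDistribution",
    "bin_distribution",
    "cluster_footprints",
    "SampleSummary",
    "summarize_sample",
    "export_footprint_map",
    "parse_footprint_map",
]


def percent_peak(n_peak_reads: int, n_total_reads: int) -> float:
    """Percentage of reads on one strand that contain at least one footprint."""
    if not 0 <= n_peak_reads <= n_total_reads:
        raise ValueError("need 0 <= n_peak_reads <= n_total_reads")
    if n_total_reads == 0:
        raise ValueError("percent_peak is undefined for zero total reads")
    return 100.0 * n_peak_reads / n_total_reads


@dataclass(frozen=True)
class LengthStats:
    """Footprint length summary: arithmetic mean, sample SD, cutoff exceedance."""

    n: int
    mean: float | None
    sd: float | None  # None when fewer than two footprints
    cutoff: int
    fraction_over_cutoff: float | None
    lengths: np.ndarray = field(repr=False, default=None)


def length_stats(footprints: Sequence[Footprint], cutoff: int = 400) -> LengthStats:
    lengths = np.asarray([fp.length for fp in footprints], dtype=float)
    if len(lengths) == 0:
        return LengthStats(0, None, None, cutoff, None, lengths)
    return LengthStats(
        n=len(lengths),
        mean=float(lengths.mean()),
        sd=float(lengths.std(ddof=1)) if len(lengths) > 1 else None,
        cutoff=cutoff,
        fraction_over_cutoff=float(np.mean(lengths > cutoff)),
        lengths=lengths,
    )


@dataclass(frozen=True)
class BinnedDistribution:
    """Non-exclusive positional binning across the homology window.

    Each footprint contributes 1 to every bin its closed interval
    [start, end] overlaps by at least 1 nt; values are divided by the
    total footprint count, so they need not sum to 1.
    """

    bin_size: int
    bins: tuple[tuple[int, int], ...]  # 0-based half-open, tiling the homology
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": [b[0] for b in self.bins],
                "bin_end": [b[1] for b in self.bins],
                "fraction": self.values,
            }
        )


def bin_distribution(
    footprints: Sequence[Footprint],
    reference: DonorReference,
    bin_size: int = 100,
) -> BinnedDistribution:
    """Bin footprints into ``bin_size``-nt bins across the homology window.

    Bins are anchored at homology_start; the final partial bin is kept.
    Zero footprints gives an all-zero distribution (with a warning).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    h0, h1 = reference.homology_start, reference.homology_end
    edges = list(range(h0, h1, bin_size)) + [h1]
    bins = tuple((edges[i], edges[i + 1]) for i in range(len(edges) - 1))
    values = np.zeros(len(bins), dtype=float)
    if not footprints:
        warnings.warn("bin_distribution called with zero footprints", stacklevel=2)
        return BinnedDistribution(bin_size, bins, values)
    for fp in footprints:
        for i, (b0, b1) in enumerate(bins):
            if fp.start <= b1 - 1 and fp.end >= b0:  # closed interval, >=1 nt overlap
                values[i] += 1.0
    return BinnedDistribution(bin_size, bins, values / len(footprints))


def cluster_footprints(
    footprints_by_read: Mapping[str, Sequence[Footprint]],
) -> list[str]:
    """Order footprint-containing reads 5'->3' by their first footprint.

    Sort key: (first footprint start, first footprint end, read_id);
    reads without footprints are excluded.  Deterministic and idempotent.
    """
    keyed = []
    for read_id, fps in footprints_by_read.items():
        if fps:
            first = min(fps, key=lambda fp: (fp.start, fp.end))
            keyed.append((first.start, first.end, read_id))
    return [rid for _, _, rid in sorted(keyed)]


@dataclass(frozen=True)
class SampleSummary:
    """Per-strand footprint summary for one sample."""

    strand: str
    n_total_reads: int
    n_peak_reads: int
    percent_peak: float | None
    n_footprints: int
    n_multi_footprint_reads: int
    lengths: LengthStats

    def to_row(self) -> dict:
        return {
            "strand": self.strand,
            "n_total_reads": self.n_total_reads,
            "n_peak_reads": self.n_peak_reads,
            "percent_peak": (
                round(self.percent_peak, 2) if self.percent_peak is not None else np.nan
            ),
            "n_footprints": self.n_footprints,
            "n_multi_footprint_reads": self.n_multi_footprint_reads,
            "length_mean": self.lengths.mean if self.lengths.mean is not None else np.nan,
            "length_sd": self.lengths.sd if self.lengths.sd is not None else np.nan,
            "fraction_over_cutoff": (
                self.lengths.fraction_over_cutoff
                if self.lengths.fraction_over_cutoff is not None
                else np.nan
            ),
        }


def summarize_sample(
    tracks: Sequence[ReadConversionTrack],
    footprints_by_read: Mapping[str, Sequence[Footprint]],
    length_cutoff: int = 400,
) -> dict[str, SampleSummary]:
    """Summaries keyed by strand.

    A multi-footprint read counts once toward n_peak_reads but every
    footprint enters the length statistics.
    """
    out = {}
    for strand in ("top", "bottom"):
        strand_tracks = [t for t in tracks if t.active_strand == strand]
        fps: list[Footprint] = []
        n_peak = n_multi = 0
        for t in strand_tracks:
            read_fps = list(footprints_by_read.get(t.read_id, ()))
            if read_fps:
                n_peak += 1
                n_multi += len(read_fps) > 1
                fps.extend(read_fps)
        n_total = len(strand_tracks)
        out[strand] = SampleSummary(
            strand=strand,
            n_total_reads=n_total,
            n_peak_reads=n_peak,
            percent_peak=percent_peak(n_peak, n_total) if n_total else None,
            n_footprints=len(fps),
            n_multi_footprint_reads=n_multi,
            lengths=length_stats(fps, cutoff=length_cutoff),
        )
    return out


# ---------------------------------------------------------------------------
# footprint maps

_GLYPHS = {"outside": ".", UNCONVERTED: "u", CONVERTED: "c", MASKED: "m", "footprint": "F"}


def export_footprint_map(
    tracks: Sequence[ReadConversionTrack],
    footprints_by_read: Mapping[str, Sequence[Footprint]],
    reference: DonorReference,
    out_prefix: str | Path,
    png: bool = True,
) -> Path:
    """Write a footprint map (text matrix, optionally PNG) for one strand.

    One row per read, one column per strand cytosine on the reference.
    Glyphs: '.' not covered, 'u' unconverted, 'c' converted, 'm' masked,
    'F' cytosine inside a called footprint.  Reads are clustered 5'->3'.
    Raises if tracks mix strands.
    """
    strands = {t.active_strand for t in tracks}
    if len(strands) > 1:
        raise ValueError(f"mixed strands in one map: {sorted(strands)}")
    strand = strands.pop() if strands else "top"
    columns = reference.cytosine_positions(strand)
    col_index = {int(p): i for i, p in enumerate(columns)}

    order = cluster_footprints(
        {t.read_id: footprints_by_read.get(t.read_id, ()) for t in tracks}
    )
    rank = {rid: i for i, rid in enumerate(order)}
    tracks = sorted(tracks, key=lambda t: (rank.get(t.read_id, len(rank)), t.read_id))

    matrix = np.full((len(tracks), len(columns)), _GLYPHS["outside"], dtype="U1")
    for r, t in enumerate(tracks):
        pos, status = t.as_strand(strand)
        for p, s in zip(pos.tolist(), status.tolist()):
            matrix[r, col_index[p]] = _GLYPHS[s]
        for fp in footprints_by_read.get(t.read_id, ()):
            for p in pos[(pos >= fp.start) & (pos <= fp.end)].tolist():
                if matrix[r, col_index[p]] != _GLYPHS[MASKED]:
                    matrix[r, col_index[p]] = _GLYPHS["footprint"]

    out_prefix = Path(out_prefix)
    text_path = out_prefix.with_suffix(".txt")
    with open(text_path, "w") as fh:
        fh.write(f"#reference\t{reference.name}\tstrand\t{strand}\n")
        fh.write("#positions\t" + "\t".join(map(str, columns.tolist())) + "\n")
        fh.write(f"#homology\t{reference.homology_start}\t{reference.homology_end}\n")
        for t, row in zip(tracks, matrix):
            fh.write(f"{t.read_id}\t{''.join(row)}\n")
    if png:
        _render_png(matrix, columns, reference, out_prefix.with_suffix(".png"))
    return text_path


def _render_png(matrix, columns, reference, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    # white: not covered; yellow: unconverted cytosine; green: converted;
    # grey: masked; red: in-footprint — the field's map colour convention
    lut = {".": 0, "u": 1, "c": 2, "m": 3, "F": 4}
    img = np.vectorize(lut.get)(matrix) if matrix.size else np.zeros((1, 1), dtype=int)
    cmap = ListedColormap(["white", "gold", "forestgreen", "lightgrey", "red"])
    fig, ax = plt.subplots(figsize=(10, max(2, 0.02 * matrix.shape[0] + 1)))
    ax.imshow(img, aspect="auto", cmap=cmap, vmin=0, vmax=4, interpolation="nearest")
    in_hom = (columns >= reference.homology_start) & (columns < reference.homology_end)
    idx = np.flatnonzero(in_hom)
    if len(idx):
        ax.axvline(idx[0] - 0.5, color="blue", ls=":", lw=1)
        ax.axvline(idx[-1] + 0.5, color="blue", ls=":", lw=1)
    ax.set_xlabel("cytosine index along reference (homology dotted blue)")
    ax.set_ylabel("reads (clustered 5'→3')")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def parse_footprint_map(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Recover per-read footprint intervals from a text footprint map.

    Returns read_id -> list of (start, end) where start/end are the
    reference positions of the first/last in-footprint cytosine — the
    same convention as :class:`~dloopmap.peaks.Footprint` boundaries.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    positions: np.ndarray | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#positions"):
                positions = np.asarray(line.split("\t")[1:], dtype=int)
                continue
            if line.startswith("#") or not line:
                continue
            rid, glyphs = line.split("\t")
            assert positions is not None, "map file lacks a #positions header"
            fps = []
            i = 0
            while i < len(glyphs):
                if glyphs[i] == "F":
                    j = i
                    while j + 1 < len(glyphs) and glyphs[j + 1] in "Fm":
                        j += 1
                    while glyphs[j] != "F":
                        j -= 1
                    fps.append((int(positions[i]), int(positions[j])))
                    i = j + 1
                else:
                    i += 1
            intervals[rid] = fps
    return intervals
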