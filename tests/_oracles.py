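"""Independent brute-force oracles used to check the fast implementations.

These deliberately avoid the vectorised code paths of the package: every
window is enumerated and scored by direct counting.
"""

from __future__ import annotations

import numpy as np

from dloopmap.convert import CONVERTED, MASKED, ReadConversionTrack


def brute_force_peaks(positions, status, t: float, w: int) -> list[tuple[int, int]]:
    """All-windows enumeration peak caller.

    Scores every window of w consecutive unmasked cytosines by direct
    counting, groups maximal runs of consecutive positive windows (one
    negative window terminates a peak), unions each run's coverage, and
    trims to the outermost converted cytosines.  Returns (start, end)
    pairs in reference coordinates.
    """
    pts = [(int(p), int(s)) for p, s in zip(positions, status) if s != MASKED]
    pos = [p for p, _ in pts]
    conv = [s == CONVERTED for _, s in pts]
    n = len(pos)
    if n < w:
        return []
    flags = [sum(conv[i : i + w]) / w >= t - 1e-9 for i in range(n - w + 1)]
    out = []
    i = 0
    while i < len(flags):
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(flags) and flags[j + 1]:
            j += 1
        covered = range(i, j + w)  # cytosine indices in the union of the run's windows
        conv_idx = [k for k in covered if conv[k]]
        if conv_idx:
            out.append((pos[conv_idx[0]], pos[conv_idx[-1]]))
        i = j + 1
    return out


def brute_force_window_spans(positions, w: int) -> tuple[int, int]:
    """Min/max nt span over every window of w consecutive cytosines."""
    spans = [positions[i + w - 1] - positions[i] for i in range(len(positions) - w + 1)]
    return int(min(spans)), int(max(spans))


def make_track(
    positions,
    status,
    read_id: str = "r0",
    strand: str = "top",
    expected_length: int = 1,
    observed_length: int = 1,
) -> ReadConversionTrack:
    """Build a single-strand track directly (test scaffolding)."""
    positions = np.asarray(positions, dtype=np.int64)
    status = np.asarray(status, dtype=np.int8)
    empty_p = np.zeros(0, dtype=np.int64)
    empty_s = np.zeros(0, dtype=np.int8)
    top = strand == "top"
    return ReadConversionTrack(
        read_id=read_id,
        strand_call=strand,
        top_positions=positions if top else empty_p,
        top_status=status if top else empty_s,
        bottom_positions=empty_p if top else positions,
        bottom_status=empty_s if top else status,
        n_CT=int((status == CONVERTED).sum()) if top else 0,
        n_GA=0 if top else int((status == CONVERTED).sum()),
        expected_length=expected_length,
        observed_length=observed_length,
    )


def random_track(rng: np.random.Generator, max_cytosines: int = 200) -> ReadConversionTrack:
    """A random conversion track with clustered and isolated conversions."""
    n = int(rng.integers(0, max_cytosines + 1))
    gaps = rng.integers(1, 12, size=n)
    positions = np.cumsum(gaps)
    status = np.zeros(n, dtype=np.int8)
    # background conversions
    status[rng.random(n) < rng.uniform(0.0, 0.3)] = CONVERTED
    # a few dense converted patches so peaks actually occur
    for _ in range(int(rng.integers(0, 4))):
        if n == 0:
            break
        a = int(rng.integers(0, n))
        b = min(n, a + int(rng.integers(5, 80)))
        patch = status[a:b]
        patch[rng.random(b - a) < rng.uniform(0.5, 1.0)] = CONVERTED
    # masked sprinkles
    status[rng.random(n) < rng.uniform(0.0, 0.15)] = MASKED
    return make_track(positions, status)
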