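"""Dyad calling and nucleosome-free-region (NFR) delineation.

The dyad axis of a positioned nucleosome is operationalised as a local
maximum of the smoothed occupancy profile. An NFR is the interval between
a fixed offset (default 75 bp) from each of two adjacent dyad axes: with
dyads d1 < d2 the NFR is the half-open interval [d1 + offset, d2 - offset),
emitted when its width reaches `min_width`. Both interval boundaries are
therefore exactly `offset` bp from their flanking dyads.

Maps recorded under different physiological conditions (e.g. active
growth vs stationary phase) can be compared by reciprocal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mnase_profile import OccupancyProfile

DEFAULT_OFFSET = 75  # bp from dyad axis to NFR border


class NfrConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DyadCall:
    chrom: str
    position: int
    height: float
    prominence: float

    def __post_init__(self) -> None:
        if not (self.height >= self.prominence >= 0):
            raise ValueError("require height >= prominence >= 0")


@dataclass(frozen=True)
class NucleosomeFreeRegion:
    chrom: str
    start: int
    end: int
    left_dyad: DyadCall
    right_dyad: DyadCall
    condition: str = ""

    @property
    def width(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        offset_l = self.start - self.left_dyad.position
        offset_r = self.right_dyad.position - self.end
        if offset_l != offset_r or offset_l < 0:
            raise ValueError("NFR borders must sit at equal offsets from both dyads")


def _plateau_maxima(values: np.ndarray) -> list[int]:
    """Leftmost indices of interior maximal plateaus (boundaries excluded)."""
    n = len(values)
    peaks = []
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j < n - 1 and values[j + 1] < values[i]:
                peaks.append(i)  # leftmost sample of the plateau
            i = j + 1
        else:
            i += 1
    return peaks


def _prominence(values: np.ndarray, peak: int) -> float:
    """Peak height minus the higher of the two bounding minima.

    Each bounding minimum is the lowest value between the peak and the
    nearest strictly higher sample on that side (or the profile edge).
    """
    h = values[peak]
    left_min = h
    for v in values[peak - 1 :: -1]:
        if v > h:
            break
        left_min = min(left_min, v)
    right_min = h
    for v in values[peak + 1 :]:
        if v > h:
            break
        right_min = min(right_min, v)
    return float(h - max(left_min, right_min))


def call_dyads(profile: OccupancyProfile, min_separation: int = 120,
               min_prominence_fraction: float = 0.05) -> list[DyadCall]:
    """Local profile maxima retained greedily in descending height order.

    Plateau peaks are represented by their leftmost sample. Candidates
    with prominence below `min_prominence_fraction` x max(profile) are
    suppressed; retained peaks are pairwise at least `min_separation` bp
    apart (the default 120 bp sits below the nucleosome repeat length but
    above the smoothing scale). Ties in height break to the leftmost
    position. An all-zero profile yields an empty list.
    """
    if min_separation < 1:
        raise NfrConfigError("min_separation must be >= 1")
    values = np.asarray(profile.values, dtype=float)
    vmax = values.max(initial=0.0)
    if vmax == 0:
        return []
    threshold = min_prominence_fraction * vmax
    candidates = []
    for pos in _plateau_maxima(values):
        prom = _prominence(values, pos)
        if prom >= threshold:
            candidates.append((pos, float(values[pos]), prom))
    retained: list[tuple[int, float, float]] = []
    for pos, height, prom in sorted(candidates, key=lambda c: (-c[1], c[0])):
        if all(abs(pos - r[0]) >= min_separation for r in retained):
            retained.append((pos, height, prom))
    retained.sort()
    return [DyadCall(profile.chrom, pos, height, prom)
            for pos, height, prom in retained]


def delineate_nfrs(dyads: list[DyadCall], offset: int = DEFAULT_OFFSET,
                   min_width: int = 20, condition: str = "") -> list[NucleosomeFreeRegion]:
    """NFRs between consecutive dyads, borders `offset` bp from each dyad.

    For adjacent dyads d1 < d2 the candidate interval is
    [d1 + offset, d2 - offset); it is emitted when its width is at least
    `min_width` (default 20 bp, which admits ~50 bp promoter NFRs with
    margin while rejecting degenerate gaps). Nothing is called outside
    the outermost dyads.
    """
    if offset < 0 or min_width < 1:
        raise NfrConfigError("require offset >= 0 and min_width >= 1")
    dyads = sorted(dyads, key=lambda d: d.position)
    nfrs = []
    for d1, d2 in zip(dyads, dyads[1:]):
        start, end = d1.position + offset, d2.position - offset
        if end - start >= min_width:
            nfrs.append(NucleosomeFreeRegion(d1.chrom, start, end, d1, d2,
                                             condition=condition))
    return nfrs


def _overlap(a: NucleosomeFreeRegion, b: NucleosomeFreeRegion) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def compare_conditions(nfrs_a: list[NucleosomeFreeRegion],
                       nfrs_b: list[NucleosomeFreeRegion],
                       min_reciprocal_overlap: float = 0.5) -> pd.DataFrame:
    """Label NFRs from two condition maps as shared or condition-specific.

    A pair is shared when the overlap is at least `min_reciprocal_overlap`
    of both widths; pairing is 1-to-1, greedily by greatest overlap with
    ties broken towards the leftmost partner.
    """
    pairs = []
    for i, a in enumerate(nfrs_a):
        for j, b in enumerate(nfrs_b):
            ov = _overlap(a, b)
            if ov >= min_reciprocal_overlap * a.width and \
               ov >= min_reciprocal_overlap * b.width:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], nfrs_a[t[1]].start, nfrs_b[t[2]].start))
    matched_a: dict[int, int] = {}
    matched_b: dict[int, int] = {}
    for ov, i, j in pairs:
        if i not in matched_a and j not in matched_b:
            matched_a[i] = j
            matched_b[j] = i
    rows = []
    for i, a in enumerate(nfrs_a):
        rows.append({"condition": a.condition or "a", "chrom": a.chrom,
                     "start": a.start, "end": a.end,
                     "status": "shared" if i in matched_a else "condition-specific",
                     "partner_index": matched_a.get(i, -1)})
    for j, b in enumerate(nfrs_b):
        rows.append({"condition": b.condition or "b", "chrom": b.chrom,
                     "start": b.start, "end": b.end,
                     "status": "shared" if j in matched_b else "condition-specific",
                     "partner_index": matched_b.get(j, -1)})
    return pd.DataFrame(rows)
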