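"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by direct enumeration (regex scans,
per-base loops, exhaustive subset search) without touching the library's
code paths for that operation.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_coverage(fragments, length: int) -> np.ndarray:
    values = np.zeros(length, dtype=int)
    for s, e in fragments:
        for i in range(s, e):
            values[i] += 1
    return values


def brute_dyad_density(fragments, length: int) -> np.ndarray:
    values = np.zeros(length, dtype=int)
    for s, e in fragments:
        values[(s + e - 1) // 2] += 1
    return values


def brute_local_maxima(values) -> list[int]:
    """Leftmost indices of interior maximal plateaus, by direct scanning."""
    v = list(values)
    peaks = []
    for i in range(1, len(v) - 1):
        if v[i] <= v[i - 1]:
            continue
        j = i
        while j + 1 < len(v) and v[j + 1] == v[i]:
            j += 1
        if j + 1 < len(v) and v[j + 1] < v[i]:
            peaks.append(i)
    return peaks


def brute_prominence(values, peak: int) -> float:
    v = list(values)
    h = v[peak]
    sides = []
    for rng in (range(peak - 1, -1, -1), range(peak + 1, len(v))):
        lowest = h
        for idx in rng:
            if v[idx] > h:
                break
            lowest = min(lowest, v[idx])
        sides.append(lowest)
    return h - max(sides)


def brute_call_dyads(values, min_separation: int, min_prominence_fraction: float
                     ) -> list[int]:
    """Exhaustive local-maxima enumeration + the same greedy suppression rule."""
    vmax = max(values) if len(values) else 0
    if vmax == 0:
        return []
    cands = [(p, values[p], brute_prominence(values, p))
             for p in brute_local_maxima(values)]
    cands = [c for c in cands if c[2] >= min_prominence_fraction * vmax]
    retained = []
    for pos, h, prom in sorted(cands, key=lambda c: (-c[1], c[0])):
        if all(abs(pos - r) >= min_separation for r in retained):
            retained.append(pos)
    return sorted(retained)


def brute_scan(seq: str, start: int, spacer_len: int = 20,
               pam: str = "NGG") -> list[tuple[int, str, str, str]]:
    """Regex-based protospacer scan: (spacer_start, strand, spacer, pam)."""
    pam_re = pam.replace("N", "[ACGT]")
    sites = []
    for m in re.finditer(rf"(?=([ACGT]{{{spacer_len}}})({pam_re}))", seq):
        sites.append((start + m.start(), "+", m.group(1), m.group(2)))
    rc_pam_re = rc(pam).replace("N", "[ACGT]")
    for m in re.finditer(rf"(?=({rc_pam_re})([ACGT]{{{spacer_len}}}))", seq):
        sites.append((start + m.start() + len(pam), "-",
                      rc(m.group(2)), rc(m.group(1))))
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def brute_offtargets(spacer: str, chrom: str, spacer_start: int, strand: str,
                     sequences: dict[str, str], max_mm: int,
                     require_pam: bool = True, pam: str = "NGG") -> list[int]:
    """Per-base Hamming scan over every PAM-adjacent locus on both strands."""
    L = len(spacer)

    def pam_ok(s: str, pattern: str) -> bool:
        table = {"N": "ACGT", "A": "A", "C": "C", "G": "G", "T": "T"}
        return len(s) == len(pattern) and \
            all(b in table[p] for b, p in zip(s, pattern))

    counts = [0] * (max_mm + 1)
    for name, seq in sequences.items():
        n = len(seq)
        for i in range(n - L + 1):
            # plus strand
            if not require_pam or pam_ok(seq[i + L:i + L + 3], pam):
                if not (require_pam and i + L + 3 > n):
                    if not (name == chrom and strand == "+" and i == spacer_start):
                        mm = sum(a != b for a, b in zip(spacer, seq[i:i + L]))
                        if mm <= max_mm:
                            counts[mm] += 1
            # minus strand: genomic PAM immediately 5' of the window
            if not require_pam or (i >= 3 and pam_ok(rc(seq[i - 3:i]), pam)):
                if not (name == chrom and strand == "-" and i == spacer_start):
                    mm = sum(a != b for a, b in zip(spacer, rc(seq[i:i + L])))
                    if mm <= max_mm:
                        counts[mm] += 1
    return counts


def brute_rank(scores) -> list:
    """Selection sort with explicit pairwise precedence (no key reuse)."""
    def precedes(a, b) -> bool:
        if a.total != b.total:
            return a.total > b.total
        if abs(a.tss_distance) != abs(b.tss_distance):
            return abs(a.tss_distance) < abs(b.tss_distance)
        if a.site.strand != b.site.strand:
            return a.site.strand == "+"
        return a.site.spacer_start < b.site.spacer_start

    remaining = list(scores)
    out = []
    while remaining:
        best = remaining[0]
        for cand in remaining[1:]:
            if precedes(cand, best):
                best = cand
        out.append(best)
        remaining.remove(best)
    return out


def brute_multiplex(ranked, k: int, min_spacing: int) -> list:
    """The unique greedy-consistent feasible subset, found by set enumeration.

    Enumerates every spacing-feasible subset of rank indices and returns
    the one where each member is exactly the first compatible candidate
    given its predecessors (and no further guide could be appended below
    the size cap).
    """
    centers = [g.site.center() for g in ranked]
    n = len(ranked)

    def feasible(idx: tuple[int, ...]) -> bool:
        return all(abs(centers[a] - centers[b]) >= min_spacing
                   for a, b in itertools.combinations(idx, 2))

    def greedy_consistent(idx: tuple[int, ...]) -> bool:
        chosen: list[int] = []
        for j in range(n):
            if len(chosen) == k:
                break
            compatible = all(abs(centers[j] - centers[c]) >= min_spacing
                             for c in chosen)
            if j in idx:
                if not compatible:
                    return False
                chosen.append(j)
            elif compatible:
                return False  # greedy would have taken j
        return tuple(chosen) == idx

    for size in range(min(k, n), -1, -1):
        for idx in itertools.combinations(range(n), size):
            if feasible(idx) and greedy_consistent(idx):
                return [ranked[i] for i in idx]
    return []
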