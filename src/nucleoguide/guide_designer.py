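"""Protospacer enumeration and genome-wide off-target vetting.

Scans a promoter region on both strands for 20-nt protospacers adjacent
to an NGG PAM (SpCas9), then counts genome-wide off-target loci by exact
Hamming-mismatch tier at every PAM-adjacent position. Exhaustive
enumeration is deterministic and strictly more stringent than heuristic
similarity search; tiers 0-3 are reported so users can apply their own
tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dna import encode, matches_pattern, pattern_mask, revcomp
from .genome_model import Genome, PromoterRegion


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ProtospacerSite:
    """A spacer+PAM site with strand-resolved genomic coordinates.

    `spacer` and `pam` are given 5'->3' in sgRNA orientation; on the minus
    strand the genome substring at `spacer_interval` is therefore the
    reverse complement of `spacer`, and the PAM sits immediately 5' of the
    spacer in genome coordinates.
    """

    chrom: str
    strand: str
    spacer: str
    spacer_start: int
    spacer_end: int
    pam: str
    pam_start: int
    pam_end: int

    def center(self) -> int:
        """Floor midpoint of the spacer interval (integer base position)."""
        return (self.spacer_start + self.spacer_end - 1) // 2

    def validate(self, genome: Genome) -> None:
        seq = genome.sequences[self.chrom]
        spacer_genomic = seq[self.spacer_start:self.spacer_end]
        pam_genomic = seq[self.pam_start:self.pam_end]
        if self.strand == "+":
            assert spacer_genomic == self.spacer
            assert pam_genomic == self.pam
            assert self.pam_start == self.spacer_end
        else:
            assert revcomp(spacer_genomic) == self.spacer
            assert revcomp(pam_genomic) == self.pam
            assert self.pam_end == self.spacer_start


@dataclass
class OffTargetReport:
    site: ProtospacerSite
    counts: list[int]  # indexed by mismatch count 0..max_mismatches
    example_hits: list[tuple[str, int, str]] = field(default_factory=list)

    def lowest_tier(self) -> int | None:
        for tier, n in enumerate(self.counts):
            if n:
                return tier
        return None


def scan_protospacers(region: PromoterRegion, genome: Genome,
                      spacer_len: int = 20, pam_pattern: str = "NGG"
                      ) -> list[ProtospacerSite]:
    """Enumerate every PAM-adjacent protospacer within a region, both strands.

    A site requires the full spacer and PAM to lie inside the region.
    Spacers containing N are excluded (ambiguous, unsynthesizable).
    Output is sorted by spacer start, then '+' before '-'.
    """
    if spacer_len < 16:
        raise DesignError("spacer_len must be >= 16")
    seq = genome.sequences[region.chrom]
    start, end = region.start, region.end
    plen = len(pam_pattern)
    if end - start < spacer_len + plen:
        warnings.warn("region shorter than spacer + PAM; no sites", stacklevel=2)
        return []
    sub = seq[start:end]
    sites: list[ProtospacerSite] = []
    # plus strand: spacer at [i, i+L), PAM at [i+L, i+L+plen)
    for i in range(0, len(sub) - spacer_len - plen + 1):
        pam = sub[i + spacer_len:i + spacer_len + plen]
        if matches_pattern(pam, pam_pattern):
            spacer = sub[i:i + spacer_len]
            if "N" in spacer:
                continue
            sites.append(ProtospacerSite(
                region.chrom, "+", spacer,
                start + i, start + i + spacer_len,
                pam, start + i + spacer_len, start + i + spacer_len + plen))
    # minus strand: PAM (genomic) at [j, j+plen), spacer at [j+plen, j+plen+L)
    rc_pam_pattern = revcomp(pam_pattern)
    for j in range(0, len(sub) - spacer_len - plen + 1):
        pam_genomic = sub[j:j + plen]
        if matches_pattern(pam_genomic, rc_pam_pattern):
            spacer_genomic = sub[j + plen:j + plen + spacer_len]
            if "N" in spacer_genomic:
                continue
            sites.append(ProtospacerSite(
                region.chrom, "-", revcomp(spacer_genomic),
                start + j + plen, start + j + plen + spacer_len,
                revcomp(pam_genomic), start + j, start + j + plen))
    sites.sort(key=lambda s: (s.spacer_start, s.strand))
    return sites


def _tier_hits(spacer_bytes: np.ndarray, arr: np.ndarray, mask: np.ndarray,
               max_mismatches: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions (window starts) passing `mask` and their mismatch counts."""
    L = spacer_bytes.size
    pos = np.flatnonzero(mask)
    pos = pos[pos + L <= arr.size]
    if pos.size == 0:
        return pos, np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)[pos]
    mm = (windows != spacer_bytes).sum(axis=1)
    keep = mm <= max_mismatches
    return pos[keep], mm[keep]


def count_offtargets(site: ProtospacerSite, genome: Genome,
                     max_mismatches: int = 3, require_pam: bool = True,
                     pam_pattern: str = "NGG") -> OffTargetReport:
    """Tally genome-wide candidate loci by Hamming distance to the spacer.

    Every position on both strands of every chromosome where (when
    `require_pam`) a PAM-pattern match is adjacent contributes one
    candidate; its distance to the site's spacer (sgRNA orientation) is
    computed exactly and tallied into tiers 0..max_mismatches. The
    on-target locus itself (same coordinates and strand) is excluded.
    N bases never match and so count as mismatches.
    """
    L = len(site.spacer)
    if max_mismatches > L:
        raise DesignError("max_mismatches exceeds spacer length")
    plen = len(pam_pattern)
    spacer_fwd = encode(site.spacer)
    spacer_rc = encode(revcomp(site.spacer))
    counts = np.zeros(max_mismatches + 1, dtype=np.int64)
    hits_by_tier: dict[int, list[tuple[str, int, str]]] = {}

    for chrom, seq in genome.sequences.items():
        arr = encode(seq)
        n = arr.size
        # plus strand: spacer window at i requires PAM match at i+L
        if require_pam:
            pam_ok = pattern_mask(arr, pam_pattern)
            plus_mask = np.zeros(n, dtype=bool)
            if n > L:
                plus_mask[: n - L] = pam_ok[L:]
        else:
            plus_mask = np.zeros(n, dtype=bool)
            plus_mask[: max(0, n - L + 1)] = True
        pos, mm = _tier_hits(spacer_fwd, arr, plus_mask, max_mismatches)
        for p, m in zip(pos, mm):
            if chrom == site.chrom and site.strand == "+" and p == site.spacer_start:
                continue  # the on-target locus
            counts[m] += 1
            hits_by_tier.setdefault(int(m), []).append((chrom, int(p), "+"))

        # minus strand: genomic spacer window at j requires a revcomp-PAM
        # match ending at j; compare against revcomp(spacer).
        if require_pam:
            rc_ok = pattern_mask(arr, revcomp(pam_pattern))
            minus_mask = np.zeros(n, dtype=bool)
            minus_mask[plen:] = rc_ok[: n - plen]
        else:
            minus_mask = np.ones(n, dtype=bool)
        pos, mm = _tier_hits(spacer_rc, arr, minus_mask, max_mismatches)
        for p, m in zip(pos, mm):
            if chrom == site.chrom and site.strand == "-" and p == site.spacer_start:
                continue
            counts[m] += 1
            hits_by_tier.setdefault(int(m), []).append((chrom, int(p), "-"))

    examples: list[tuple[str, int, str]] = []
    for tier in sorted(hits_by_tier):
        examples = sorted(hits_by_tier[tier])[:10]
        break
    return OffTargetReport(site, counts.tolist(), examples)


def filter_candidates(sites: list[ProtospacerSite], reports: list[OffTargetReport],
                      max_tier0: int = 0, max_tier1: int = 0,
                      max_tier2: int | None = None) -> list[ProtospacerSite]:
    """Drop sites exceeding per-tier off-target ceilings (order preserved).

    Defaults demand genome-unique sites at 0 and 1 mismatch; 2-mismatch
    counts are reported but unfiltered unless a ceiling is given.
    """
    if len(sites) != len(reports):
        raise DesignError("sites and reports must align 1-to-1")
    kept = []
    for site, rep in zip(sites, reports):
        c = rep.counts + [0, 0, 0]
        if c[0] <= max_tier0 and c[1] <= max_tier1 and \
           (max_tier2 is None or c[2] <= max_tier2):
            kept.append(site)
    return kept
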