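"""Self-contained synthetic loci for testing and demonstration.

Generates a random genome with annotated genes (including a divergent
pair sharing a compact bidirectional promoter), plants phased nucleosome
arrays flanking promoter nucleosome-free regions, samples
mononucleosome-sized MNase fragments around each planted dyad, and
fabricates qPCR Ct tables with a planted fold change. Every generator is
deterministic given (parameters, seed), and the planted truth (dyads,
NFRs, TSSs) is returned alongside the data so recovery can be measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import GeneModel, Genome, detect_bidirectional
from .mnase_profile import FragmentSet
from .nfr_caller import DEFAULT_OFFSET


class SimulationError(ValueError):
    pass


@dataclass
class SimulatedLocus:
    """A synthetic genome plus its planted ground truth."""

    genome: Genome
    genes: list[GeneModel]
    truth_dyads: dict[str, np.ndarray]
    truth_nfrs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    offset: int = DEFAULT_OFFSET
    seed: int = 0


def simulate_genome(n_chrom: int = 1, length: int = 20_000, gc: float = 0.5,
                    seed: int = 0, gene_length: tuple[int, int] = (900, 1500),
                    intergenic: tuple[int, int] = (650, 950),
                    divergent_separation: tuple[int, int] = (260, 400),
                    ) -> tuple[Genome, list[GeneModel]]:
    """Random genome with annotated genes, including one divergent pair.

    Bases are i.i.d. at the requested GC content. Each chromosome starts
    with a divergently transcribed gene pair whose TSS separation is
    drawn from `divergent_separation` (spanning the ~305 bp scale of
    compact fungal bidirectional promoters), followed by alternating
    tandem genes at `intergenic` spacing. Raises on infeasible packing.
    """
    if length < 5000:
        raise SimulationError("chromosome length must be >= 5000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome_seqs: dict[str, str] = {}
    genes: list[GeneModel] = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
        genome_seqs[chrom] = seq
        cursor = 900
        # divergent pair: minus-strand gene, shared promoter, plus-strand gene
        len_a = int(rng.integers(*gene_length))
        sep = int(rng.integers(*divergent_separation))
        len_b = int(rng.integers(*gene_length))
        start_b = cursor + len_a - 1 + sep
        if start_b + len_b + 900 > length:
            raise SimulationError("chromosome too short for the divergent pair")
        ga = GeneModel(f"{chrom}g1", chrom, "-", cursor, cursor + len_a,
                       cursor + len_a - 1)
        gb = GeneModel(f"{chrom}g2", chrom, "+", start_b, start_b + len_b, start_b)
        genes += [ga, gb]
        cursor = gb.end
        i = 3
        while True:
            gap = int(rng.integers(*intergenic))
            glen = int(rng.integers(*gene_length))
            start = cursor + gap
            if start + glen + 200 > length:
                break
            strand = "+" if i % 2 else "-"
            tss = start if strand == "+" else start + glen - 1
            genes.append(GeneModel(f"{chrom}g{i}", chrom, strand,
                                   start, start + glen, tss))
            cursor = start + glen
            i += 1
    return Genome(genome_seqs), genes


def plant_nucleosomes(chrom_length: int, nfr_windows: list[tuple[int, int]],
                      repeat_length: int = 165, offset: int = DEFAULT_OFFSET,
                      jitter_sd: float = 0.0, seed: int = 0, margin: int = 80,
                      ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Phase dyads along one chromosome around the requested NFR windows.

    Each window [s, e) gets exact flanking dyads at s - offset and
    e + offset, so the truth NFR between them (at the configured offset)
    is the window itself. Segments between flanking dyads — and from the
    chromosome ends to the outermost flanks — are filled with dyads at
    approximately `repeat_length` spacing (rounded even division inside
    segments, exact stepping at the ends), jittered by N(0, jitter_sd)
    and clamped to stay out of every window. Returns (dyads, truth NFRs).
    """
    rng = np.random.default_rng(seed)
    windows = sorted(nfr_windows)
    for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
        if s2 - e1 < 2 * offset:
            raise SimulationError("NFR windows too close to carry distinct flanks")
    for s, e in windows:
        if not (margin <= s - offset and e + offset <= chrom_length - margin):
            raise SimulationError("NFR window too close to the chromosome end")
        if e - s + 2 * offset < repeat_length:
            warnings.warn("NFR window narrower than one nucleosome repeat; the "
                          "planted gap may not exclude a phased dyad", stacklevel=2)

    def jitter(pos: float, lo: int, hi: int) -> int:
        p = int(round(pos + (rng.normal(0, jitter_sd) if jitter_sd > 0 else 0)))
        return int(min(max(p, lo), hi))

    dyads: list[int] = []
    anchors: list[int] = []
    for s, e in windows:
        anchors += [s - offset, e + offset]
    if not anchors:
        anchors = [margin]  # bare lattice when no windows are requested
        dyads.append(margin)
    # leading arm
    first = anchors[0]
    k = 1
    while first - k * repeat_length >= margin:
        lo = margin
        hi = first - (k - 1) * repeat_length - repeat_length // 2
        dyads.append(jitter(first - k * repeat_length, lo, hi))
        k += 1
    # anchors and interior fills
    for a in anchors:
        if a not in dyads:
            dyads.append(a)
    fill_segments = []
    for i in range(1, len(anchors) - 1, 2):  # right flank of window i//2 -> next left flank
        fill_segments.append((anchors[i], anchors[i + 1]))
    for a, b in fill_segments:
        n_fill = max(0, int(round((b - a) / repeat_length)) - 1)
        # keep realized spacing within ~10% of the repeat (no overlapping cores)
        while n_fill > 0 and (b - a) / (n_fill + 1) < 0.9 * repeat_length:
            n_fill -= 1
        for k in range(1, n_fill + 1):
            pos = a + (b - a) * k / (n_fill + 1)
            dyads.append(jitter(pos, a + repeat_length // 2, b - repeat_length // 2))
    # trailing arm
    last = anchors[-1]
    k = 1
    while last + k * repeat_length <= chrom_length - margin:
        lo = last + (k - 1) * repeat_length + repeat_length // 2
        hi = chrom_length - margin
        dyads.append(jitter(last + k * repeat_length, lo, hi))
        k += 1
    dyads_arr = np.array(sorted(set(dyads)), dtype=np.int64)
    for s, e in windows:  # planted truth must keep the windows clean
        assert not np.any((dyads_arr >= s) & (dyads_arr < e))
    truth_nfrs = [(s, e) for s, e in windows]
    return dyads_arr, truth_nfrs


def default_nfr_windows(genes: list[GeneModel], chrom: str, chrom_length: int,
                        rng: np.random.Generator,
                        width_range: tuple[int, int] = (100, 180),
                        upstream_center: int = 150, max_gap: int = 600,
                        offset: int = DEFAULT_OFFSET) -> list[tuple[int, int]]:
    """Promoter NFR windows: one per TSS, one shared per divergent pair."""
    chrom_genes = [g for g in genes if g.chrom == chrom]
    bidir = detect_bidirectional(chrom_genes, max_gap=max_gap)
    paired = {g.gene_id for r in bidir for g in r.target_genes}
    windows: list[tuple[int, int]] = []
    for region in bidir:
        width = int(rng.integers(*width_range))
        width = min(width, region.width - 20)
        center = (region.start + region.end) // 2
        windows.append((center - width // 2, center - width // 2 + width))
    for g in chrom_genes:
        if g.gene_id in paired:
            continue
        width = int(rng.integers(*width_range))
        center = g.tss - upstream_center if g.strand == "+" else g.tss + upstream_center
        s = center - width // 2
        windows.append((s, s + width))
    windows = [(max(offset + 90, s), min(chrom_length - offset - 90, e))
               for s, e in sorted(windows)]
    merged: list[tuple[int, int]] = []
    for s, e in windows:  # merge windows whose flanking dyads would crowd
        if merged and s - merged[-1][1] < 2 * offset + 140:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def simulate_locus(seed: int = 0, n_chrom: int = 1, length: int = 20_000,
                   gc: float = 0.5, repeat_length: int = 165,
                   offset: int = DEFAULT_OFFSET, jitter_sd: float = 5.0,
                   ) -> SimulatedLocus:
    """Convenience composition: genome + genes + planted nucleosome truth."""
    genome, genes = simulate_genome(n_chrom=n_chrom, length=length, gc=gc, seed=seed)
    rng = np.random.default_rng(seed + 1)
    truth_dyads: dict[str, np.ndarray] = {}
    truth_nfrs: dict[str, list[tuple[int, int]]] = {}
    for chrom in genome.sequences:
        windows = default_nfr_windows(genes, chrom, genome.length(chrom), rng,
                                      offset=offset)
        dyads, nfrs = plant_nucleosomes(genome.length(chrom), windows,
                                        repeat_length=repeat_length, offset=offset,
                                        jitter_sd=jitter_sd,
                                        seed=seed + 2 + hash(chrom) % 1000)
        truth_dyads[chrom] = dyads
        truth_nfrs[chrom] = nfrs
    return SimulatedLocus(genome, genes, truth_dyads, truth_nfrs, offset, seed)


def simulate_fragments(dyads: np.ndarray, chrom: str, chrom_length: int,
                       fragments_per_nucleosome: int, frag_mean: float = 147,
                       frag_sd: float = 15, center_jitter_sd: float = 10,
                       length_clip: tuple[int, int] = (100, 200),
                       seed: int = 0) -> FragmentSet:
    """Sample MNase-protected fragments around each planted dyad.

    Fragment centers are the dyad plus N(0, center_jitter_sd) — emulating
    variable MNase trimming — and lengths are N(frag_mean, frag_sd)
    rounded and clipped to the mononucleosome window. The count is exactly
    fragments_per_nucleosome x len(dyads).
    """
    if fragments_per_nucleosome < 1:
        raise SimulationError("fragments_per_nucleosome must be >= 1")
    rng = np.random.default_rng(seed)
    n = fragments_per_nucleosome * len(dyads)
    centers = np.repeat(dyads, fragments_per_nucleosome) + \
        rng.normal(0, center_jitter_sd, size=n)
    lengths = np.clip(np.round(rng.normal(frag_mean, frag_sd, size=n)),
                      *length_clip).astype(np.int64)
    starts = np.round(centers).astype(np.int64) - lengths // 2
    starts = np.clip(starts, 0, chrom_length - lengths)
    frags = np.stack([starts, starts + lengths], axis=1)
    order = np.lexsort((frags[:, 1], frags[:, 0]))
    return FragmentSet(chrom, frags[order], source="bed")


def simulate_qpcr(true_fold: float, n_bio: int = 3, ct_noise_sd: float = 0.0,
                  seed: int = 0, target: str = "mdpE",
                  refs: tuple[str, ...] = ("actA", "benA"),
                  tech_reps: int = 2) -> pd.DataFrame:
    """Long-format Ct table with a planted fold change.

    Reference genes sit at fixed Cts (22 and 23 cycles; mean 22.5); the
    calibrator group's target dCt is fixed at +5.5 cycles and the treated
    group's dCt is 5.5 − log2(true_fold) + N(0, ct_noise_sd) per
    biological replicate, so a noise-free table inverts exactly through
    the Livak computation. Technical replicates are identical copies.
    """
    if true_fold <= 0:
        raise SimulationError("true_fold must be positive")
    rng = np.random.default_rng(seed)
    ref_cts = {r: 22.0 + i for i, r in enumerate(refs)}
    ref_mean = float(np.mean(list(ref_cts.values())))
    base_dct = 5.5
    rows = []
    for group, prefix in (("calibrator", "control"), ("treated", "treated")):
        for b in range(1, n_bio + 1):
            sample = f"{prefix}_{b}"
            if group == "calibrator":
                dct = base_dct
            else:
                noise = rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                dct = base_dct - np.log2(true_fold) + noise
            for gene, ct in ((target, ref_mean + dct), *ref_cts.items()):
                for t in range(1, tech_reps + 1):
                    rows.append({"sample_id": sample, "gene_id": gene,
                                 "replicate": t, "ct": float(ct),
                                 "efficiency": 100.0})
    return pd.DataFrame(rows)
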