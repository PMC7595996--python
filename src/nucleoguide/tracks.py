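"""Plain-text genome-track and table I/O (bedGraph, BED, FASTA, GFF3, SAM).

All emitted coordinates are 0-based half-open (bedGraph/BED convention);
GFF3 is written 1-based inclusive. Output is deterministic: fixed column
orders, fixed float formatting, no timestamps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .genome_model import GeneModel, Genome
from .guide_designer import OffTargetReport, ProtospacerSite
from .guide_ranker import GuideScore
from .mnase_profile import FragmentSet, OccupancyProfile
from .nfr_caller import DyadCall, NucleosomeFreeRegion


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_bedgraph(profile: OccupancyProfile, path, mode: str = "w") -> None:
    """Run-length-compressed 4-column bedGraph; zero runs are kept explicit."""
    v = np.asarray(profile.values)
    with open(path, mode) as fh:
        if v.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [v.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{profile.chrom}\t{s}\t{e}\t{_fmt(v[s])}\n")


def read_bedgraph(path) -> dict[str, OccupancyProfile]:
    """Read a bedGraph into per-chromosome profiles (length = last covered base)."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, val = line.split()[:4]
            spans.setdefault(chrom, []).append((int(s), int(e), float(val)))
    out = {}
    for chrom, rows in spans.items():
        length = max(e for _, e, _ in rows)
        values = np.zeros(length)
        for s, e, val in rows:
            values[s:e] = val
        out[chrom] = OccupancyProfile(chrom, values)
    return out


def write_dyads_bed(dyads: list[DyadCall], path) -> None:
    """Dyad axes as 1-bp BED6 records; score = prominence."""
    with open(path, "w") as fh:
        for d in sorted(dyads, key=lambda d: (d.chrom, d.position)):
            fh.write(f"{d.chrom}\t{d.position}\t{d.position + 1}\t"
                     f"dyad\t{_fmt(d.prominence)}\t.\n")


def write_nfrs_bed(nfrs: list[NucleosomeFreeRegion], path) -> None:
    """NFRs as BED6; the name column carries the condition label."""
    with open(path, "w") as fh:
        for n in sorted(nfrs, key=lambda n: (n.chrom, n.start)):
            name = n.condition or "NFR"
            fh.write(f"{n.chrom}\t{n.start}\t{n.end}\t{name}\t{n.width}\t.\n")


def read_nfrs_bed(path) -> list[tuple[str, int, int, str]]:
    """NFR intervals (chrom, start, end, label) from a BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            label = fields[3] if len(fields) > 3 else ""
            out.append((fields[0], int(fields[1]), int(fields[2]), label))
    return out


def candidates_frame(sites: list[ProtospacerSite],
                     reports: list[OffTargetReport] | None = None) -> pd.DataFrame:
    rows = []
    for i, site in enumerate(sites):
        row = {"chrom": site.chrom, "start": site.spacer_start,
               "end": site.spacer_end, "strand": site.strand,
               "spacer": site.spacer, "pam": site.pam,
               "pam_start": site.pam_start, "pam_end": site.pam_end}
        if reports is not None:
            for tier, n in enumerate(reports[i].counts):
                row[f"mm{tier}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def ranked_frame(scores: list[GuideScore]) -> pd.DataFrame:
    rows = []
    for rank, g in enumerate(scores, start=1):
        rows.append({
            "rank": rank, "target_gene": g.target_gene,
            "chrom": g.site.chrom, "start": g.site.spacer_start,
            "end": g.site.spacer_end, "strand": g.site.strand,
            "spacer": g.site.spacer, "pam": g.site.pam,
            "tss_distance": g.tss_distance,
            "nfr_component": round(g.nfr_component, 6),
            "distance_component": round(g.distance_component, 6),
            "offtarget_component": round(g.offtarget_component, 6),
            "crispri_flag": g.crispri_flag, "preferred": g.preferred,
            "total": round(g.total, 6),
        })
    return pd.DataFrame(rows)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.sequences:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: list[GeneModel], path) -> None:
    """Gene features, converted back to GFF3 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\tnucleoguide\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def write_fragments_bed(fragments: FragmentSet, path, mode: str = "w") -> None:
    with open(path, mode) as fh:
        for s, e in fragments.fragments:
            fh.write(f"{fragments.chrom}\t{s}\t{e}\n")


def write_fragments_sam(fragment_sets: dict[str, FragmentSet], genome: Genome,
                        path, read_length: int = 50) -> None:
    """Fully specified paired-end records (PE50-style) for each fragment.

    Read 1 covers the fragment's 5' end, read 2 its 3' end, with correct
    template lengths, so the fragments recovered from this SAM equal the
    input FragmentSets exactly.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": name, "LN": genome.length(name)}
                     for name in genome.sequences]}
    ref_ids = {name: i for i, name in enumerate(genome.sequences)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for chrom in genome.sequences:
            if chrom not in fragment_sets:
                continue
            fs = fragment_sets[chrom]
            seq = genome.sequences[chrom]
            for idx, (s, e) in enumerate(fs.fragments):
                rl = min(read_length, e - s)
                for first in (True, False):
                    a = pysam.AlignedSegment()
                    a.query_name = f"{chrom}_frag{idx}"
                    a.reference_id = ref_ids[chrom]
                    a.next_reference_id = ref_ids[chrom]
                    a.mapping_quality = 60
                    a.cigarstring = f"{rl}M"
                    if first:
                        a.flag = 99   # paired, proper, mate reverse, read1
                        a.reference_start = s
                        a.next_reference_start = e - rl
                        a.template_length = e - s
                        a.query_sequence = seq[s:s + rl]
                    else:
                        a.flag = 147  # paired, proper, reverse, read2
                        a.reference_start = e - rl
                        a.next_reference_start = s
                        a.template_length = -(e - s)
                        a.query_sequence = seq[e - rl:e]
                    a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                    out.write(a)


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
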