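"""Guide scoring, ranking, bidirectional assignment and multiplex selection.

A candidate guide for dCas9-activator (CRISPRa) recruitment is scored by
three bounded components:

* NFR membership — activators bind poorly inside positioned nucleosomes,
  so the fraction of spacer bases lying in nucleosome-free regions is
  rewarded (1 when the spacer sits entirely inside an NFR);
* TSS distance — activation is strongest in a window upstream of the
  TSS (defaults 42-210 bp, spacer center to TSS, with a tendency towards
  <110 bp reported separately); the component is 1 inside the window and
  tapers linearly to 0 over one window-width outside;
* off-target burden — 1/(1 + weighted mismatch-tier counts).

Guides whose spacer encroaches on the TSS (within `crispri_exclusion` bp
upstream, or downstream of it) risk steric interference (CRISPRi) rather
than activation and are zeroed outright.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from .genome_model import GeneModel, PromoterRegion
from .guide_designer import OffTargetReport, ProtospacerSite
from .nfr_caller import NucleosomeFreeRegion


class RankingError(ValueError):
    pass


@dataclass
class RankingConfig:
    """Tunable scoring parameters (all distances in bp)."""

    window_min: int = 42
    window_max: int = 210
    preferred_max: int = 110
    crispri_exclusion: int = 30
    w_nfr: float = 0.4
    w_distance: float = 0.4
    w_offtarget: float = 0.2
    tier_weights: tuple[float, ...] = (10.0, 5.0, 1.0, 0.2)

    def __post_init__(self) -> None:
        if not (0 < self.window_min < self.preferred_max <= self.window_max):
            raise RankingError("require 0 < window_min < preferred_max <= window_max")
        if self.crispri_exclusion < 0:
            raise RankingError("crispri_exclusion must be >= 0")
        weights = (self.w_nfr, self.w_distance, self.w_offtarget)
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise RankingError("component weights must be non-negative and sum to 1")


@dataclass
class GuideScore:
    site: ProtospacerSite
    target_gene: str
    tss_distance: int          # positive = upstream of the TSS
    nfr_component: float
    distance_component: float
    crispri_flag: bool
    offtarget_component: float
    total: float
    preferred: bool = False    # center within the preferred (<110 bp) zone

    def __post_init__(self) -> None:
        for c in (self.nfr_component, self.distance_component, self.offtarget_component):
            if not (0.0 <= c <= 1.0 + 1e-12):
                raise RankingError("score components must lie in [0, 1]")


@dataclass
class MultiplexSet:
    guides: list[GuideScore]
    pairwise_min_distance: int
    combined: float = field(init=False)

    def __post_init__(self) -> None:
        for a, b in itertools.combinations(self.guides, 2):
            if abs(a.site.center() - b.site.center()) < self.pairwise_min_distance:
                raise RankingError("multiplex guides violate pairwise spacing")
        self.combined = sum(g.total for g in self.guides)


def _upstream_distance(position: int, gene: GeneModel) -> int:
    """Signed distance of a base from the TSS; positive = upstream (5')."""
    if gene.strand == "+":
        return gene.tss - position
    return position - gene.tss


def distance_component(tss_distance: float, config: RankingConfig) -> float:
    """1 on [window_min, window_max]; linear taper to 0 over one window width."""
    width = config.window_max - config.window_min
    if tss_distance < config.window_min:
        return max(0.0, 1.0 - (config.window_min - tss_distance) / width)
    if tss_distance > config.window_max:
        return max(0.0, 1.0 - (tss_distance - config.window_max) / width)
    return 1.0


def _nfr_component(site: ProtospacerSite, nfrs: list[NucleosomeFreeRegion]) -> float:
    length = site.spacer_end - site.spacer_start
    covered = 0
    for nfr in nfrs:
        if nfr.chrom != site.chrom:
            continue
        covered += max(0, min(site.spacer_end, nfr.end) - max(site.spacer_start, nfr.start))
    return min(1.0, covered / length)


def score_guide(site: ProtospacerSite, promoter: PromoterRegion, gene: GeneModel,
                nfrs: list[NucleosomeFreeRegion], report: OffTargetReport | None,
                config: RankingConfig | None = None) -> GuideScore:
    """Score one candidate against one gene's TSS.

    The TSS distance is measured from the TSS to the spacer's floor
    midpoint. A crispri flag is raised when any spacer base lies within
    `crispri_exclusion` bp upstream of the TSS or at/downstream of it,
    and forces the total to 0.
    """
    config = config or RankingConfig()
    if not (promoter.start <= site.spacer_start and site.spacer_end <= promoter.end):
        raise RankingError("site lies outside the promoter region")
    center = site.center()
    tss_distance = _upstream_distance(center, gene)
    dists = [_upstream_distance(b, gene)
             for b in (site.spacer_start, site.spacer_end - 1)]
    crispri = min(dists) <= config.crispri_exclusion
    nfr_c = _nfr_component(site, nfrs)
    dist_c = distance_component(tss_distance, config)
    if report is None:
        ot_c = 1.0
    else:
        burden = sum(w * n for w, n in zip(config.tier_weights, report.counts))
        ot_c = 1.0 / (1.0 + burden)
    total = 0.0 if crispri else (config.w_nfr * nfr_c +
                                 config.w_distance * dist_c +
                                 config.w_offtarget * ot_c)
    return GuideScore(site, gene.gene_id, tss_distance, nfr_c, dist_c,
                      crispri, ot_c, total,
                      preferred=0 < tss_distance <= config.preferred_max)


def _rank_key(score: GuideScore):
    return (-score.total, abs(score.tss_distance),
            0 if score.site.strand == "+" else 1, score.site.spacer_start)


def rank_guides(scores: list[GuideScore]) -> list[GuideScore]:
    """Descending by total; ties by |TSS distance|, then '+' strand, then position."""
    return sorted(scores, key=_rank_key)


@dataclass
class BidirectionalAssignment:
    scores: tuple[GuideScore, GuideScore]  # (left gene, right gene) by coordinate
    primary: str                           # gene_id predicted as the main target

    def __iter__(self):
        return iter(self.scores)


def assign_bidirectional(site: ProtospacerSite, promoter: PromoterRegion,
                         nfrs: list[NucleosomeFreeRegion],
                         report: OffTargetReport | None,
                         config: RankingConfig | None = None
                         ) -> BidirectionalAssignment:
    """Score one site against both genes of a bidirectional promoter.

    Both scores are always reported — guide-to-TSS proximity did not
    reliably predict which divergent gene responds more strongly in
    practice — with the higher-scoring gene labelled as the nominal
    primary target (ties: smaller |TSS distance|, then the
    leftmost-coordinate gene).
    """
    if not promoter.bidirectional:
        raise RankingError("assign_bidirectional requires a bidirectional promoter")
    left, right = sorted(promoter.target_genes, key=lambda g: g.start)
    s_left = score_guide(site, promoter, left, nfrs, report, config)
    s_right = score_guide(site, promoter, right, nfrs, report, config)
    if (s_left.total, -abs(s_left.tss_distance)) > (s_right.total, -abs(s_right.tss_distance)):
        primary = left.gene_id
    elif (s_right.total, -abs(s_right.tss_distance)) > (s_left.total, -abs(s_left.tss_distance)):
        primary = right.gene_id
    else:
        primary = left.gene_id  # documented tie-break: leftmost-coordinate gene
    return BidirectionalAssignment((s_left, s_right), primary)


def select_multiplex(ranked: list[GuideScore], k: int,
                     min_spacing: int = 30) -> MultiplexSet:
    """Greedy multiplex selection respecting a pairwise center spacing.

    Walks the ranked list, skipping any guide whose spacer center is
    closer than `min_spacing` bp to an already-selected guide (default
    30 bp, beyond the dCas9/sgRNA footprint so co-expressed guides do not
    compete), stopping at `k` guides or exhaustion. Warns when fewer than
    `k` are selectable, and when k=1 is requested (single guides may be
    insufficient for activation; combinations of two or more guides are
    typically required).
    """
    if k < 1:
        raise RankingError("k must be >= 1")
    if k == 1:
        warnings.warn("k=1 requested: single guides may fail to activate; "
                      "consider a multiplex of 2 or more", stacklevel=2)
    selected: list[GuideScore] = []
    for g in ranked:
        if len(selected) == k:
            break
        if all(abs(g.site.center() - s.site.center()) >= min_spacing
               for s in selected):
            selected.append(g)
    if len(selected) < k:
        warnings.warn(f"only {len(selected)} of {k} requested guides satisfy "
                      f"the {min_spacing} bp spacing", stacklevel=2)
    return MultiplexSet(selected, min_spacing)
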