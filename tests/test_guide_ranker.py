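"""Guide scoring, ranking determinism, bidirectional assignment, multiplexing."""

import numpy as np
import pytest

from nucleoguide.genome_model import GeneModel, PromoterRegion
from nucleoguide.guide_designer import OffTargetReport, ProtospacerSite
from nucleoguide.guide_ranker import (RankingConfig, RankingError,
                                      assign_bidirectional, distance_component,
                                      rank_guides, score_guide, select_multiplex)
from nucleoguide.nfr_caller import DyadCall, NucleosomeFreeRegion

from oracles import brute_multiplex, brute_rank

TSS = 2000
GENE = GeneModel("target", "chr1", "+", TSS, TSS + 900, TSS)
PROMOTER = PromoterRegion("chr1", TSS - 900, TSS + 100, [GENE], False,
                          {"target": TSS})


def site_at_center(center, strand="+", chrom="chr1"):
    start = center - 9  # 20-mer floor midpoint start+9
    return ProtospacerSite(chrom, strand, "A" * 20, start, start + 20,
                           "TGG", start + 20, start + 23)


def nfr(start, end, chrom="chr1"):
    return NucleosomeFreeRegion(chrom, start, end,
                                DyadCall(chrom, start - 75, 1.0, 1.0),
                                DyadCall(chrom, end + 75, 1.0, 1.0))


def unique_report(site):
    return OffTargetReport(site, [0, 0, 0, 0])


class TestScoreGuide:
    def test_ideal_guide_scores_full_components(self):
        site = site_at_center(TSS - 100)
        score = score_guide(site, PROMOTER, GENE, [nfr(TSS - 200, TSS - 50)],
                            unique_report(site))
        assert score.nfr_component == 1.0
        assert score.distance_component == 1.0
        assert not score.crispri_flag
        assert score.tss_distance == 100
        assert score.total == pytest.approx(1.0)

    def test_spacer_overlapping_tss_is_zeroed(self):
        site = site_at_center(TSS - 5)
        score = score_guide(site, PROMOTER, GENE, [], unique_report(site))
        assert score.crispri_flag and score.total == 0.0

    def test_spacer_outside_all_nfrs(self):
        site = site_at_center(TSS - 100)
        score = score_guide(site, PROMOTER, GENE, [nfr(TSS - 700, TSS - 600)],
                            unique_report(site))
        assert score.nfr_component == 0.0

    def test_partial_nfr_overlap_is_fractional(self):
        site = site_at_center(TSS - 100)  # spacer [1891, 1911)
        score = score_guide(site, PROMOTER, GENE, [nfr(1901, 1950)],
                            unique_report(site))
        assert score.nfr_component == pytest.approx(0.5)

    def test_site_outside_promoter_rejected(self):
        site = site_at_center(TSS - 2000 + 100)
        with pytest.raises(RankingError):
            score_guide(site, PROMOTER, GENE, [], unique_report(site))

    def test_offtarget_burden_monotonicity(self):
        site = site_at_center(TSS - 100)
        cfg = RankingConfig()
        scores = []
        for counts in ([0, 0, 0, 0], [0, 1, 0, 0], [1, 1, 0, 0], [1, 1, 9, 9]):
            rep = OffTargetReport(site, counts)
            scores.append(score_guide(site, PROMOTER, GENE, [], rep, cfg)
                          .offtarget_component)
        assert scores == sorted(scores, reverse=True)

    def test_window_widening_never_lowers_distance_component(self):
        for d in range(-50, 400, 7):
            narrow = distance_component(d, RankingConfig(window_max=180))
            wide = distance_component(d, RankingConfig(window_max=260))
            assert wide >= narrow - 1e-12


class TestDistanceComponent:
    def test_plateau_bounds_are_the_window(self):
        cfg = RankingConfig()
        assert distance_component(42, cfg) == 1.0
        assert distance_component(210, cfg) == 1.0
        assert distance_component(41, cfg) < 1.0
        assert distance_component(211, cfg) < 1.0

    def test_linear_taper_reaches_zero_after_one_window_width(self):
        cfg = RankingConfig()
        width = cfg.window_max - cfg.window_min
        assert distance_component(cfg.window_max + width, cfg) == 0.0
        assert distance_component(cfg.window_max + width // 2, cfg) == \
            pytest.approx(1 - (width // 2) / width)


class TestRankGuides:
    def _scores(self, rng, n=12):
        out = []
        for i in range(n):
            center = TSS - int(rng.integers(45, 700))
            site = site_at_center(center, strand=rng.choice(["+", "-"]))
            rep = OffTargetReport(site, [int(rng.integers(0, 2)), 0, 0, 0])
            nfrs = [nfr(TSS - 400, TSS - 150)] if rng.random() < 0.7 else []
            out.append(score_guide(site, PROMOTER, GENE, nfrs, rep))
        return out

    def test_descending_with_tie_breaks(self):
        a = site_at_center(TSS - 100)
        b = site_at_center(TSS - 150)
        full_nfr = [nfr(TSS - 400, TSS - 50)]
        sa = score_guide(a, PROMOTER, GENE, full_nfr, unique_report(a))
        sb = score_guide(b, PROMOTER, GENE, full_nfr, unique_report(b))
        assert sa.total == sb.total
        assert rank_guides([sb, sa])[0] is sa  # smaller distance wins ties

    def test_matches_selection_sort_oracle(self, rng):
        for _ in range(20):
            scores = self._scores(rng)
            assert rank_guides(scores) == brute_rank(scores)

    def test_byte_identical_across_runs(self, rng):
        scores = self._scores(rng)
        first = [(g.site.spacer_start, g.total) for g in rank_guides(scores)]
        second = [(g.site.spacer_start, g.total) for g in rank_guides(list(scores))]
        assert first == second


class TestAssignBidirectional:
    LEFT = GeneModel("gl", "chr1", "-", 1000, 2001, 2000)
    RIGHT = GeneModel("gr", "chr1", "+", 2305, 3300, 2305)
    REGION = PromoterRegion("chr1", 2000, 2305, [LEFT, RIGHT], True,
                            {"gl": 2000, "gr": 2305})
    NFRS = [nfr(2050, 2260)]

    def test_both_genes_scored_and_primary_labelled(self):
        site = site_at_center(2100)
        result = assign_bidirectional(site, self.REGION, self.NFRS,
                                      unique_report(site))
        s_left, s_right = result.scores
        assert s_left.target_gene == "gl" and s_right.target_gene == "gr"
        assert s_left.tss_distance == 100 and s_right.tss_distance == 205
        assert result.primary == "gl"  # equal totals; smaller distance wins

    def test_crispri_zeroes_one_gene_only(self):
        site = site_at_center(2025)  # within 30 bp of left TSS only
        result = assign_bidirectional(site, self.REGION, self.NFRS,
                                      unique_report(site))
        s_left, s_right = result.scores
        assert s_left.crispri_flag and s_left.total == 0.0
        assert not s_right.crispri_flag and s_right.total > 0.0

    def test_non_bidirectional_promoter_rejected(self):
        site = site_at_center(TSS - 100)
        with pytest.raises(RankingError):
            assign_bidirectional(site, PROMOTER, [], unique_report(site))

    def test_equidistant_tie_goes_to_leftmost_gene(self):
        left = GeneModel("gl", "chr1", "-", 1000, 2001, 2000)
        right = GeneModel("gr", "chr1", "+", 2300, 3300, 2300)
        region = PromoterRegion("chr1", 2000, 2300, [left, right], True)
        site = site_at_center(2150)
        result = assign_bidirectional(site, region, [nfr(2050, 2250)],
                                      unique_report(site))
        assert result.primary == "gl"


class TestSelectMultiplex:
    def _ranked(self, centers, rng=None):
        full_nfr = [nfr(TSS - 800, TSS - 40)]
        scores = []
        for c in centers:
            site = site_at_center(c)
            scores.append(score_guide(site, PROMOTER, GENE, full_nfr,
                                      unique_report(site)))
        return rank_guides(scores)

    def test_k1_returns_top_guide_with_warning(self):
        ranked = self._ranked([TSS - 100, TSS - 200])
        with pytest.warns(UserWarning, match="k=1"):
            chosen = select_multiplex(ranked, 1)
        assert chosen.guides == [ranked[0]]

    def test_four_spaced_candidates_all_selected(self):
        ranked = self._ranked([TSS - 60, TSS - 110, TSS - 160, TSS - 210])
        chosen = select_multiplex(ranked, 4, min_spacing=30)
        assert len(chosen.guides) == 4
        assert chosen.combined == pytest.approx(sum(g.total for g in ranked))

    def test_crowded_candidates_warn_when_short(self):
        ranked = self._ranked([TSS - 100, TSS - 110, TSS - 120])
        with pytest.warns(UserWarning, match="spacing"):
            chosen = select_multiplex(ranked, 3, min_spacing=50)
        assert len(chosen.guides) < 3

    def test_matches_exhaustive_subset_oracle(self, rng):
        for _ in range(20):
            centers = sorted(set(TSS - int(x)
                                 for x in rng.integers(45, 500, size=6)))
            ranked = self._ranked(centers)
            k = int(rng.integers(1, 5))
            spacing = int(rng.integers(10, 120))
            with pytest.warns(UserWarning) if k == 1 else _nullcontext():
                chosen = select_multiplex(ranked, k, spacing)
            oracle = brute_multiplex(ranked, k, spacing)
            assert [g.site.spacer_start for g in chosen.guides] == \
                [g.site.spacer_start for g in oracle]

    def test_emitted_set_satisfies_pairwise_spacing(self, rng):
        import itertools
        for _ in range(20):
            centers = sorted(set(TSS - int(x)
                                 for x in rng.integers(45, 800, size=8)))
            ranked = self._ranked(centers)
            chosen = select_multiplex(ranked, 4, min_spacing=60)
            for a, b in itertools.combinations(chosen.guides, 2):
                assert abs(a.site.center() - b.site.center()) >= 60


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
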