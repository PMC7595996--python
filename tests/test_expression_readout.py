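"""Livak 2^-ddCt computation, efficiency filtering, significance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucleoguide.expression_readout import (QpcrMeasurement, ReadoutError,
                                            fold_change, fold_change_table,
                                            significance, validate_efficiency)
from nucleoguide.synthetic_data import simulate_qpcr


def ct_table(rows):
    """rows: (sample, gene, ct) expanded into duplicate technical reps."""
    data = []
    for sample, gene, ct in rows:
        for rep in (1, 2):
            data.append({"sample_id": sample, "gene_id": gene,
                         "replicate": rep, "ct": ct, "efficiency": 100.0})
    return pd.DataFrame(data)


class TestValidateEfficiency:
    @pytest.mark.parametrize("eff,ok", [
        (100.0, True), (85.0, False), (110.0, True), (90.0, True),
        (89.99, False), (110.01, False)])
    def test_inclusive_window(self, eff, ok):
        assert validate_efficiency(eff) is ok

    def test_measurement_object_accepted(self):
        m = QpcrMeasurement("s", "g", [22.0, 22.1], 95.0)
        assert validate_efficiency(m)


class TestFoldChange:
    REFS = ("actA", "benA")

    def _table(self, treated_target_ct):
        rows = []
        for sample, tct in (("cal_1", 28.0), ("cal_2", 28.0),
                            ("tr_1", treated_target_ct), ("tr_2", treated_target_ct)):
            rows += [(sample, "mdpE", tct), (sample, "actA", 22.0),
                     (sample, "benA", 23.0)]
        return ct_table(rows)

    def test_identical_groups_give_fold_one(self):
        r = fold_change(self._table(28.0), "mdpE", self.REFS,
                        ["cal_1", "cal_2"], ["tr_1", "tr_2"])
        assert r.folds == [1.0, 1.0] and r.mean_fold == 1.0

    def test_ddct_minus_two_gives_fold_four(self):
        r = fold_change(self._table(26.0), "mdpE", self.REFS,
                        ["cal_1", "cal_2"], ["tr_1", "tr_2"])
        assert r.delta_delta_ct == [-2.0, -2.0]
        assert r.folds == [4.0, 4.0]

    def test_two_sample_two_reference_toy_table_matches_hand_computation(self):
        # Hand-worked Livak arithmetic:
        # calibrator: target 30.0, refs 24.0/26.0 -> ref mean 25.0, dCt 5.0
        # treated:    target 27.5, refs 24.5/25.5 -> ref mean 25.0, dCt 2.5
        # ddCt = -2.5 -> fold = 2^2.5 = 5.65685...
        rows = [("cal_1", "t", 30.0), ("cal_1", "r1", 24.0), ("cal_1", "r2", 26.0),
                ("cal_2", "t", 30.0), ("cal_2", "r1", 24.0), ("cal_2", "r2", 26.0),
                ("tr_1", "t", 27.5), ("tr_1", "r1", 24.5), ("tr_1", "r2", 25.5),
                ("tr_2", "t", 27.5), ("tr_2", "r1", 24.5), ("tr_2", "r2", 25.5)]
        r = fold_change(ct_table(rows), "t", ("r1", "r2"),
                        ["cal_1", "cal_2"], ["tr_1", "tr_2"])
        assert r.folds == pytest.approx([2 ** 2.5] * 2)

    def test_scale_invariance_under_global_ct_shift(self):
        base = self._table(26.0)
        shifted = base.copy()
        shifted["ct"] = shifted["ct"] + 3.25
        r0 = fold_change(base, "mdpE", self.REFS, ["cal_1", "cal_2"],
                         ["tr_1", "tr_2"])
        r1 = fold_change(shifted, "mdpE", self.REFS, ["cal_1", "cal_2"],
                         ["tr_1", "tr_2"])
        assert r0.folds == r1.folds

    def test_failing_primer_efficiency_excludes_gene(self):
        df = self._table(26.0)
        df.loc[df["gene_id"] == "mdpE", "efficiency"] = 85.0
        with pytest.raises(ReadoutError, match="excluded"):
            fold_change(df, "mdpE", self.REFS, ["cal_1", "cal_2"],
                        ["tr_1", "tr_2"])

    def test_missing_reference_sample_is_an_error(self):
        df = self._table(26.0)
        df = df[~((df["sample_id"] == "tr_1") & (df["gene_id"] == "actA"))]
        with pytest.raises(ReadoutError, match="missing Ct"):
            fold_change(df, "mdpE", self.REFS, ["cal_1", "cal_2"],
                        ["tr_1", "tr_2"])

    def test_separate_reference_reporting(self):
        r = fold_change(self._table(26.0), "mdpE", self.REFS,
                        ["cal_1", "cal_2"], ["tr_1", "tr_2"],
                        combine_refs="separate")
        assert set(r) == {"actA", "benA"}
        assert r["actA"].folds == [4.0, 4.0]

    def test_planted_fold_recovered_exactly_without_noise(self):
        for fold in (1.0, 30.0):
            df = simulate_qpcr(true_fold=fold, n_bio=3, ct_noise_sd=0.0, seed=5)
            r = fold_change(df, "mdpE", self.REFS,
                            [f"control_{i}" for i in (1, 2, 3)],
                            [f"treated_{i}" for i in (1, 2, 3)])
            assert r.mean_fold == pytest.approx(fold, rel=1e-12)

    def test_noisy_planted_fold_recovered_within_tolerance(self):
        df = simulate_qpcr(true_fold=30.0, n_bio=6, ct_noise_sd=0.2, seed=11)
        r = fold_change(df, "mdpE", self.REFS,
                        [f"control_{i}" for i in range(1, 7)],
                        [f"treated_{i}" for i in range(1, 7)])
        assert abs(r.mean_fold - 30.0) / 30.0 < 0.2


class TestSignificance:
    def test_identical_degenerate_groups_return_p_one(self):
        assert significance([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_matches_t_distribution_tail(self):
        a, b = [1.0, 1.0, 1.0], [4.0, 4.1, 3.9]
        t, p = significance(b, a)
        # closed form: pooled-variance t with n1+n2-2 df
        na, nb = 3, 3
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        t_manual = (np.mean(b) - np.mean(a)) / (sp * math.sqrt(1 / na + 1 / nb))
        p_manual = 2 * stats.t.sf(abs(t_manual), na + nb - 2)
        assert t == pytest.approx(t_manual)
        assert p == pytest.approx(p_manual)

    def test_single_value_group_rejected(self):
        with pytest.raises(ReadoutError):
            significance([1.0], [2.0, 3.0])

    def test_stars_thresholds(self):
        rows = []
        for s, tct in (("cal_1", 28.0), ("cal_2", 28.01), ("cal_3", 27.99),
                       ("tr_1", 23.0), ("tr_2", 23.02), ("tr_3", 22.98)):
            rows += [(s, "t", tct), (s, "actA", 22.0), (s, "benA", 23.0)]
        r = fold_change(ct_table(rows), "t", ("actA", "benA"),
                        ["cal_1", "cal_2", "cal_3"], ["tr_1", "tr_2", "tr_3"])
        assert r.p_value < 0.01 and r.stars == "**"


class TestFoldChangeTable:
    def test_summary_contains_significance_column(self):
        df = simulate_qpcr(true_fold=8.0, n_bio=4, ct_noise_sd=0.05, seed=2)
        table = fold_change_table(df, ["mdpE"], ("actA", "benA"),
                                  [f"control_{i}" for i in range(1, 5)],
                                  [f"treated_{i}" for i in range(1, 5)])
        assert list(table["gene_id"]) == ["mdpE"]
        assert table.loc[0, "mean_fold"] == pytest.approx(8.0, rel=0.2)
        assert table.loc[0, "significance"] in {"*", "**"}
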