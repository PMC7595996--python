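"""Relative expression by the 2^-ddCt (Livak) method.

Quantifies activation of a target gene from qPCR cycle-threshold (Ct)
tables: technical replicates are averaged first, each sample's target Ct
is normalised against reference (housekeeping) genes — by default the
arithmetic mean of the per-reference-gene mean Cts, the fungal standards
being actA and benA — and treated samples are compared against a
calibrator group:

    dCt   = Ct_target − Ct_ref            (per sample)
    ddCt  = dCt_treated − mean dCt_calibrator
    fold  = 2^(−ddCt)                     (per biological replicate)

Primer pairs outside the accepted efficiency window (90–110 %,
inclusive) are excluded up front. Group significance uses a two-sided
equal-variance Student's t test, annotated * p<0.05 / ** p<0.01.

Input is a long-format table with columns
sample_id, gene_id, replicate, ct, efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("sample_id", "gene_id", "replicate", "ct", "efficiency")


class ReadoutError(ValueError):
    pass


@dataclass
class QpcrMeasurement:
    """Technical-replicate Cts for one gene in one sample."""

    sample_id: str
    gene_id: str
    cts: list[float]
    primer_efficiency: float  # percent

    def __post_init__(self) -> None:
        if not self.cts:
            raise ReadoutError("at least one technical replicate is required")
        if any(not (0 < c < 45) for c in self.cts):
            raise ReadoutError(f"Ct outside (0, 45) for {self.sample_id}/{self.gene_id}")

    def mean_ct(self) -> float:
        return float(np.mean(self.cts))


@dataclass
class FoldChangeResult:
    target: str
    references: tuple[str, ...]
    calibrator_samples: list[str]
    treated_samples: list[str]
    delta_ct_calibrator: list[float]
    delta_ct_treated: list[float]
    delta_delta_ct: list[float]       # per treated biological replicate
    folds: list[float]                # 2^-ddCt per treated replicate
    mean_fold: float = field(init=False)
    fold_of_mean_ddct: float = field(init=False)
    t_statistic: float = float("nan")
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        self.mean_fold = float(np.mean(self.folds))
        self.fold_of_mean_ddct = float(2.0 ** (-np.mean(self.delta_delta_ct)))

    @property
    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def validate_efficiency(measurement: QpcrMeasurement | float,
                        low: float = 90.0, high: float = 110.0) -> bool:
    """True iff the primer efficiency lies in [low, high] percent (inclusive)."""
    eff = measurement.primer_efficiency if isinstance(measurement, QpcrMeasurement) \
        else float(measurement)
    return low <= eff <= high


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct TSV and check its schema."""
    df = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ReadoutError(f"Ct table lacks columns: {sorted(missing)}")
    return df


def _mean_cts(df: pd.DataFrame, low: float, high: float) -> pd.DataFrame:
    """Average technical replicates per (sample, gene); drop failing primers."""
    eff = df.groupby("gene_id")["efficiency"].mean()
    failing = [g for g, e in eff.items() if not validate_efficiency(float(e), low, high)]
    kept = df[~df["gene_id"].isin(failing)]
    means = kept.groupby(["sample_id", "gene_id"], as_index=False)["ct"].mean()
    means.attrs["excluded_genes"] = failing
    return means


def _delta_ct(means: pd.DataFrame, target: str, refs: tuple[str, ...],
              samples: list[str]) -> list[float]:
    out = []
    table = means.set_index(["sample_id", "gene_id"])["ct"]
    for s in samples:
        try:
            ct_t = table[(s, target)]
            ref_ct = float(np.mean([table[(s, r)] for r in refs]))
        except KeyError as exc:
            raise ReadoutError(f"missing Ct for sample {s!r}: {exc}") from exc
        out.append(float(ct_t) - ref_ct)
    return out


def fold_change(df: pd.DataFrame, target: str, refs: tuple[str, ...] | list[str],
                calibrator_samples: list[str], treated_samples: list[str],
                efficiency_bounds: tuple[float, float] = (90.0, 110.0),
                combine_refs: str = "mean") -> FoldChangeResult | dict:
    """Livak 2^-ddCt fold change of `target` in treated vs calibrator samples.

    `combine_refs="mean"` (default) averages the per-reference-gene mean
    Cts into one reference Ct; `combine_refs="separate"` returns a dict
    of one FoldChangeResult per reference gene.

    Significance compares the treated per-replicate folds against the
    calibrator per-replicate folds (each calibrator replicate's fold is
    taken relative to the calibrator group mean dCt).
    """
    refs = tuple(refs)
    if combine_refs == "separate":
        return {r: fold_change(df, target, (r,), calibrator_samples,
                               treated_samples, efficiency_bounds, "mean")
                for r in refs}
    low, high = efficiency_bounds
    means = _mean_cts(df, low, high)
    present = set(means["gene_id"])
    for gene in (target, *refs):
        if gene not in present:
            raise ReadoutError(
                f"gene {gene!r} absent after efficiency filtering "
                f"(excluded: {means.attrs['excluded_genes']})")
    dct_cal = _delta_ct(means, target, refs, calibrator_samples)
    dct_tre = _delta_ct(means, target, refs, treated_samples)
    baseline = float(np.mean(dct_cal))
    ddct = [d - baseline for d in dct_tre]
    folds = [float(2.0 ** (-d)) for d in ddct]
    result = FoldChangeResult(target, refs, list(calibrator_samples),
                              list(treated_samples), dct_cal, dct_tre,
                              ddct, folds)
    cal_folds = [float(2.0 ** (-(d - baseline))) for d in dct_cal]
    if len(cal_folds) >= 2 and len(folds) >= 2:
        result.t_statistic, result.p_value = significance(folds, cal_folds)
    return result


def significance(folds_a: list[float], folds_b: list[float]
                 ) -> tuple[float, float]:
    """Two-sided, equal-variance two-sample Student's t test.

    Groups of fewer than two values are an error; two degenerate groups
    with zero variance and equal means return (0, 1) by convention.
    """
    a, b = np.asarray(folds_a, float), np.asarray(folds_b, float)
    if a.size < 2 or b.size < 2:
        raise ReadoutError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    with warnings.catch_warnings():
        # near-constant groups trigger a precision warning; the degenerate
        # equal-mean case is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def fold_change_table(df: pd.DataFrame, targets: list[str],
                      refs: tuple[str, ...] | list[str],
                      calibrator_samples: list[str],
                      treated_samples: list[str]) -> pd.DataFrame:
    """Per-gene fold-change summary with significance stars."""
    rows = []
    for target in targets:
        r = fold_change(df, target, refs, calibrator_samples, treated_samples)
        rows.append({
            "gene_id": target,
            "mean_fold": r.mean_fold,
            "fold_of_mean_ddct": r.fold_of_mean_ddct,
            "n_treated": len(r.folds),
            "t_statistic": r.t_statistic,
            "p_value": r.p_value,
            "significance": r.stars,
        })
    return pd.DataFrame(rows)
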