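"""Rater-vs-rater agreement statistics over a measurement table.

Statistics mirror the benchmark comparison of two human readers and the
automated reader over 22 cases (44 ventricles): per-side and pooled mean
absolute differences, squared Pearson correlation, a paired two-sided
Student t-test over the pooled ventricles, the count of differences under an
error threshold (1.7 mm by default), per-rater summary mean/SD, and
classification tallies under the >10 mm rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .classify import VM_THRESHOLD_MM, classify_case
from .core_io import MeasurementTable

EPSILON_MM = 1.7


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (the tables' convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_arrays(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"width lists must be equal-length 1D, got {a.shape} vs {b.shape}")
    return a, b


def mean_abs_diff(a, b) -> float:
    """Mean absolute difference, full precision."""
    a, b = _as_arrays(a, b)
    if len(a) < 1:
        raise ValueError("need at least one pair")
    return float(np.mean(np.abs(a - b)))


def pearson_r2(a, b) -> float:
    """Squared Pearson product-moment correlation."""
    a, b = _as_arrays(a, b)
    if len(a) < 3:
        raise ValueError("need at least three pairs for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def paired_t_test(a, b) -> tuple[float, float, int]:
    """Two-sided paired Student t-test; returns (t, p, df)."""
    a, b = _as_arrays(a, b)
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0, n - 1
        raise ValueError("zero-variance differences: paired t-test is degenerate")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), n - 1


def sample_sd(x) -> float:
    """Sample standard deviation (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least two values")
    return float(np.std(x, ddof=1))


def threshold_agreement(a, b, epsilon_mm: float = EPSILON_MM) -> tuple[int, int]:
    """(count of |a_i - b_i| strictly below epsilon, total pairs)."""
    a, b = _as_arrays(a, b)
    d = np.abs(a - b)
    return int(np.sum(d < epsilon_mm)), len(d)


def classification_counts(table: MeasurementTable, rater: str,
                          vm_threshold_mm: float = VM_THRESHOLD_MM) -> tuple[int, int]:
    """(n_normal, n_abnormal) for one rater's columns under the width rule."""
    right = table.widths(rater, "right")
    left = table.widths(rater, "left")
    labels = [classify_case(r, l, vm_threshold_mm=vm_threshold_mm).case_label
              for r, l in zip(right, left)]
    n_abn = sum(1 for lab in labels if lab == "ventriculomegaly")
    return len(labels) - n_abn, n_abn


@dataclass
class PairAgreement:
    """All agreement statistics for one rater pair."""

    rater_a: str
    rater_b: str
    mad_right_mm: float
    mad_left_mm: float
    mad_pooled_mm: float
    r2_right: float
    r2_left: float
    t_stat: float
    p_two_sided: float
    df: int
    within_threshold: int
    total: int
    epsilon_mm: float
    case_diffs: pd.DataFrame  # per-case |right diff|, |left diff|


@dataclass
class AgreementReport:
    """Per-pair agreement plus per-rater summaries for a measurement table."""

    pairs: list[PairAgreement]
    rater_summary: pd.DataFrame  # per rater/side: mean, sample SD, n
    classification: dict[str, tuple[int, int]] = field(default_factory=dict)
    epsilon_mm: float = EPSILON_MM

    def pair(self, a: str, b: str) -> PairAgreement:
        for p in self.pairs:
            if {p.rater_a, p.rater_b} == {a, b}:
                return p
        raise KeyError(f"no pair ({a}, {b}) in report")

    def to_frame(self) -> pd.DataFrame:
        """One row per pair, display-rounded to 2 decimals (half-up)."""
        rows = []
        for p in self.pairs:
            rows.append({
                "rater_a": p.rater_a, "rater_b": p.rater_b,
                "mad_right_mm": round_half_up(p.mad_right_mm),
                "mad_left_mm": round_half_up(p.mad_left_mm),
                "mad_pooled_mm": round_half_up(p.mad_pooled_mm),
                "r2_right": round_half_up(p.r2_right, 4),
                "r2_left": round_half_up(p.r2_left, 4),
                "t_stat": round_half_up(p.t_stat, 4),
                "p_two_sided": round_half_up(p.p_two_sided, 4),
                "df": p.df,
                "within_threshold": p.within_threshold, "total": p.total,
            })
        return pd.DataFrame(rows)


def build_report(table: MeasurementTable,
                 pairs: list[tuple[str, str]] | None = None,
                 epsilon_mm: float = EPSILON_MM) -> AgreementReport:
    """Assemble the full agreement report for the requested rater pairs.

    ``pairs`` defaults to all unordered rater pairs in table order.
    """
    raters = table.raters
    if pairs is None:
        pairs = [(raters[i], raters[j])
                 for i in range(len(raters)) for j in range(i + 1, len(raters))]
    for a, b in pairs:
        for r in (a, b):
            if r not in raters:
                raise KeyError(f"unknown rater {r!r}; table has {raters}")

    out = []
    for a, b in pairs:
        ar, al = table.widths(a, "right"), table.widths(a, "left")
        br, bl = table.widths(b, "right"), table.widths(b, "left")
        pooled_a, pooled_b = table.pooled_widths(a), table.pooled_widths(b)
        t, p, df = paired_t_test(pooled_a, pooled_b)
        within, total = threshold_agreement(pooled_a, pooled_b, epsilon_mm)
        diffs = pd.DataFrame({
            "case_id": table.frame["case_id"],
            "right_abs_diff_mm": np.abs(ar - br),
            "left_abs_diff_mm": np.abs(al - bl),
        })
        out.append(PairAgreement(
            rater_a=a, rater_b=b,
            mad_right_mm=mean_abs_diff(ar, br),
            mad_left_mm=mean_abs_diff(al, bl),
            mad_pooled_mm=mean_abs_diff(pooled_a, pooled_b),
            r2_right=pearson_r2(ar, br), r2_left=pearson_r2(al, bl),
            t_stat=t, p_two_sided=p, df=df,
            within_threshold=within, total=total, epsilon_mm=epsilon_mm,
            case_diffs=diffs))

    summary_rows = []
    for r in raters:
        for side in ("right", "left"):
            w = table.widths(r, side)
            summary_rows.append({"rater": r, "side": side, "n": len(w),
                                 "mean_mm": float(np.mean(w)),
                                 "sd_mm": sample_sd(w)})
    classification = {r: classification_counts(table, r) for r in raters}
    return AgreementReport(pairs=out, rater_summary=pd.DataFrame(summary_rows),
                           classification=classification, epsilon_mm=epsilon_mm)


__all__ = ["EPSILON_MM", "round_half_up", "mean_abs_diff", "pearson_r2",
           "paired_t_test", "sample_sd", "threshold_agreement",
           "classification_counts", "PairAgreement", "AgreementReport",
           "build_report"]
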