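"""Small genetics statistics: segregation ratios and qPCR fold changes."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from scipy import stats as sp_stats

from .errors import ValidationError


@dataclass(frozen=True)
class SegregationResult:
    n_class_a: int
    n_class_b: int
    ratio: float          # half-up rounded to 2 decimals, as reported
    ratio_raw: float
    expected_ratio: tuple[int, int]
    chi2: float
    df: int
    p_value: float


def segregation_ratio(n_a: int, n_b: int, ndigits: int = 2) -> float:
    """Phenotype ratio a/b rounded half-up, e.g. 883:296 -> 2.98."""
    if n_b == 0:
        raise ZeroDivisionError("class-b count is zero; ratio undefined")
    quantum = Decimal(1).scaleb(-ndigits)
    return float((Decimal(n_a) / Decimal(n_b)).quantize(quantum, rounding=ROUND_HALF_UP))


def chi_square_gof(
    observed: Sequence[int], expected_ratio: Sequence[float] = (3, 1)
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of observed counts against an expected ratio.

    Returns (chi2, df, p) with df = classes - 1.  No continuity correction by
    default (counts here are in the hundreds); pass pre-corrected counts if
    one is wanted.
    """
    if len(observed) != len(expected_ratio):
        raise ValidationError("observed and expected_ratio lengths differ")
    if any(o < 0 for o in observed):
        raise ValidationError("negative observed counts")
    total = sum(observed)
    if total <= 0:
        raise ValidationError("total observed count must be positive")
    weight = sum(expected_ratio)
    expected = [total * w / weight for w in expected_ratio]
    chi2, p = sp_stats.chisquare(observed, f_exp=expected)
    return float(chi2), len(observed) - 1, float(p)


def segregation_analysis(
    n_a: int, n_b: int, expected_ratio: tuple[int, int] = (3, 1)
) -> SegregationResult:
    """Ratio plus chi-square goodness of fit against a Mendelian expectation."""
    chi2, df, p = chi_square_gof([n_a, n_b], expected_ratio)
    return SegregationResult(
        n_class_a=n_a,
        n_class_b=n_b,
        ratio=segregation_ratio(n_a, n_b),
        ratio_raw=n_a / n_b,
        expected_ratio=expected_ratio,
        chi2=chi2,
        df=df,
        p_value=p,
    )


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^(-ddCt) method.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator.
    """
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)
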