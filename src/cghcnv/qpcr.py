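"""qPCR standard-curve fitting, relative copy number, and genotype classing.

Quantification follows the standard-curve method: a serial dilution of one
reference DNA sample (the published series is 2.5, 5, 10, 20, 40, 80 ng/ul,
each in triplicate) yields a fitted line of mean Ct versus log10(input
quantity). For perfect amplification efficiency the slope is
-1/log10(2) = -3.3219 cycles per decade, and in general

    efficiency = 10^(-1/slope) - 1.

A sample Ct converts to a quantity via the curve, and the relative copy
number is that quantity divided by the quantity of the reference unit (by
default the curve's value at 1 ng of reference DNA, taken as one unit).
Duplication genotypes are classed against the 1x / 1.5x / 2x fold anchors of
a heterozygous-vs-homozygous duplication, with decision bounds at the
midpoints (1.25 and 1.75).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "StandardCurve",
    "CopyNumberEstimate",
    "GENOTYPE_BOUNDS",
    "fit_standard_curve",
    "estimate_copy_number",
    "classify_genotype",
]

#: genotype class bounds in fold units: (0, 1.25) baseline, [1.25, 1.75)
#: one-and-a-half-fold, [1.75, inf) two-fold.
GENOTYPE_BOUNDS = (1.25, 1.75)


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # cycles per log10(quantity)
    intercept: float  # Ct at 1 ng (log10 q = 0)
    r_squared: float
    efficiency_estimate: float

    def ct_to_quantity(self, ct) -> np.ndarray:
        """Invert the curve: quantity (ng) = 10^((ct - intercept) / slope)."""
        return np.power(10.0, (np.asarray(ct, dtype=float) - self.intercept) / self.slope)

    def quantity_to_ct(self, quantity_ng) -> np.ndarray:
        return self.intercept + self.slope * np.log10(np.asarray(quantity_ng, dtype=float))


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    locus: str
    relative_cn: float
    replicate_cv: float

    def __post_init__(self):
        if self.relative_cn <= 0:
            raise ValueError("relative_cn must be > 0")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


def fit_standard_curve(ct_table: pd.DataFrame) -> StandardCurve:
    """OLS fit of mean Ct versus log10(quantity) over a dilution series.

    ``ct_table`` needs columns ``quantity_ng`` and ``ct`` (replicate rows are
    averaged per quantity before fitting). At least 3 distinct quantities are
    required; a non-negative slope (signal not decreasing with input) is an
    error, and an efficiency estimate outside (0, 1.2] draws a warning.
    """
    if (ct_table["quantity_ng"] <= 0).any():
        raise ValueError("standard quantities must be positive")
    means = ct_table.groupby("quantity_ng")["ct"].mean()
    if len(means) < 3:
        raise ValueError("need >= 3 distinct standard quantities")
    fit = linregress(np.log10(means.index.to_numpy(dtype=float)), means.to_numpy())
    if fit.slope >= 0:
        raise ValueError("standard curve slope is non-negative: no valid amplification")
    efficiency = float(10.0 ** (-1.0 / fit.slope) - 1.0)
    if not (0.0 < efficiency <= 1.2):
        warnings.warn(
            f"amplification efficiency estimate {efficiency:.3f} outside (0, 1.2]",
            stacklevel=2,
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency_estimate=efficiency,
    )


def estimate_copy_number(
    ct: float | np.ndarray | list,
    curve: StandardCurve,
    reference_ct_at_unit: float,
    sample_id: str = "",
    locus: str = "",
) -> CopyNumberEstimate:
    """Convert a sample's Ct (scalar or replicates) to relative copy number.

    ``reference_ct_at_unit`` is the Ct of the reference unit (typically the
    curve evaluated at the quantity that defines one copy unit). Replicates
    are aggregated as the mean Ct; the CV of the replicate-wise quantities is
    reported (no outlier rejection is performed).
    """
    cts = np.atleast_1d(np.asarray(ct, dtype=float))
    q = curve.ct_to_quantity(cts)
    q_ref = float(curve.ct_to_quantity(reference_ct_at_unit))
    mean_q = float(curve.ct_to_quantity(cts.mean()))
    cv = float(q.std(ddof=1) / q.mean()) if len(q) > 1 else 0.0
    return CopyNumberEstimate(
        sample_id=sample_id,
        locus=locus,
        relative_cn=mean_q / q_ref,
        replicate_cv=cv,
    )


def classify_genotype(relative_cn: float) -> str:
    """Class a fold estimate as baseline, one_and_half_fold, or two_fold.

    With the duplication's 1x / 1.5x / 2x anchors (wild type, heterozygous,
    homozygous duplication), the midpoint bounds are cn < 1.25 -> baseline,
    1.25 <= cn < 1.75 -> one_and_half_fold, cn >= 1.75 -> two_fold.
    """
    if relative_cn <= 0:
        raise ValueError("relative_cn must be > 0")
    lo, hi = GENOTYPE_BOUNDS
    if relative_cn < lo:
        return "baseline"
    if relative_cn < hi:
        return "one_and_half_fold"
    return "two_fold"
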