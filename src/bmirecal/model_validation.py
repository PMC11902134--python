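"""Back-transform validation of the fitted log-polynomial model.

Measured BMI is regressed on predicted BMI; an unbiased model yields a slope
of 1 and intercept of 0, checked by an F test on the single slope = 1
restriction, together with a paired t-test on the mean difference, Pearson
correlation, and a CUSUM check that the measured-predicted relation is linear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import FitError
from .model_building import cusum_linearity_test

__all__ = ["ValidationResult", "validate_predictions"]


@dataclass(frozen=True)
class ValidationResult:
    slope: float
    intercept: float
    slope_test_stat: float  # F statistic of the slope = 1 restriction
    slope_test_p: float
    paired_diff_mean: float
    paired_t_p: float
    pearson_r: float
    r_squared: float
    cusum_linear_ok: bool

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_test_stat": self.slope_test_stat,
            "slope_test_p": self.slope_test_p,
            "paired_diff_mean": self.paired_diff_mean,
            "paired_t_p": self.paired_t_p,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "cusum_linear_ok": self.cusum_linear_ok,
        }


def validate_predictions(
    bmi_measured: Sequence[float],
    bmi_predicted: Sequence[float],
    alpha: float = 0.05,
    seed: int | None = None,
    n_null_sims: int = 2000,
) -> ValidationResult:
    """Validate predicted BMI against measured BMI.

    OLS of measured on predicted; two-sided tests throughout. The CUSUM flag
    is True when linearity of the measured~predicted relation is *not*
    rejected at ``alpha``.
    """
    y = np.asarray(bmi_measured, dtype=float)
    x = np.asarray(bmi_predicted, dtype=float)
    if y.size != x.size:
        raise FitError("measured and predicted must have equal length")
    if y.size < 10:
        raise FitError(f"validation needs n >= 10, got {y.size}")
    if np.std(x) == 0.0:
        raise FitError("predictions have zero variance; slope undefined")

    design = sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    intercept, slope = res.params

    if np.allclose(y, x):
        # identity case: residual variance 0 makes the restriction test 0/0
        slope_f, slope_p = 0.0, 1.0
        paired_p = 1.0
    else:
        ftest = res.f_test((np.array([[0.0, 1.0]]), np.array([1.0])))
        slope_f, slope_p = float(ftest.fvalue), float(ftest.pvalue)
        paired_p = float(stats.ttest_rel(y, x).pvalue)
        if np.isnan(paired_p):  # zero-variance difference, no deviation
            paired_p = 1.0

    pearson_r = float(stats.pearsonr(y, x).statistic) if np.std(y) > 0 else 1.0 if np.allclose(y, x) else 0.0

    cusum = cusum_linearity_test(x, y, alpha=alpha, seed=seed, n_null_sims=n_null_sims)

    return ValidationResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_test_stat=slope_f,
        slope_test_p=slope_p,
        paired_diff_mean=float(np.mean(y - x)),
        paired_t_p=paired_p,
        pearson_r=pearson_r,
        r_squared=float(res.rsquared) if np.std(y) > 0 else 1.0,
        cusum_linear_ok=not cusum.reject_linearity,
    )
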