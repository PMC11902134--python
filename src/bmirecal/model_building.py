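"""Linearity testing and log-scale polynomial model building.

The BMI~BF% relation is tested for linearity with a residual-CUSUM test whose
critical value is obtained by a seeded Monte-Carlo permutation null, then
modelled by least squares on the natural-log scale, ln(BMI) = c0 + c1*BF% +
c2*BF%^2 + ..., with the polynomial degree chosen by adjusted R-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ExtrapolationWarning, FitError

__all__ = [
    "AdiposityModel",
    "CusumResult",
    "cusum_linearity_test",
    "fit_log_polynomial",
    "predict_bmi",
    "DEFAULT_EXTRAPOLATION_GUARD",
]

#: BF-percentage points beyond the fitted range for which predictions are
#: still allowed (with a warning); cut-off substitution at BF% = 26 commonly
#: exceeds the observed athlete range (a lean cohort's maximum BF% is often
#: below 24), so the guard must reach a few points past the sample maximum.
DEFAULT_EXTRAPOLATION_GUARD = 4.0


@dataclass(frozen=True)
class AdiposityModel:
    """Fitted log-polynomial ln(BMI) model with fit diagnostics."""

    coeffs: tuple[float, ...]
    degree: int
    r_squared: float
    resid_sd: float
    n_fit: int
    bf_range_fit: tuple[float, float]

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise FitError(f"degree must be in {{1, 2, 3}}, got {self.degree}")
        if len(self.coeffs) != self.degree + 1:
            raise FitError("coeffs length must equal degree + 1")
        if not (0.0 <= self.r_squared <= 1.0):
            raise FitError(f"r_squared outside [0, 1]: {self.r_squared}")
        if self.n_fit <= self.degree + 1:
            raise FitError(f"n_fit={self.n_fit} too small for degree {self.degree}")

    def polynomial(self, x: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the log-scale polynomial at BF% ``x``."""
        return np.polyval(self.coeffs[::-1], x)

    def to_dict(self) -> dict:
        return {
            "coeffs": list(self.coeffs),
            "degree": self.degree,
            "r_squared": self.r_squared,
            "resid_sd": self.resid_sd,
            "n_fit": self.n_fit,
            "bf_range_fit": list(self.bf_range_fit),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdiposityModel":
        return cls(
            coeffs=tuple(d["coeffs"]),
            degree=int(d["degree"]),
            r_squared=float(d["r_squared"]),
            resid_sd=float(d["resid_sd"]),
            n_fit=int(d["n_fit"]),
            bf_range_fit=(float(d["bf_range_fit"][0]), float(d["bf_range_fit"][1])),
        )


@dataclass(frozen=True)
class CusumResult:
    """Outcome of the residual-CUSUM linearity test."""

    statistic: float
    threshold: float
    alpha: float
    reject_linearity: bool
    n: int
    n_null_sims: int
    seed: int | None
    p_value: float

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "threshold": self.threshold,
            "alpha": self.alpha,
            "reject_linearity": self.reject_linearity,
            "n": self.n,
            "n_null_sims": self.n_null_sims,
            "seed": self.seed,
            "p_value": self.p_value,
        }


def _cusum_stat(resid_ordered: np.ndarray, resid_sd: float | np.ndarray) -> float | np.ndarray:
    n = resid_ordered.shape[-1]
    scale = np.asarray(resid_sd) * np.sqrt(n)
    path = np.cumsum(resid_ordered, axis=-1) / scale[..., None] if scale.ndim else np.cumsum(resid_ordered, axis=-1) / scale
    out = np.max(np.abs(path), axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def cusum_linearity_test(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    seed: int | None = None,
    n_null_sims: int = 2000,
) -> CusumResult:
    """Residual-CUSUM test of linearity of ``y`` against ``x``.

    Fits the straight line y ~ x, orders the residuals by ascending x and
    takes the maximum absolute standardized cumulative sum as the statistic.
    The critical value is the (1 - alpha) quantile of the statistic under a
    seeded Monte-Carlo null: residuals are permuted, the line is refitted to
    the permuted pseudo-response and the statistic recomputed, so the null
    respects the least-squares constraints (refit residuals equal the
    annihilator projection of the permuted residuals). Systematic curvature
    makes same-signed residuals cluster along the x axis, inflating the
    cumulative sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 20:
        raise FitError(f"CUSUM test needs n >= 20, got {n}")
    if y.size != n:
        raise FitError("x and y must have equal length")
    if np.unique(x).size < 5:
        raise FitError("x must take at least 5 distinct values")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)  # already in ascending-x order
    resid_sd = float(np.std(resid))

    # residuals at float round-off for an exactly linear response count as zero
    if resid_sd <= 1e-12 * max(1.0, float(np.std(ys))):
        return CusumResult(
            statistic=0.0,
            threshold=np.inf,
            alpha=alpha,
            reject_linearity=False,
            n=n,
            n_null_sims=n_null_sims,
            seed=seed,
            p_value=1.0,
        )

    statistic = float(_cusum_stat(resid, resid_sd))

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(resid, (n_null_sims, 1)), axis=1)
    # refit under the null: residuals of y* = fit + perm are M @ perm with
    # M the OLS annihilator of [1, x]
    design = np.column_stack([np.ones(n), xs])
    q, _ = np.linalg.qr(design)
    null_resid = perms - (perms @ q) @ q.T
    null_sd = null_resid.std(axis=1)
    null_sd[null_sd == 0.0] = np.inf
    null_stats = _cusum_stat(null_resid, null_sd)
    threshold = float(np.quantile(null_stats, 1.0 - alpha))
    p_value = float((np.sum(null_stats >= statistic) + 1) / (n_null_sims + 1))

    return CusumResult(
        statistic=statistic,
        threshold=threshold,
        alpha=alpha,
        reject_linearity=statistic > threshold,
        n=n,
        n_null_sims=n_null_sims,
        seed=seed,
        p_value=p_value,
    )


def fit_log_polynomial(
    bf_pct: Sequence[float],
    bmi: Sequence[float],
    max_degree: int = 3,
) -> AdiposityModel:
    """Regress ln(BMI) on polynomial terms of BF% and select the degree.

    Degrees 1..max_degree are fitted by least squares; the returned model is
    the one with the highest adjusted R-squared (plain R-squared would always
    prefer the largest degree), while plain R-squared is what is reported.
    """
    x = np.asarray(bf_pct, dtype=float)
    y = np.asarray(bmi, dtype=float)
    if x.size != y.size:
        raise FitError("bf_pct and bmi must have equal length")
    if max_degree not in (1, 2, 3):
        raise FitError(f"max_degree must be in {{1, 2, 3}}, got {max_degree}")
    if x.size <= max_degree + 2:
        raise FitError(f"need n > max_degree + 2, got n={x.size}")
    if (y <= 0).any():
        raise FitError("all BMI values must be positive for the log transform")
    if np.unique(x).size <= max_degree:
        raise FitError("predictor has too few distinct values (collinear design)")

    ln_y = np.log(y)
    tss = float(np.sum((ln_y - ln_y.mean()) ** 2))

    best = None
    for degree in range(1, max_degree + 1):
        design = np.vander(x, degree + 1, increasing=True)
        coeffs, _, rank, _ = np.linalg.lstsq(design, ln_y, rcond=None)
        if rank < degree + 1:
            continue
        resid = ln_y - design @ coeffs
        rss = float(resid @ resid)
        r2 = 0.0 if tss == 0.0 else max(0.0, 1.0 - rss / tss)
        n, p = x.size, degree + 1
        adj = -np.inf if tss == 0.0 else 1.0 - (1.0 - (1.0 - rss / tss)) * (n - 1) / (n - p)
        resid_sd = float(np.sqrt(rss / (n - p)))
        cand = (adj, -degree, degree, coeffs, r2, resid_sd)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        raise FitError("design matrix is rank deficient at every degree")

    _, _, degree, coeffs, r2, resid_sd = best
    return AdiposityModel(
        coeffs=tuple(float(c) for c in coeffs),
        degree=degree,
        r_squared=min(1.0, r2),
        resid_sd=resid_sd,
        n_fit=int(x.size),
        bf_range_fit=(float(x.min()), float(x.max())),
    )


def predict_bmi(
    model: AdiposityModel,
    bf_pct: Sequence[float] | float,
    guard: float = DEFAULT_EXTRAPOLATION_GUARD,
) -> np.ndarray | float:
    """Back-transform the log-polynomial: pBMI = exp(polynomial(BF%)).

    Values outside the fitted BF% range raise :class:`ExtrapolationWarning`
    (never silently); evaluation still proceeds, and callers needing a hard
    stop apply ``guard`` themselves (see cut-off derivation).
    """
    scalar = np.isscalar(bf_pct)
    x = np.atleast_1d(np.asarray(bf_pct, dtype=float))
    lo, hi = model.bf_range_fit
    outside = (x < lo) | (x > hi)
    if outside.any():
        beyond = (x < lo - guard) | (x > hi + guard)
        level = "beyond the extrapolation guard" if beyond.any() else "outside the fitted range"
        warnings.warn(
            f"predicting at BF% {level} [{lo:.2f}, {hi:.2f}] (guard {guard})",
            ExtrapolationWarning,
            stacklevel=2,
        )
    pred = np.exp(model.polynomial(x))
    return float(pred[0]) if scalar else pred
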