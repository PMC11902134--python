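"""Derive population-specific BMI cut-offs by threshold substitution.

The reference body-fat thresholds are substituted into the fitted
log-polynomial and back-transformed (antilog) to BMI units; the inverse map
from BMI back to BF% solves the polynomial on the physiologic (rising)
branch.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .classification import BfBands, CutoffSet, round_half_up
from .errors import CutoffOrderingError, ExtrapolationError, InversionError
from .model_building import DEFAULT_EXTRAPOLATION_GUARD, AdiposityModel, predict_bmi
from .errors import ExtrapolationWarning

__all__ = ["derive_cutoffs", "bmi_to_bf"]


def _check_guard(model: AdiposityModel, x: float, guard: float, what: str) -> None:
    lo, hi = model.bf_range_fit
    if x < lo - guard or x > hi + guard:
        raise ExtrapolationError(
            f"{what} BF% = {x} lies beyond the extrapolation guard "
            f"[{lo - guard:.2f}, {hi + guard:.2f}] of the fitted range"
        )


def derive_cutoffs(
    model: AdiposityModel,
    bands: BfBands = BfBands(),
    rounding: int = 1,
    guard: float = DEFAULT_EXTRAPOLATION_GUARD,
) -> CutoffSet:
    """Substitute body-fat thresholds into the model and back-transform.

    Returns a :class:`CutoffSet` named ``"derived"`` whose thresholds are
    rounded half-up to ``rounding`` decimals; the unrounded values and the
    generating bands are kept in the provenance block.
    """
    _check_guard(model, bands.overweight_bf, guard, "overweight band")
    _check_guard(model, bands.obesity_bf, guard, "obesity band")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        over_raw = float(predict_bmi(model, bands.overweight_bf, guard=guard))
        obes_raw = float(predict_bmi(model, bands.obesity_bf, guard=guard))
    if obes_raw <= over_raw:
        raise CutoffOrderingError(
            f"model is non-increasing over the band interval: "
            f"cut-offs ({over_raw:.3f}, {obes_raw:.3f}) are not ordered"
        )

    over = round_half_up(over_raw, rounding)
    obes = round_half_up(obes_raw, rounding)
    if obes <= over:
        raise CutoffOrderingError(
            f"rounded cut-offs coincide at {rounding} decimals: ({over}, {obes})"
        )
    return CutoffSet(
        name="derived",
        overweight_bmi=over,
        obesity_bmi=obes,
        provenance={
            "model": model.to_dict(),
            "bands": {"overweight_bf": bands.overweight_bf, "obesity_bf": bands.obesity_bf},
            "unrounded": [over_raw, obes_raw],
            "rounding": rounding,
        },
    )


def bmi_to_bf(
    model: AdiposityModel,
    bmi: float,
    guard: float = DEFAULT_EXTRAPOLATION_GUARD,
) -> float:
    """Invert the log-polynomial: the BF% at which the model attains ``bmi``.

    For quadratic models the root inside the guarded fit range is returned;
    when both roots qualify the one on the rising limb (positive derivative)
    is chosen, since adiposity cut-offs live on the rising branch.
    """
    if not bmi > 0:
        raise InversionError(f"bmi must be positive, got {bmi}")
    if model.degree > 2:
        raise InversionError("inversion implemented for degrees 1 and 2 only")
    target = math.log(bmi)
    lo, hi = model.bf_range_fit
    lo_g, hi_g = lo - guard, hi + guard

    if model.degree == 1:
        c0, c1 = model.coeffs
        if c1 == 0:
            raise InversionError("constant model cannot be inverted")
        roots = [(target - c0) / c1]
    else:
        c0, c1, c2 = model.coeffs
        if c2 == 0:
            if c1 == 0:
                raise InversionError("constant model cannot be inverted")
            roots = [(target - c0) / c1]
        else:
            disc = c1**2 - 4 * c2 * (c0 - target)
            if disc < 0:
                raise InversionError(
                    f"bmi = {bmi} is not attained by the model (negative discriminant)"
                )
            sq = math.sqrt(disc)
            roots = [(-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2)]

    in_range = [r for r in roots if lo_g <= r <= hi_g]
    if not in_range:
        raise InversionError(
            f"no root of the model at bmi = {bmi} lies within the guarded "
            f"BF% range [{lo_g:.2f}, {hi_g:.2f}] (roots: {roots})"
        )
    if len(in_range) == 1:
        return float(in_range[0])

    def deriv(r: float) -> float:
        cs = model.coeffs
        return sum(k * cs[k] * r ** (k - 1) for k in range(1, len(cs)))

    rising = [r for r in in_range if deriv(r) > 0]
    return float(rising[0] if rising else in_range[0])
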