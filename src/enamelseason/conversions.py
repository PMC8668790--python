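"""Delta-18O scale conversions and the water-to-enamel-phosphate prediction.

The central relationship is the empirical mammal-enamel calibration

    d18O_PO4* = 0.9 * d18O_w + 23        (permil, VSMOW)

which predicts the enamel phosphate value of a theoretical
evaporation-insensitive animal drinking water of composition ``d18O_w``.
Carbonate values reported on the VPDB scale convert to VSMOW through the
standard Coplen affine transform ``1.03091 * d + 30.91``.

All operations are pure, never round, and vectorize elementwise over
array input.  Presentation-layer rounding to one decimal is left to
callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, ScaleMismatchError

__all__ = [
    "DeltaValue",
    "ConversionConstants",
    "DEFAULT_CONSTANTS",
    "water_to_phosphate",
    "phosphate_to_water",
    "vpdb_to_vsmow",
    "vsmow_to_vpdb",
    "co3_po4_spacing",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Coefficients of the affine conversions, overridable via run config."""

    eq_slope: float = 0.9  # water -> phosphate slope
    eq_intercept: float = 23.0  # water -> phosphate intercept, permil
    vpdb_slope: float = 1.03091  # VPDB -> VSMOW (Coplen)
    vpdb_intercept: float = 30.91  # permil


DEFAULT_CONSTANTS = ConversionConstants()


@dataclass(frozen=True)
class DeltaValue:
    """A delta-18O value tagged with its reference scale and analyte."""

    value: float
    scale: str = "VSMOW"
    analyte: str = "water"

    def __post_init__(self) -> None:
        if self.scale not in ("VSMOW", "VPDB"):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        if self.analyte not in ("water", "PO4", "CO3"):
            raise InvalidInputError(f"unknown analyte {self.analyte!r}")
        if self.scale == "VPDB" and self.analyte != "CO3":
            raise InvalidInputError("VPDB scale is only used for CO3 values")
        if not np.isfinite(self.value):
            raise InvalidInputError("delta value must be finite")


def _as_finite_array(d, name: str):
    arr = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite, got {d!r}")
    return arr


def _maybe_scalar(arr, template):
    return float(arr) if np.isscalar(template) or np.ndim(template) == 0 else arr


def water_to_phosphate(dw, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Predict enamel d18O_PO4* (permil VSMOW) from water d18O_w (permil VSMOW).

    Affine and strictly increasing; differences map as ``0.9 * delta``.
    """
    arr = _as_finite_array(dw, "d18O_w")
    return _maybe_scalar(constants.eq_slope * arr + constants.eq_intercept, dw)


def phosphate_to_water(dp, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Algebraic inverse of :func:`water_to_phosphate`."""
    arr = _as_finite_array(dp, "d18O_PO4")
    return _maybe_scalar((arr - constants.eq_intercept) / constants.eq_slope, dp)


def _check_scale(d, expected: str):
    """Return the numeric payload, enforcing the scale tag when present."""
    if isinstance(d, DeltaValue):
        if d.scale != expected:
            raise ScaleMismatchError(f"expected a {expected} value, got {d.scale}")
        return d.value
    return d


def vpdb_to_vsmow(d, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Convert a carbonate d18O value from the VPDB to the VSMOW scale.

    Accepts a bare number (assumed VPDB) or a tagged :class:`DeltaValue`;
    a value already tagged VSMOW is rejected.
    """
    val = _check_scale(d, "VPDB")
    arr = _as_finite_array(val, "d18O (VPDB)")
    out = constants.vpdb_slope * arr + constants.vpdb_intercept
    if isinstance(d, DeltaValue):
        return DeltaValue(float(out), scale="VSMOW", analyte=d.analyte)
    return _maybe_scalar(out, val)


def vsmow_to_vpdb(d, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Inverse of :func:`vpdb_to_vsmow` (CO3 values only)."""
    val = _check_scale(d, "VSMOW")
    arr = _as_finite_array(val, "d18O (VSMOW)")
    out = (arr - constants.vpdb_intercept) / constants.vpdb_slope
    if isinstance(d, DeltaValue):
        return DeltaValue(float(out), scale="VPDB", analyte="CO3")
    return _maybe_scalar(out, val)


def co3_po4_spacing(dco3, dpo4):
    """Carbonate-phosphate spacing ``d18O_CO3 - d18O_PO4`` (both VSMOW).

    The spacing is the standard diagenesis check for bioapatite; both
    inputs must be on the VSMOW scale (enforced when tagged).
    """
    c = _check_scale(dco3, "VSMOW")
    p = _check_scale(dpo4, "VSMOW")
    ca = _as_finite_array(c, "d18O_CO3")
    pa = _as_finite_array(p, "d18O_PO4")
    out = ca - pa
    if np.ndim(c) == 0 and np.ndim(p) == 0:
        return float(out)
    return out
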