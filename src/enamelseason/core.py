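"""Shared data containers for intra-tooth isotope analysis.

The containers here are deliberately thin wrappers around numpy arrays:
an :class:`IsotopeSeries` is one specimen's serially drilled profile with
replicate measurements, a :class:`MonthlyWaterSeries` is a 12-month
environmental-water record, a :class:`ToothGeometry` carries the enamel
formation parameters of the time-averaging model, and an
:class:`InputSeries` is a primary (body-water-equivalent) signal on a
uniform axial grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "IsotopeSeries",
    "MonthlyWaterSeries",
    "ToothGeometry",
    "InputSeries",
]

#: Axial position convention: millimetres measured from the occlusal
#: (first-formed) end of the crown, increasing toward the root.  Enamel is
#: laid down occlusal-to-root, so larger positions are later-formed.
POSITION_DATUM = "from_occlusal"


@dataclass(frozen=True)
class ToothGeometry:
    """Enamel formation geometry for the time-averaging transfer function.

    Parameters
    ----------
    la : float
        Length of apposition in mm: the axial extent of the slanted
        enamel-matrix secretion front. Default 7 mm, the midpoint of the
        2-12 mm range reported for small bovids.
    lm : float
        Length of maturation in mm: the axial extent of crown that is
        actively mineralizing at any one time. Default 13.3 mm.
    fi : float
        Initial mineral fraction: share of final mineral content present
        at matrix secretion, the remainder added during maturation.
        Default 0.25.
    sample_length : float
        Axial width of one drilled sample in mm. Default 2 mm.
    depth_fraction : float
        Fraction of enamel thickness intersected by the drill. Default
        0.75 (drilling through ~75% of the enamel).
    growth_rate : float
        Crown extension rate in mm/year. Default 30 mm/year.
    """

    la: float = 7.0
    lm: float = 13.3
    fi: float = 0.25
    sample_length: float = 2.0
    depth_fraction: float = 0.75
    growth_rate: float = 30.0

    def __post_init__(self) -> None:
        if not (self.la > 0 and self.lm > 0 and self.sample_length > 0):
            raise InvalidInputError("la, lm and sample_length must be positive")
        if not 0 < self.fi < 1:
            raise InvalidInputError(f"fi must lie in (0, 1), got {self.fi}")
        if not 0 < self.depth_fraction <= 1:
            raise InvalidInputError(
                f"depth_fraction must lie in (0, 1], got {self.depth_fraction}"
            )
        if not self.growth_rate > 0:
            raise InvalidInputError("growth_rate must be positive")

    def with_la(self, la: float) -> "ToothGeometry":
        """Return a copy with a different apposition length."""
        return replace(self, la=la)


@dataclass
class IsotopeSeries:
    """Serial enamel (or bone/water) delta-18O profile for one specimen.

    ``positions`` are strictly increasing axial coordinates in mm from the
    occlusal end; ``replicates`` holds one 1-D array of repeated
    measurements per position (typically triplicates).
    """

    specimen_id: str
    positions: np.ndarray
    replicates: list[np.ndarray]
    analyte: str = "PO4"
    scale: str = "VSMOW"
    cohort: str = "modern"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1:
            raise InvalidInputError("positions must be one-dimensional")
        if len(self.replicates) != self.positions.size:
            raise InvalidInputError("one replicate set required per position")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise InvalidInputError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidInputError("positions must be finite")
        self.replicates = [np.atleast_1d(np.asarray(r, dtype=float)) for r in self.replicates]
        for r in self.replicates:
            if r.size < 1:
                raise InsufficientDataError("each position needs >= 1 replicate")
            if not np.all(np.isfinite(r)):
                raise InvalidInputError("replicate values must be finite")
        if self.analyte not in ("PO4", "CO3", "water"):
            raise InvalidInputError(f"unknown analyte {self.analyte!r}")
        if self.scale not in ("VSMOW", "VPDB"):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        if self.scale == "VPDB" and self.analyte != "CO3":
            raise InvalidInputError("VPDB scale is only valid for CO3 values")

    @property
    def n_samples(self) -> int:
        return self.positions.size

    def replicate_means(self) -> np.ndarray:
        """Per-position mean of the replicate measurements."""
        return np.array([r.mean() for r in self.replicates])

    def replicate_sds(self) -> np.ndarray:
        """Per-position sample standard deviation (0 for single replicates)."""
        return np.array([r.std(ddof=1) if r.size > 1 else 0.0 for r in self.replicates])

    def span_mm(self) -> float:
        """Axial extent covered by the sample centers."""
        return float(self.positions.max() - self.positions.min())


@dataclass
class MonthlyWaterSeries:
    """Twelve monthly environmental-water delta-18O values (permil VSMOW)."""

    months: np.ndarray = field(default_factory=lambda: np.arange(1, 13))
    values: np.ndarray = field(default_factory=lambda: np.full(12, np.nan))

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.months.size != 12 or self.values.size != 12:
            raise InvalidInputError("a monthly water series needs exactly 12 entries")
        if sorted(self.months.tolist()) != list(range(1, 13)):
            raise InvalidInputError("months must be a permutation of 1..12")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("water values must be finite")
        order = np.argsort(self.months)
        self.months = self.months[order]
        self.values = self.values[order]

    def value_for(self, month: int) -> float:
        return float(self.values[month - 1])


@dataclass
class InputSeries:
    """Primary input signal on a uniform axial grid (permil VSMOW, PO4 space)."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.positions.size < 2:
            raise InvalidInputError("an input series needs >= 2 grid nodes")
        if self.positions.shape != self.values.shape:
            raise InvalidInputError("positions and values must have equal length")
        d = np.diff(self.positions)
        step = d.mean()
        if step <= 0 or np.max(np.abs(d - step)) > 1e-9 * step:
            raise InvalidInputError("input grid must be uniform and increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("input values must be finite")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def n_nodes(self) -> int:
        return self.positions.size
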