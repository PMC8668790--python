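"""Forward transfer function: primary input signal -> measured enamel profile.

Enamel does not record body water instantaneously.  Mineral accumulates
in two stages — a thin matrix laid down at the secretion front (a
fraction ``fi`` of final mineral) and the remainder added while a length
``lm`` of crown matures behind the front — and a drill bit of finite
width integrates over both.  The measured profile is therefore a moving
average of the primary signal.  This module expresses that averaging as
a row-stochastic matrix acting on a discretized input series, following
the apposition/maturation transfer-function approach used for ungulate
teeth.

The axial kernel for one sample is the superposition of

* a uniform window of width ``la * depth_fraction`` carrying weight
  ``fi`` (the slanted secretion front intersected over the drilled
  depth), and
* a uniform window of width ``lm`` carrying weight ``1 - fi``
  (maturation mineral added as the front advances),

both extending rootward (toward later-formed enamel) from the sample
position, convolved with a uniform window of width ``sample_length``
(the drill footprint) centered on the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import InputSeries, IsotopeSeries, ToothGeometry
from .errors import OutOfRangeError, ResolutionError

__all__ = [
    "AveragingMatrix",
    "build_kernel",
    "kernel_support_mm",
    "build_averaging_matrix",
    "forward_profile",
    "position_to_months",
    "DEFAULT_STEP",
]

#: Default axial grid spacing, mm.
DEFAULT_STEP = 0.1


@dataclass
class AveragingMatrix:
    """Dense averaging operator: one row per sample, one column per grid node."""

    weights: np.ndarray
    row_positions: np.ndarray
    col_positions: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.row_positions = np.asarray(self.row_positions, dtype=float)
        self.col_positions = np.asarray(self.col_positions, dtype=float)

    def apply(self, values: np.ndarray) -> np.ndarray:
        return self.weights @ np.asarray(values, dtype=float)


def _window_weights(width: float, step: float, centered: bool) -> tuple[np.ndarray, int]:
    """Discretize a uniform window of total weight 1 onto grid cells.

    Cell ``j`` covers ``[(j - 1/2) step, (j + 1/2) step)``.  A centered
    window spans ``[-width/2, width/2)``; otherwise it starts at the
    near edge of cell 0 and extends toward positive offsets.  End cells
    receive fractional weight proportional to their overlap, so kernels
    vary continuously with the geometry and converge under grid
    refinement.  Returns ``(weights, first_cell_index)``.
    """
    if not centered and width <= step * (1 + 1e-9):
        # unresolvable rootward window: all mass in the origin cell
        return np.ones(1), 0
    start = -width / 2.0 if centered else 0.0
    end = start + width
    j_min = math.floor(start / step + 0.5)
    j_max = math.ceil(end / step + 0.5) - 1
    j_max = max(j_max, j_min)
    idx = np.arange(j_min, j_max + 1)
    cell_lo = (idx - 0.5) * step
    cell_hi = (idx + 0.5) * step
    overlap = np.minimum(cell_hi, end) - np.maximum(cell_lo, start)
    overlap = np.clip(overlap, 0.0, None)
    if overlap.sum() <= 0:  # zero-width limit: all mass in one cell
        overlap = np.ones(1)
        idx = np.array([j_min])
    return overlap / overlap.sum(), int(idx[0])


def build_kernel(geometry: ToothGeometry, step: float = DEFAULT_STEP):
    """Normalized axial weighting function for one drilled sample.

    Returns ``(weights, offset)`` where ``weights[i]`` is the weight of
    the grid node at axial displacement ``(offset + i) * step`` from the
    sample center (positive = rootward / later-formed).

    Raises
    ------
    ResolutionError
        If ``step`` exceeds ``min(la, lm) / 5``; coarser grids cannot
        resolve the geometry.
    """
    if step <= 0:
        raise ResolutionError("step must be positive")
    widths = (
        geometry.la * geometry.depth_fraction,
        geometry.lm,
        geometry.sample_length,
    )
    degenerate = all(w <= step * (1 + 1e-9) for w in widths)
    if not degenerate and step > min(geometry.la, geometry.lm) / 5 + 1e-12:
        # a fully degenerate geometry (all windows within one cell) is a
        # deliberate identity kernel, not a resolution failure
        raise ResolutionError(
            f"step {step} mm too coarse for geometry "
            f"(need <= min(la, lm)/5 = {min(geometry.la, geometry.lm) / 5:.3g} mm)"
        )
    apposition, app0 = _window_weights(
        geometry.la * geometry.depth_fraction, step, centered=False
    )
    maturation, mat0 = _window_weights(geometry.lm, step, centered=False)
    n = max(apposition.size, maturation.size)
    growth = np.zeros(n)  # app0 == mat0 == 0 for rootward windows
    growth[: apposition.size] += apposition * geometry.fi
    growth[: maturation.size] += maturation * (1.0 - geometry.fi)
    drill, drill0 = _window_weights(geometry.sample_length, step, centered=True)
    kernel = np.convolve(growth, drill)
    offset = app0 + drill0
    # trim numerically-zero ends so the reported support is tight
    nz = np.nonzero(kernel > 1e-15)[0]
    kernel = kernel[nz[0] : nz[-1] + 1]
    offset += int(nz[0])
    kernel = kernel / kernel.sum()
    return kernel, offset


def kernel_support_mm(geometry: ToothGeometry) -> float:
    """Rootward extent (mm) of a sample's kernel beyond its center."""
    return max(geometry.la * geometry.depth_fraction, geometry.lm) + geometry.sample_length / 2


def build_averaging_matrix(
    geometry: ToothGeometry,
    input_series: InputSeries,
    sample_centers,
    step: float | None = None,
) -> AveragingMatrix:
    """Assemble the sample-averaging matrix on the input grid.

    Each row is the kernel of :func:`build_kernel` centered at the
    sample position, truncated at the grid boundaries and renormalized
    to sum to 1 (so constant signals are reproduced exactly at the tooth
    ends rather than padded with invented data).
    """
    centers = np.atleast_1d(np.asarray(sample_centers, dtype=float))
    grid = input_series.positions
    h = input_series.step if step is None else step
    lo, hi = grid[0], grid[-1]
    if np.any(centers < lo - 1e-9) or np.any(centers > hi + 1e-9):
        raise OutOfRangeError(
            f"sample centers must lie within the input grid [{lo:g}, {hi:g}] mm"
        )
    kernel, offset = build_kernel(geometry, h)
    n_nodes = grid.size
    weights = np.zeros((centers.size, n_nodes))
    for i, c in enumerate(centers):
        i0 = int(round((c - lo) / h)) + offset
        idx = np.arange(i0, i0 + kernel.size)
        inside = (idx >= 0) & (idx < n_nodes)
        if not inside.any():
            raise OutOfRangeError(f"kernel for sample at {c:g} mm misses the grid")
        np.add.at(weights[i], idx[inside], kernel[inside])
        weights[i] /= weights[i].sum()
    return AveragingMatrix(weights=weights, row_positions=centers, col_positions=grid.copy())


def forward_profile(
    input_series: InputSeries,
    geometry: ToothGeometry,
    sample_centers,
    specimen_id: str = "forward",
) -> IsotopeSeries:
    """Predict the measured serial profile for a primary input series.

    The prediction is the matrix-vector product of the averaging matrix
    with the input values: linear in the input, and never exceeding the
    input extrema (every row is a convex combination).
    """
    matrix = build_averaging_matrix(geometry, input_series, sample_centers)
    predicted = matrix.apply(input_series.values)
    return IsotopeSeries(
        specimen_id=specimen_id,
        positions=matrix.row_positions,
        replicates=[np.array([v]) for v in predicted],
        analyte="PO4",
        scale="VSMOW",
        cohort="model",
    )


def position_to_months(positions, geometry: ToothGeometry):
    """Elapsed months of growth since the first sampled enamel.

    ``months = 12 * (position - min(position)) / growth_rate``; earlier
    formed (occlusal) enamel maps to smaller elapsed time.
    """
    pos = np.atleast_1d(np.asarray(positions, dtype=float))
    months = 12.0 * (pos - pos.min()) / geometry.growth_rate
    return float(months[0]) if np.ndim(positions) == 0 else months
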