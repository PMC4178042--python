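"""Signed local curvature of the Bruch's membrane line.

The membrane trace is first carried into isotropic physical coordinates
(micrometres along the scan line, micrometres of depth), resampled onto a
dense 1-µm grid, and then differentiated with a three-point central-difference
stencil whose arms are fixed at h = 500 µm — the spacing of the A-scans the
method samples.  Each curvature value therefore summarises the local shape of
a 1000-µm window sliding at 1-µm steps.

Sign convention
---------------
Depth is posterior-positive (image row 0 is the vitreous side).  With
f(x) the depth of the membrane,

    kappa = f'' / (1 + f'^2)^(3/2)

so kappa > 0 where the membrane is convex toward the vitreous (an anterior
bump), kappa < 0 for a posterior bowl.  A normal posterior pole — a sphere of
radius R seen from inside — has kappa = -1/R everywhere; a staphyloma floor
is strongly negative and its edge ring crosses zero into positive values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import BoundaryTrace
from .oct_io import Calibration

__all__ = [
    "PhysicalTrace",
    "CurvatureProfile",
    "to_physical",
    "resample_dense",
    "local_curvature",
    "curvature_profile",
    "DEFAULT_STENCIL_ARM_UM",
    "DEFAULT_STEP_UM",
    "DEFAULT_MAX_GAP_UM",
]

#: Stencil arm h: the A-scan spacing of the acquisition protocol (µm).
DEFAULT_STENCIL_ARM_UM = 500.0
#: Dense evaluation grid pitch (µm).
DEFAULT_STEP_UM = 1.0
#: Interpolation is not trusted across gaps wider than this (µm).
DEFAULT_MAX_GAP_UM = 1000.0


@dataclass
class PhysicalTrace:
    """A boundary trace in physical units.

    ``position_um`` increases along the scan line (0 at the fovea column);
    ``depth_um`` is posterior-positive.
    """

    position_um: np.ndarray
    depth_um: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.position_um.shape == self.depth_um.shape == self.valid.shape):
            raise ValueError("position, depth and valid must have equal length")
        if self.position_um.ndim != 1:
            raise ValueError("trace arrays must be one-dimensional")
        if np.any(np.diff(self.position_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.depth_um[self.valid])):
            raise ValueError("depths must be finite wherever valid")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class CurvatureProfile:
    """Dense signed curvature along one scan line (1/µm vs µm)."""

    position_um: np.ndarray
    kappa: np.ndarray
    valid: np.ndarray
    h_um: float = DEFAULT_STENCIL_ARM_UM

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.position_um.shape == self.kappa.shape == self.valid.shape):
            raise ValueError("position, kappa and valid must have equal length")
        if self.h_um <= 0:
            raise ValueError("h_um must be positive")
        if self.valid.size and not np.all(np.isfinite(self.kappa[self.valid])):
            raise ValueError("kappa must be finite wherever valid")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def to_physical(trace: BoundaryTrace, calib: Calibration, center_col: int) -> PhysicalTrace:
    """Scale a pixel-space boundary trace to isotropic physical coordinates.

    Corrects for the anisotropic pixel pitch of the B-scan: position is
    ``(column - center_col) * lateral_um_per_px`` (0 at the fovea), depth is
    ``depth_px * axial_um_per_px``.
    """
    depth_px = np.asarray(trace.depth_px, dtype=float)
    valid = np.asarray(trace.valid, dtype=bool)
    if valid.sum() < 2:
        raise ValueError("trace needs at least 2 valid columns")
    cols = np.arange(depth_px.size, dtype=float)
    position = (cols - float(center_col)) * calib.lateral_um_per_px
    depth = np.where(valid, depth_px, 0.0) * calib.axial_um_per_px
    return PhysicalTrace(position_um=position, depth_um=depth, valid=valid)


def resample_dense(
    trace: PhysicalTrace,
    step_um: float = DEFAULT_STEP_UM,
    max_gap_um: float = DEFAULT_MAX_GAP_UM,
) -> PhysicalTrace:
    """Linearly interpolate a trace onto a uniform ``step_um`` grid.

    The grid spans the valid extent of the input.  Grid points that fall
    inside a gap between valid samples wider than ``max_gap_um`` are marked
    invalid rather than bridged by interpolation.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    pos = trace.position_um[trace.valid]
    dep = trace.depth_um[trace.valid]
    if pos.size < 2:
        raise ValueError("need at least 2 valid samples to resample")

    start = np.ceil(pos[0] / step_um) * step_um
    stop = np.floor(pos[-1] / step_um) * step_um
    n = int(round((stop - start) / step_um)) + 1
    grid = start + step_um * np.arange(n)
    depth = np.interp(grid, pos, dep)

    # a grid point inherits validity from the gap of source samples around it
    right = np.searchsorted(pos, grid, side="left")
    right = np.clip(right, 1, pos.size - 1)
    gap = pos[right] - pos[right - 1]
    valid = gap <= max_gap_um
    # points exactly on a valid source sample are always valid
    on_node = np.isin(grid, pos)
    valid |= on_node
    return PhysicalTrace(position_um=grid, depth_um=depth, valid=valid)


def local_curvature(f_minus, f0, f_plus, h_um: float):
    """Three-point central-difference signed curvature (1/µm).

    ``f_minus, f0, f_plus`` are posterior-positive depths (µm) at positions
    x-h, x, x+h.  The first and second derivatives are central differences

        f' = (f_plus - f_minus) / (2 h)
        f'' = (f_plus - 2 f0 + f_minus) / h^2

    and kappa = f'' / (1 + f'^2)^(3/2).  Collinear points give exactly 0 —
    a 1000-µm window of straight membrane is locally flat by construction.
    Accepts scalars or arrays (broadcast).
    """
    if h_um <= 0:
        raise ValueError("h_um must be positive")
    f_minus = np.asarray(f_minus, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    f_plus = np.asarray(f_plus, dtype=float)
    if not (np.all(np.isfinite(f_minus)) and np.all(np.isfinite(f0)) and np.all(np.isfinite(f_plus))):
        raise ValueError("curvature stencil requires finite depths")
    fp = (f_plus - f_minus) / (2.0 * h_um)
    fpp = (f_plus - 2.0 * f0 + f_minus) / (h_um * h_um)
    kappa = fpp / np.power(1.0 + fp * fp, 1.5)
    if kappa.ndim == 0:
        return float(kappa)
    return kappa


def curvature_profile(
    trace: PhysicalTrace,
    h_um: float = DEFAULT_STENCIL_ARM_UM,
    step_um: float = DEFAULT_STEP_UM,
) -> CurvatureProfile:
    """Evaluate the sliding 1000-µm stencil over a dense trace.

    ``trace`` must sit on (or is resampled to) a uniform ``step_um`` grid.
    Curvature is evaluated at every grid centre whose two stencil neighbours
    at ±``h_um`` exist and are valid; centres within ``h_um`` of the trace
    ends — the 500-µm margins the protocol discards — or adjacent to invalid
    spans are masked invalid.
    """
    spacing = np.diff(trace.position_um)
    if spacing.size == 0 or not np.allclose(spacing, step_um, rtol=0, atol=1e-9 * max(1.0, step_um)):
        trace = resample_dense(trace, step_um=step_um)

    k = int(round(h_um / step_um))
    if k < 1:
        raise ValueError("h_um must be at least one grid step")
    n = trace.position_um.size
    if n < 2 * k + 1:
        warnings.warn("trace shorter than the 1000-um stencil window; empty profile")
        empty = np.empty(0)
        return CurvatureProfile(empty, empty.copy(), np.empty(0, dtype=bool), h_um=h_um)

    centers = trace.position_um[k:-k]
    f_minus = trace.depth_um[: -2 * k]
    f0 = trace.depth_um[k:-k]
    f_plus = trace.depth_um[2 * k :]
    # a centre is trusted only if its whole ±h window is valid, not just the
    # three stencil samples — curvature describes the window it spans
    window_ok = ndimage.minimum_filter1d(
        trace.valid.astype(np.uint8), size=2 * k + 1, mode="constant", cval=0
    ).astype(bool)
    valid = window_ok[k:-k]

    kappa = np.zeros_like(f0)
    if valid.any():
        kappa[valid] = local_curvature(f_minus[valid], f0[valid], f_plus[valid], h_um)
    return CurvatureProfile(position_um=centers, kappa=kappa, valid=valid, h_um=h_um)
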