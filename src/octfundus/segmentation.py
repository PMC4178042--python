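"""Retinal boundary detection in a B-scan.

The cascade: a median filter removes speckle outliers, a depth-direction
second-derivative (Hessian ridge) filter emphasises bright horizontal layer
bands, and a Sobel filter supplies signed vertical gradients.  Per A-scan
column, the first supra-threshold ridge peak from the vitreous side seeds the
inner limiting membrane (refined anteriorly to the nearest gradient peak) and
the nerve-fiber-layer boundary (gradient peak searched posteriorly); the last
supra-threshold ridge peak seeds the Bruch's membrane line, refined
posteriorly to the nearest gradient peak.  A one-dimensional open snake then
smooths each boundary, with manually corrected columns pinned.

All depths are row indices (row 0 = vitreous side); detection is column-local,
so no lateral coupling exists before the snake stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

__all__ = [
    "BoundaryTrace",
    "SnakeParams",
    "SegmentationError",
    "SnakeDivergenceError",
    "denoise",
    "layer_response",
    "gradient_response",
    "detect_boundaries",
    "refine_snakes",
    "snake_energy",
    "apply_corrections",
    "DEFAULT_THRESHOLD_FRAC",
    "DEFAULT_HESSIAN_SIGMA_AXIAL",
    "DEFAULT_HESSIAN_SIGMA_LATERAL",
]

#: Ridge-peak acceptance threshold, as a fraction of the per-image maximum
#: response — scale-free across 8- and 16-bit inputs.
DEFAULT_THRESHOLD_FRAC = 0.3
#: Axial scale of the ridge filter (px); device layer bands are a few px thick.
DEFAULT_HESSIAN_SIGMA_AXIAL = 2.0
DEFAULT_HESSIAN_SIGMA_LATERAL = 1.0
#: How far (px) gradient refinement may walk from a ridge initialisation.
DEFAULT_REFINE_RANGE_PX = 12


class SegmentationError(RuntimeError):
    """No column produced a usable boundary."""


class SnakeDivergenceError(RuntimeError):
    """The snake energy increased beyond tolerance."""


@dataclass
class BoundaryTrace:
    """Per-column depth of one named layer boundary.

    ``depth_px`` is in rows; ``valid`` flags columns with a detection;
    ``manual`` flags manually re-plotted columns (manual implies valid).
    """

    depth_px: np.ndarray
    valid: np.ndarray
    manual: np.ndarray
    layer: str = "BM"

    def __post_init__(self) -> None:
        self.depth_px = np.asarray(self.depth_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.manual = np.asarray(self.manual, dtype=bool)
        if not (self.depth_px.shape == self.valid.shape == self.manual.shape):
            raise ValueError("depth, valid and manual must have equal length")
        if np.any(self.manual & ~self.valid):
            raise ValueError("manual columns must be valid")

    @property
    def n_cols(self) -> int:
        return self.depth_px.size


@dataclass(frozen=True)
class SnakeParams:
    """Open-snake weights: ``alpha`` tension, ``beta`` stiffness."""

    alpha: float = 0.1
    beta: float = 1.0
    iterations: int = 200
    step: float = 0.5
    convergence_px: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.step <= 0:
            raise ValueError("step must be positive")


def denoise(image: np.ndarray, size: int = 3) -> np.ndarray:
    """Median-filter the B-scan with a ``size`` × ``size`` window."""
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if size > min(image.shape):
        raise ValueError(f"median window {size} exceeds image extent {image.shape}")
    return ndimage.median_filter(image, size=size, mode="nearest")


def layer_response(
    image: np.ndarray,
    sigma_axial: float = DEFAULT_HESSIAN_SIGMA_AXIAL,
    sigma_lateral: float = DEFAULT_HESSIAN_SIGMA_LATERAL,
) -> np.ndarray:
    """Ridge strength of bright horizontal bands (non-negative).

    The dominant Hessian component for a horizontal band is the axial second
    derivative; its negated Gaussian-derivative response peaks at band centres
    and is ~0 for vertical structure, giving the orientation selectivity the
    layer filter needs.
    """
    img = np.asarray(image, dtype=float)
    d2 = ndimage.gaussian_filter(
        img, sigma=(sigma_axial, sigma_lateral), order=(2, 0), mode="nearest"
    )
    # the truncated derivative kernel does not sum exactly to zero; remove the
    # DC leak so uniform regions give zero response
    probe = np.ones(2 * int(4 * sigma_axial + 0.5) + 9)
    leak = float(ndimage.gaussian_filter1d(probe, sigma_axial, order=2)[probe.size // 2])
    smooth = ndimage.gaussian_filter(
        img, sigma=(sigma_axial, sigma_lateral), order=0, mode="nearest"
    )
    return np.clip(-(d2 - leak * smooth), 0.0, None)


def gradient_response(image: np.ndarray) -> np.ndarray:
    """Signed Sobel depth-gradient; positive where intensity grows with depth."""
    img = np.asarray(image, dtype=float)
    return ndimage.sobel(img, axis=0, mode="nearest") / 8.0


def _nearest_gradient_peak(
    g_col: np.ndarray, start: int, direction: int, want_sign: int, max_range: int
) -> int | None:
    """Index of the nearest local extremum of ``want_sign * g`` from ``start``.

    Walks row-by-row in ``direction`` (−1 anterior, +1 posterior) and returns
    the first strict local maximum of ``want_sign * g_col`` with the wanted
    sign, or None within ``max_range``.
    """
    n = g_col.size
    s = g_col * want_sign
    for offset in range(max_range + 1):
        i = start + direction * offset
        if i <= 0 or i >= n - 1:
            break
        if s[i] > 0 and s[i] >= s[i - 1] and s[i] >= s[i + 1] and (s[i] > s[i - 1] or s[i] > s[i + 1]):
            return i
    return None


def detect_boundaries(
    image: np.ndarray,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    column_valid: np.ndarray | None = None,
    sigma_axial: float = DEFAULT_HESSIAN_SIGMA_AXIAL,
    sigma_lateral: float = DEFAULT_HESSIAN_SIGMA_LATERAL,
    median_size: int = 3,
    refine_range_px: int = DEFAULT_REFINE_RANGE_PX,
) -> tuple[BoundaryTrace, BoundaryTrace, BoundaryTrace]:
    """Detect the ILM, NFL boundary and Bruch's membrane in one B-scan.

    Returns ``(ilm, nfl, bm)`` traces.  Columns with no ridge peak reaching
    ``threshold_frac`` of the image's maximum ridge response are invalid; if
    every column is invalid a :class:`SegmentationError` is raised.
    """
    if not (0.0 < threshold_frac <= 1.0):
        raise ValueError("threshold_frac must lie in (0, 1]")
    den = denoise(image, size=median_size)
    ridge = layer_response(den, sigma_axial, sigma_lateral)
    grad = gradient_response(den)
    # robust maximum: isolated speckle spikes must not drag the scale-free
    # threshold above the true band response
    ridge_max = float(np.quantile(ridge, 0.999)) if ridge.max() > 0 else 0.0
    peak_height = threshold_frac * ridge_max if ridge_max > 0 else np.inf

    n_rows, n_cols = den.shape
    if column_valid is None:
        column_valid = np.ones(n_cols, dtype=bool)

    depth = {k: np.zeros(n_cols) for k in ("ILM", "NFL", "BM")}
    valid = {k: np.zeros(n_cols, dtype=bool) for k in ("ILM", "NFL", "BM")}

    for c in range(n_cols):
        if not column_valid[c]:
            continue
        peaks, _ = find_peaks(ridge[:, c], height=peak_height)
        if peaks.size == 0:
            continue
        first, last = int(peaks[0]), int(peaks[-1])

        # ILM: refine anteriorly to the nearest rising (dark→bright) edge
        ilm = _nearest_gradient_peak(grad[:, c], first, -1, +1, refine_range_px)
        depth["ILM"][c] = ilm if ilm is not None else first
        valid["ILM"][c] = True

        # NFL boundary: falling edge posterior to the same initial value
        nfl = _nearest_gradient_peak(grad[:, c], first + 1, +1, -1, refine_range_px)
        if nfl is not None:
            depth["NFL"][c] = nfl
            valid["NFL"][c] = True

        # BM: last ridge peak, refined posteriorly to the falling edge into
        # the choroid
        bm = _nearest_gradient_peak(grad[:, c], last, +1, -1, refine_range_px)
        depth["BM"][c] = bm if bm is not None else last
        valid["BM"][c] = True

    if not valid["BM"].any():
        raise SegmentationError("no column produced a supra-threshold boundary")

    manual = np.zeros(n_cols, dtype=bool)
    return tuple(
        BoundaryTrace(depth[k], valid[k], manual.copy(), layer=k)
        for k in ("ILM", "NFL", "BM")
    )


def snake_energy(
    trace: BoundaryTrace,
    image: np.ndarray,
    params: SnakeParams = SnakeParams(),
    sigma_axial: float = DEFAULT_HESSIAN_SIGMA_AXIAL,
    sigma_lateral: float = DEFAULT_HESSIAN_SIGMA_LATERAL,
) -> float:
    """Total snake energy of a trace (summed over its contiguous valid spans).

    The quantity :func:`refine_snakes` minimises; useful for verifying that
    refinement never increases it.
    """
    ridge = layer_response(denoise(image), sigma_axial, sigma_lateral)
    rmax = float(ridge.max())
    ridge_n = ridge / rmax if rmax > 0 else ridge
    n_rows = ridge_n.shape[0]

    v = trace.valid
    starts = np.flatnonzero(v & ~np.concatenate(([False], v[:-1])))
    ends = np.flatnonzero(v & ~np.concatenate((v[1:], [False])))
    total = 0.0
    for s, e in zip(starts, ends):
        cols = np.arange(s, e + 1)
        d = trace.depth_px[cols]
        total += params.alpha * np.sum(np.diff(d) ** 2)
        if d.size >= 3:
            total += params.beta * np.sum(np.diff(d, 2) ** 2)
        rows = np.clip(d, 0, n_rows - 1)
        lo = np.floor(rows).astype(int)
        hi = np.minimum(lo + 1, n_rows - 1)
        frac = rows - lo
        total += np.sum(-((1 - frac) * ridge_n[lo, cols] + frac * ridge_n[hi, cols]))
    return float(total)


def refine_snakes(
    trace: BoundaryTrace,
    image: np.ndarray,
    params: SnakeParams = SnakeParams(),
    sigma_axial: float = DEFAULT_HESSIAN_SIGMA_AXIAL,
    sigma_lateral: float = DEFAULT_HESSIAN_SIGMA_LATERAL,
) -> BoundaryTrace:
    """Smooth a boundary with a 1-D open active contour.

    Minimises tension + stiffness + image energy (negative normalised ridge
    response, linearly interpolated in depth) by gradient descent with
    backtracking, so total energy is non-increasing by construction.  Manual
    columns are pinned; invalid columns split the contour into independent
    spans.  Raises :class:`SnakeDivergenceError` if energy ever increases
    beyond tolerance (which backtracking should prevent).
    """
    ridge = layer_response(denoise(image), sigma_axial, sigma_lateral)
    rmax = float(ridge.max())
    ridge_n = ridge / rmax if rmax > 0 else ridge
    n_rows = ridge_n.shape[0]

    depth = trace.depth_px.copy()
    movable = trace.valid & ~trace.manual

    # contiguous valid spans
    v = trace.valid
    starts = np.flatnonzero(v & ~np.concatenate(([False], v[:-1])))
    ends = np.flatnonzero(v & ~np.concatenate((v[1:], [False])))

    for s, e in zip(starts, ends):
        cols = np.arange(s, e + 1)
        if cols.size < 3:
            continue
        mv = movable[cols]
        if not mv.any():
            continue
        d = depth[cols].astype(float)

        def img_e(dd, cols=cols):
            rows = np.clip(dd, 0, n_rows - 1)
            lo = np.floor(rows).astype(int)
            hi = np.minimum(lo + 1, n_rows - 1)
            frac = rows - lo
            val = (1 - frac) * ridge_n[lo, cols] + frac * ridge_n[hi, cols]
            return -val

        def total_e(dd):
            e_int = params.alpha * np.sum(np.diff(dd) ** 2)
            e_int += params.beta * np.sum(np.diff(dd, 2) ** 2) if dd.size >= 3 else 0.0
            return e_int + np.sum(img_e(dd))

        energy = total_e(d)
        step = params.step
        for _ in range(params.iterations):
            # analytic internal-energy gradient
            grad_int = np.zeros_like(d)
            diff1 = np.diff(d)
            grad_int[:-1] -= 2 * params.alpha * diff1
            grad_int[1:] += 2 * params.alpha * diff1
            if d.size >= 3:
                diff2 = np.diff(d, 2)
                grad_int[:-2] += 2 * params.beta * diff2
                grad_int[1:-1] -= 4 * params.beta * diff2
                grad_int[2:] += 2 * params.beta * diff2
            # image gradient by central difference of the interpolant
            h = 0.5
            grad_img = (img_e(d + h) - img_e(d - h)) / (2 * h)
            grad = grad_int + grad_img
            grad[~mv] = 0.0

            gmax = np.abs(grad).max()
            if gmax == 0:
                break
            # backtracking line search keeps the energy monotone
            trial_step = step
            while True:
                d_new = d - trial_step * grad
                d_new = np.clip(d_new, 0, n_rows - 1)
                d_new[~mv] = d[~mv]
                e_new = total_e(d_new)
                if e_new <= energy + 1e-12:
                    break
                trial_step *= 0.5
                if trial_step < 1e-8:
                    d_new = d
                    e_new = energy
                    break
            if e_new > energy + 1e-9:
                raise SnakeDivergenceError(
                    f"snake energy increased ({energy} -> {e_new})"
                )
            disp = np.abs(d_new - d).max()
            d, energy, step = d_new, e_new, min(trial_step * 2.0, params.step)
            if disp < params.convergence_px:
                break
        depth[cols] = d

    return BoundaryTrace(depth, trace.valid.copy(), trace.manual.copy(), trace.layer)


def apply_corrections(
    trace: BoundaryTrace, corrections: list[tuple[int, float]]
) -> BoundaryTrace:
    """Overwrite columns with manually re-plotted depths.

    Corrected columns become valid and manual (so later refinement pins them);
    all other columns are untouched.  Out-of-range columns raise IndexError.
    """
    depth = trace.depth_px.copy()
    valid = trace.valid.copy()
    manual = trace.manual.copy()
    for col, depth_px in corrections:
        col = int(col)
        if not (0 <= col < trace.n_cols):
            raise IndexError(f"correction column {col} outside [0, {trace.n_cols})")
        depth[col] = float(depth_px)
        valid[col] = True
        manual[col] = True
    return BoundaryTrace(depth, valid, manual, trace.layer)
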