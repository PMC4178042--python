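"""The curvature color scale and the en-face topographic map.

Curvature maps color-code signed local curvature: yellow RGB(255, 255, 0) at
κ = 0 (locally flat), grading linearly per channel to green RGB(0, 192, 32)
at κ = +0.0005 1/µm (convex toward the vitreous) and to red RGB(255, 0, 0)
at κ = −0.0005 1/µm (posterior bowl); the scale saturates at |κ| = 1/2000.
On such a map a posterior staphyloma reads directly: an orange-red floor
surrounded by a green-yellow ring where the wall inflects at the edge.

The en-face raster is built from the 12 radial profiles in polar
coordinates: each raster pixel takes the curvature of its radius on the two
angularly adjacent half-lines, interpolated linearly in angle (on κ, not on
RGB, so the zero-crossing ring survives), then colored.  If one neighbour is
missing the nearest half-line's value is used; a pixel is invalid only when
its nearest half-line is invalid there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curvature import CurvatureProfile

__all__ = [
    "ColorScale",
    "EyeCurvatureMap",
    "kappa_to_rgb",
    "render_enface",
    "coverage_of_map",
    "DEFAULT_COLOR_SCALE",
    "ANALYSIS_RADIUS_UM",
]

#: Radius of the analysis disk: the 9-mm scan minus the two 500-µm margins.
ANALYSIS_RADIUS_UM = 4000.0


@dataclass(frozen=True)
class ColorScale:
    """Endpoint colors and the saturation magnitude of the κ color code."""

    kappa_max: float = 5e-4  # 1/µm; colors clamp beyond ±1/2000
    yellow: tuple[int, int, int] = (255, 255, 0)
    green: tuple[int, int, int] = (0, 192, 32)
    red: tuple[int, int, int] = (255, 0, 0)

    def __post_init__(self) -> None:
        if self.kappa_max <= 0:
            raise ValueError("kappa_max must be positive")
        for name in ("yellow", "green", "red"):
            if any(not (0 <= c <= 255) for c in getattr(self, name)):
                raise ValueError(f"{name} channels must lie in [0, 255]")


DEFAULT_COLOR_SCALE = ColorScale()


@dataclass
class EyeCurvatureMap:
    """Rendered en-face topography plus its source radial profiles.

    ``raster`` is RGBA uint8 (invalid pixels alpha 0); ``kappa_raster`` holds
    the interpolated κ field (NaN where invalid); ``valid_mask`` the per-pixel
    validity.  The fovea sits at the raster centre pixel.
    """

    profiles: list[tuple[float, CurvatureProfile]]
    raster: np.ndarray
    kappa_raster: np.ndarray
    valid_mask: np.ndarray
    um_per_px: float
    scale: ColorScale = field(default_factory=ColorScale)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def kappa_to_rgb(kappa, scale: ColorScale = DEFAULT_COLOR_SCALE):
    """Map signed curvature to its display color.

    Per-channel linear interpolation yellow→green on (0, +kappa_max] and
    yellow→red on [−kappa_max, 0); |κ| beyond kappa_max clamps to the
    endpoint color.  Channels are rounded half-up to integers.  Scalars give
    an ``(r, g, b)`` tuple, arrays an ``(..., 3)`` uint8 array.  Non-finite
    κ raises.
    """
    k = np.asarray(kappa, dtype=float)
    if not np.all(np.isfinite(k)):
        raise ValueError("curvature must be finite")
    t = np.clip(k / scale.kappa_max, -1.0, 1.0)
    yellow = np.array(scale.yellow, dtype=float)
    green = np.array(scale.green, dtype=float)
    red = np.array(scale.red, dtype=float)
    tp = np.clip(t, 0.0, 1.0)[..., None]
    tn = np.clip(-t, 0.0, 1.0)[..., None]
    rgb = yellow + tp * (green - yellow) + tn * (red - yellow)
    rgb = _round_half_up(rgb).astype(np.uint8)
    if k.ndim == 0:
        return tuple(int(c) for c in rgb)
    return rgb


def _halfline_table(
    profiles: list[tuple[float, CurvatureProfile]], r_max_um: float, r_step_um: float
):
    """κ and validity of every directed half-line on a common radius grid.

    Each profile at angle θ contributes two half-lines: θ (its s ≥ 0 side)
    and θ+180° (s ≤ 0).  Values are taken at the nearest profile sample.
    """
    radii = np.arange(0.0, r_max_um + r_step_um / 2, r_step_um)
    angles, kappas, valids = [], [], []
    for angle, prof in profiles:
        for phi, sign in ((angle % 360.0, +1.0), ((angle + 180.0) % 360.0, -1.0)):
            s = sign * radii
            idx = np.searchsorted(prof.position_um, s)
            idx = np.clip(idx, 1, prof.position_um.size - 1)
            left = idx - 1
            choose_left = np.abs(prof.position_um[left] - s) <= np.abs(
                prof.position_um[idx] - s
            )
            nearest = np.where(choose_left, left, idx)
            dist = np.abs(prof.position_um[nearest] - s)
            in_range = dist <= r_step_um
            angles.append(phi)
            kappas.append(np.where(in_range, prof.kappa[nearest], np.nan))
            valids.append(in_range & prof.valid[nearest])
    order = np.argsort(angles)
    return (
        np.asarray(angles)[order],
        np.asarray(kappas)[order],
        np.asarray(valids)[order],
        radii,
    )


def render_enface(
    profiles: list[tuple[float, CurvatureProfile]],
    resolution_um_per_px: float = 10.0,
    scale: ColorScale = DEFAULT_COLOR_SCALE,
    field_um: float = 9000.0,
) -> EyeCurvatureMap:
    """Render the en-face curvature raster from radial profiles.

    Needs at least 2 profiles at distinct angles.  The raster spans
    ``field_um`` at ``resolution_um_per_px``; x grows rightward, y upward
    (row 0 is the top).  Pixels outside every half-line's valid extent are
    transparent.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 radial profiles to render")
    if len({a % 180.0 for a, _ in profiles}) < 2:
        raise ValueError("profiles must have distinct angles")

    half = field_um / 2.0
    n = int(round(field_um / resolution_um_per_px)) + 1
    coord = -half + resolution_um_per_px * np.arange(n)
    x = coord[None, :]
    y = -coord[:, None]  # row 0 at +y (top)
    r = np.hypot(x, y)
    phi = np.rad2deg(np.arctan2(y, x)) % 360.0

    hl_angles, hl_kappa, hl_valid, radii = _halfline_table(
        profiles, r_max_um=half, r_step_um=1.0
    )
    n_hl = hl_angles.size

    # angular neighbours (wrapping)
    idx_hi = np.searchsorted(hl_angles, phi.ravel(), side="right") % n_hl
    idx_lo = (idx_hi - 1) % n_hl
    a_lo = hl_angles[idx_lo]
    a_hi = hl_angles[idx_hi]
    span = (a_hi - a_lo) % 360.0
    span = np.where(span == 0, 360.0, span)
    w = ((phi.ravel() - a_lo) % 360.0) / span

    ri = np.rint(r.ravel()).astype(int)
    in_disk = ri <= int(radii[-1])
    ri = np.clip(ri, 0, int(radii[-1]))

    k_lo = hl_kappa[idx_lo, ri]
    k_hi = hl_kappa[idx_hi, ri]
    v_lo = hl_valid[idx_lo, ri]
    v_hi = hl_valid[idx_hi, ri]

    nearest_is_lo = w < 0.5
    both = v_lo & v_hi
    kappa = np.where(both, (1 - w) * k_lo + w * k_hi, np.nan)
    only_lo = v_lo & ~v_hi
    only_hi = v_hi & ~v_lo
    kappa = np.where(only_lo, k_lo, kappa)
    kappa = np.where(only_hi, k_hi, kappa)
    valid = in_disk & np.where(nearest_is_lo, v_lo, v_hi)
    kappa = np.where(valid, kappa, np.nan)

    kappa_raster = kappa.reshape(r.shape)
    valid_mask = valid.reshape(r.shape)

    rgba = np.zeros((*r.shape, 4), dtype=np.uint8)
    safe = np.where(valid_mask, kappa_raster, 0.0)
    rgba[..., :3] = kappa_to_rgb(safe, scale)
    rgba[..., 3] = np.where(valid_mask, 255, 0)

    return EyeCurvatureMap(
        profiles=list(profiles),
        raster=rgba,
        kappa_raster=kappa_raster,
        valid_mask=valid_mask,
        um_per_px=float(resolution_um_per_px),
        scale=scale,
    )


def coverage_of_map(
    eye_map: EyeCurvatureMap, analysis_radius_um: float = ANALYSIS_RADIUS_UM
) -> float:
    """Valid fraction of the 8-mm analysis disk of the rendered raster."""
    n = eye_map.valid_mask.shape[0]
    half = (n - 1) / 2.0
    rows, cols = np.indices(eye_map.valid_mask.shape)
    r = np.hypot(rows - half, cols - half) * eye_map.um_per_px
    disk = r <= analysis_radius_um
    if not disk.any():
        return 0.0
    return float(np.count_nonzero(eye_map.valid_mask & disk) / np.count_nonzero(disk))
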