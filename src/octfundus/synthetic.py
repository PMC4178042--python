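"""Synthetic radial OCT scan sets with known Bruch's membrane geometry.

Phantom eyes are built from a parametric posterior-pole surface: a base
sphere (the globe wall) plus optional Gaussian deformations — a wide bowl for
a posterior staphyloma, a narrow deep pit for a focal choroidal excavation.
Twelve radial B-scans through the fovea are rendered as layered intensity
images (hyperreflective inner-limiting-membrane and retinal-pigment-epithelium
/ Bruch's membrane bands over a darker retina and choroid) with multiplicative
log-normal speckle, alongside the exact membrane row per A-scan, so every
downstream stage can be validated against ground truth.

Depth convention: posterior-positive, referenced to the fovea.  The base
sphere contributes ``-sagitta(r)`` (the periphery of a normal posterior pole
lies anterior to the fovea), so a plain sphere trace has signed curvature
-1/R; bowls and excavations add posterior depth at their centre, giving the
negative-floor / positive-edge-ring curvature pattern of a staphyloma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curvature import PhysicalTrace, curvature_profile
from .metrics import EyeMetrics, eye_metrics
from .oct_io import BScan, Calibration, RadialScanSet

__all__ = [
    "SurfaceModel",
    "GroupSpec",
    "CohortSpec",
    "MetricGroupSpec",
    "GenerationError",
    "surface_depth",
    "sample_radial_traces",
    "render_bscan",
    "render_radial_set",
    "ground_truth_metrics",
    "generate_cohort",
    "sample_metrics_cohort",
    "DEFAULT_CALIBRATION",
]

#: Phantom B-scan pixel pitch (µm/px): ~7 axial × 20 lateral is a realistic
#: SD-OCT export for a 9-mm line at 451 A-scans.
DEFAULT_CALIBRATION = Calibration(axial_um_per_px=7.0, lateral_um_per_px=20.0)

_DEFAULT_INTENSITIES = {
    "vitreous": 0.03,
    "ilm_edge": 0.5,
    "ilm_band": 0.85,
    "retina": 0.25,
    "rpe_band": 0.9,
    "bm_edge": 0.45,
    "choroid": 0.12,
}


class GenerationError(RuntimeError):
    """The requested phantom does not fit the requested image geometry."""


@dataclass(frozen=True)
class SurfaceModel:
    """Parametric Bruch's membrane surface over the 9-mm field.

    ``kind`` selects the active terms: ``sphere`` (base globe only),
    ``staphyloma`` (adds the wide Gaussian bowl), ``excavation`` (adds the
    narrow pit), ``composite`` (both).  Depths are µm, posterior-positive;
    ``center_offset_um`` shifts the bowl/pit centre in the en-face plane.
    """

    kind: str = "sphere"
    base_radius_um: float = 13000.0
    bowl_depth_um: float = 800.0
    bowl_sigma_um: float = 1500.0
    excavation_depth_um: float = 150.0
    excavation_sigma_um: float = 300.0
    center_offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "staphyloma", "excavation", "composite"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if self.base_radius_um <= 0:
            raise ValueError("base_radius_um must be positive")
        if self.bowl_sigma_um <= 0 or self.excavation_sigma_um <= 0:
            raise ValueError("Gaussian sigmas must be positive")
        if self.bowl_depth_um < 0 or self.excavation_depth_um < 0:
            raise ValueError("deformation depths must be non-negative")

    @property
    def has_bowl(self) -> bool:
        return self.kind in ("staphyloma", "composite")

    @property
    def has_excavation(self) -> bool:
        return self.kind in ("excavation", "composite")


def surface_depth(model: SurfaceModel, x_um, y_um):
    """Posterior-positive membrane depth (µm) at en-face position (x, y).

    Relative to the fovea: ``-sagitta(r)`` of the base sphere plus the active
    Gaussian deformations.  Raises if a point leaves the spherical cap.
    """
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    r2 = x * x + y * y
    R = model.base_radius_um
    if np.any(r2 >= R * R):
        raise ValueError("field point outside the base sphere's lateral extent")
    depth = np.sqrt(R * R - r2) - R  # == -sagitta(r), 0 at the fovea
    ox, oy = model.center_offset_um
    if model.has_bowl:
        rho2 = (x - ox) ** 2 + (y - oy) ** 2
        depth = depth + model.bowl_depth_um * np.exp(-rho2 / (2.0 * model.bowl_sigma_um**2))
    if model.has_excavation:
        rho2 = (x - ox) ** 2 + (y - oy) ** 2
        depth = depth + model.excavation_depth_um * np.exp(
            -rho2 / (2.0 * model.excavation_sigma_um**2)
        )
    if depth.ndim == 0:
        return float(depth)
    return depth


def sample_radial_traces(
    model: SurfaceModel,
    n_angles: int = 12,
    half_width_um: float = 4500.0,
    step_um: float = 500.0,
) -> list[tuple[float, PhysicalTrace]]:
    """Ideal membrane traces along ``n_angles`` radial lines through the fovea.

    Angles are evenly spaced over [0, 180): ``k * 180 / n_angles``.  Each trace
    samples s ∈ [-half_width, +half_width] at ``step_um``; position s < 0 is
    the angle+180° half-line.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    n = int(round(2 * half_width_um / step_um)) + 1
    s = -half_width_um + step_um * np.arange(n)
    traces = []
    for k in range(n_angles):
        angle = 180.0 * k / n_angles
        theta = np.deg2rad(angle)
        depth = surface_depth(model, s * np.cos(theta), s * np.sin(theta))
        traces.append(
            (angle, PhysicalTrace(s, np.asarray(depth), np.ones(n, dtype=bool)))
        )
    return traces


def _column_profile(n_rows, ilm_rows, bm_rows, intensities):
    """Noiseless layered image from integer ILM/BM rows per column."""
    I = intensities
    rows = np.arange(n_rows)[:, None]
    ilm = ilm_rows[None, :]
    bm = bm_rows[None, :]
    img = np.full((n_rows, ilm_rows.size), I["vitreous"], dtype=float)
    img = np.where(rows == ilm, I["ilm_edge"], img)
    img = np.where((rows >= ilm + 1) & (rows <= ilm + 3), I["ilm_band"], img)
    img = np.where((rows >= ilm + 4) & (rows <= bm - 4), I["retina"], img)
    img = np.where((rows >= bm - 3) & (rows <= bm - 1), I["rpe_band"], img)
    img = np.where(rows == bm, I["bm_edge"], img)
    img = np.where(rows > bm, I["choroid"], img)
    return img


def render_bscan(
    trace: PhysicalTrace,
    calib: Calibration = DEFAULT_CALIBRATION,
    angle_deg: float = 0.0,
    retina_thickness_um: float = 300.0,
    intensities: dict | None = None,
    speckle_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_rows: int | None = None,
    depth_ref_um: float | None = None,
    top_margin_px: int = 10,
    band_free_columns: list[tuple[int, int]] | None = None,
) -> tuple[BScan, np.ndarray, np.ndarray]:
    """Render one B-scan from an ideal membrane trace.

    The trace must be sampled at the lateral pixel pitch.  Returns
    ``(scan, bm_rows, ilm_rows)`` where the row arrays are the ground-truth
    integer band positions actually rendered per column.  ``depth_ref_um``
    anchors the row mapping (pass the set-wide minimum depth so all scans of
    an eye share a depth frame).  ``band_free_columns`` renders ``[start,
    stop)`` column ranges as band-less background (e.g. mirror artifacts).

    Speckle is multiplicative log-normal, ``I * exp(sigma*Z - sigma^2/2)``,
    seeded and reproducible; output is 8-bit.
    """
    intensities = {**_DEFAULT_INTENSITIES, **(intensities or {})}
    spacing = np.diff(trace.position_um)
    if not np.allclose(spacing, calib.lateral_um_per_px):
        raise ValueError("trace sampling must match the lateral pixel pitch")

    depth = np.asarray(trace.depth_um, dtype=float)
    ref = float(depth.min()) if depth_ref_um is None else float(depth_ref_um)
    retina_px = int(round(retina_thickness_um / calib.axial_um_per_px))
    if retina_px < 9:
        raise GenerationError("retina thinner than the rendered band structure")
    bm_rows = np.rint(
        top_margin_px + retina_px + (depth - ref) / calib.axial_um_per_px
    ).astype(int)
    ilm_rows = bm_rows - retina_px

    needed = int(bm_rows.max()) + 8
    if n_rows is None:
        n_rows = needed
    elif needed > n_rows or ilm_rows.min() < 1:
        raise GenerationError(
            f"trace depth range needs {needed} rows but image has {n_rows}"
        )

    img = _column_profile(n_rows, ilm_rows, bm_rows, intensities)
    if band_free_columns:
        for start, stop in band_free_columns:
            img[:, start:stop] = intensities["vitreous"]

    if speckle_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        z = rng.standard_normal(img.shape)
        img = img * np.exp(speckle_sigma * z - 0.5 * speckle_sigma**2)
    img = np.clip(img, 0.0, 1.0)
    pixels = np.rint(img * 255).astype(np.uint8)

    center_col = int(np.argmin(np.abs(trace.position_um)))
    scan = BScan(
        pixels=pixels,
        calib=calib,
        angle_deg=angle_deg,
        center_col=center_col,
        scan_width_um=float(trace.position_um[-1] - trace.position_um[0]),
    )
    return scan, bm_rows, ilm_rows


def render_radial_set(
    model: SurfaceModel,
    eye_id: str = "phantom",
    calib: Calibration = DEFAULT_CALIBRATION,
    n_angles: int = 12,
    n_cols: int = 451,
    retina_thickness_um: float = 300.0,
    speckle_sigma: float = 0.2,
    seed: int = 0,
) -> tuple[RadialScanSet, list[dict]]:
    """Render a full radial acquisition of a phantom eye.

    Returns the scan set plus per-scan ground truth: a list of dicts with
    ``angle_deg``, ``bm_rows``, ``ilm_rows`` and the ideal ``trace``.  All
    scans share one depth reference so the eye is geometrically consistent.
    """
    if n_cols % 2 == 0:
        raise ValueError("n_cols must be odd so the fovea sits on a column")
    half_width = (n_cols - 1) // 2 * calib.lateral_um_per_px
    traces = sample_radial_traces(
        model, n_angles=n_angles, half_width_um=half_width, step_um=calib.lateral_um_per_px
    )
    ref = min(float(t.depth_um.min()) for _, t in traces)
    n_rows = None
    # size the frame once for the deepest scan
    max_depth = max(float(t.depth_um.max()) for _, t in traces)
    retina_px = int(round(retina_thickness_um / calib.axial_um_per_px))
    n_rows = 10 + retina_px + int(np.ceil((max_depth - ref) / calib.axial_um_per_px)) + 9

    rng = np.random.default_rng(seed)
    scans, truth = [], []
    for angle, trace in traces:
        scan, bm_rows, ilm_rows = render_bscan(
            trace,
            calib=calib,
            angle_deg=angle,
            retina_thickness_um=retina_thickness_um,
            speckle_sigma=speckle_sigma,
            seed=rng,
            n_rows=n_rows,
            depth_ref_um=ref,
        )
        scans.append(scan)
        truth.append(
            {"angle_deg": angle, "bm_rows": bm_rows, "ilm_rows": ilm_rows, "trace": trace}
        )
    return RadialScanSet(eye_id=eye_id, scans=scans), truth


def ground_truth_metrics(
    model: SurfaceModel,
    n_angles: int = 12,
    half_width_um: float = 4500.0,
    h_um: float = 500.0,
    step_um: float = 1.0,
) -> EyeMetrics:
    """Eye metrics computed from the noiseless analytic surface.

    Samples each radial section densely and applies the same sliding-stencil
    curvature as the measurement pipeline, so it is the exact target the
    pipeline should recover in the absence of noise.
    """
    traces = sample_radial_traces(
        model, n_angles=n_angles, half_width_um=half_width_um, step_um=step_um
    )
    profiles = [curvature_profile(t, h_um=h_um, step_um=step_um) for _, t in traces]
    return eye_metrics(profiles)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: n eyes drawn from surface-parameter distributions.

    ``params`` maps SurfaceModel field names to either a number (fixed) or a
    distribution dict ``{"dist": "normal"|"lognormal", "mean": m, "sd": s}``
    (normal draws are clipped to stay positive where required).
    """

    label: str
    n: int
    kind: str = "sphere"
    params: dict = field(default_factory=dict)
    speckle_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("each group needs n >= 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0
    n_angles: int = 12
    render: bool = True

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort spec has no groups")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        doc = json.loads(Path(path).read_text())
        groups = tuple(
            GroupSpec(
                label=g["label"],
                n=int(g["n"]),
                kind=g.get("kind", "sphere"),
                params=g.get("params", {}),
                speckle_sigma=float(g.get("speckle_sigma", 0.2)),
            )
            for g in doc.get("groups", [])
        )
        return cls(
            groups=groups,
            seed=int(doc.get("seed", 0)),
            n_angles=int(doc.get("n_angles", 12)),
            render=bool(doc.get("render", True)),
        )


def _draw_param(rng: np.random.Generator, spec, positive: bool) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    dist = spec.get("dist", "normal")
    m, s = float(spec["mean"]), float(spec["sd"])
    if dist == "normal":
        v = rng.normal(m, s)
        if positive:
            v = max(v, 0.05 * m if m > 0 else 1e-9)
        return v
    if dist == "lognormal":
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2
        return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))
    raise ValueError(f"unknown distribution {dist!r}")


_POSITIVE_PARAMS = {
    "base_radius_um",
    "bowl_depth_um",
    "bowl_sigma_um",
    "excavation_depth_um",
    "excavation_sigma_um",
}


def generate_cohort(spec: CohortSpec) -> list[dict]:
    """Draw a labelled synthetic cohort; deterministic given ``spec.seed``.

    Returns one record per eye: ``eye_id``, ``label``, ``model``,
    ``truth`` (noiseless-surface :class:`EyeMetrics`), and — when
    ``spec.render`` — the rendered ``scan_set`` with its per-scan ground-truth
    rows.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for group in spec.groups:
        for i in range(group.n):
            kwargs = {"kind": group.kind}
            for name, pspec in group.params.items():
                if name == "center_offset_um":
                    kwargs[name] = tuple(float(v) for v in pspec)
                else:
                    kwargs[name] = _draw_param(rng, pspec, name in _POSITIVE_PARAMS)
            model = SurfaceModel(**kwargs)
            eye_id = f"{group.label}_{i:03d}"
            record = {
                "eye_id": eye_id,
                "label": group.label,
                "model": model,
                "truth": ground_truth_metrics(model, n_angles=spec.n_angles),
            }
            if spec.render:
                scan_set, scan_truth = render_radial_set(
                    model,
                    eye_id=eye_id,
                    n_angles=spec.n_angles,
                    speckle_sigma=group.speckle_sigma,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                record["scan_set"] = scan_set
                record["scan_truth"] = scan_truth
            records.append(record)
    return records


# ---------------------------------------------------------------------------
# metric-space cohorts (for classifier studies)


@dataclass(frozen=True)
class MetricGroupSpec:
    """Marginal mean ± SD of (mean |κ|, var κ) for one group of eyes."""

    label: str
    n: int
    mean_abs_mean: float
    mean_abs_sd: float
    var_mean: float
    var_sd: float


def sample_metrics_cohort(
    groups: list[MetricGroupSpec],
    seed: int = 0,
    log_correlation: float = 0.8,
) -> pd.DataFrame:
    """Draw per-eye (mean |κ|, var κ) pairs from group-level statistics.

    Each group's marginals are moment-matched log-normals (both metrics are
    positive and right-skewed), coupled with correlation ``log_correlation``
    on the log scale — mean curvature and its variance rise together with
    staphyloma severity.  Returns a DataFrame with columns ``label``,
    ``mean_abs_kappa``, ``var_kappa``.
    """
    rng = np.random.default_rng(seed)
    rho = float(log_correlation)
    if not (-1.0 < rho < 1.0):
        raise ValueError("log_correlation must lie in (-1, 1)")
    rows = []
    for g in groups:
        z1 = rng.standard_normal(g.n)
        z2 = rho * z1 + np.sqrt(1 - rho * rho) * rng.standard_normal(g.n)
        for value_z, m, s, name in (
            (z1, g.mean_abs_mean, g.mean_abs_sd, "mean_abs_kappa"),
            (z2, g.var_mean, g.var_sd, "var_kappa"),
        ):
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2
            vals = np.exp(mu + np.sqrt(sigma2) * value_z)
            if name == "mean_abs_kappa":
                mean_abs = vals
            else:
                var = vals
        rows.append(pd.DataFrame({"label": g.label, "mean_abs_kappa": mean_abs, "var_kappa": var}))
    return pd.concat(rows, ignore_index=True)
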