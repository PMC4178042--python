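"""I/O for radial OCT scan sets and analysis outputs.

A scan set is described by a JSON manifest (one file per eye) pointing at
grayscale TIFF/PNG B-scans and carrying per-scan calibration and geometry:

.. code-block:: json

    {
      "eye_id": "eye01",
      "scans": [
        {"image": "scan_000.tiff",
         "angle_deg": 0.0,
         "axial_um_per_px": 7.0,
         "lateral_um_per_px": 20.0,
         "center_col": 225,
         "scan_width_um": 9000,
         "invalid_columns": [[0, 8], [440, 451]]}
      ],
      "corrections": "corrections.csv"
    }

``invalid_columns`` are optional half-open ``[start, stop)`` column ranges to
exclude (e.g. mirror-inversion artifacts near the scan edges).  The optional
corrections file is a CSV with columns ``angle_deg, column, depth_px`` of
manually re-plotted Bruch's membrane points.

Coordinate conventions: image row 0 is the most anterior (vitreous) side and
depth grows with the row index; columns run left→right along the scan line;
indices are 0-based.  The scan angle is the line's en-face orientation,
counter-clockwise from horizontal, in [0, 180); the left image half is the
angle+180° half-line.  Loaders never rescale intensities — 8- and 16-bit
images come back exactly as stored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import imageio.v3 as iio
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .curvature_map import EyeCurvatureMap
    from .metrics import EyeMetrics

__all__ = [
    "Calibration",
    "BScan",
    "RadialScanSet",
    "ManifestError",
    "ScanLoadError",
    "load_radial_set",
    "write_radial_set",
    "write_outputs",
    "read_corrections",
    "read_curvature_csv",
    "read_metrics_csv",
    "NOMINAL_SCAN_WIDTH_UM",
]

#: Nominal transverse extent of one radial line (µm).
NOMINAL_SCAN_WIDTH_UM = 9000.0

# float64 -> text -> float64 is lossless at 17 significant digits
_CSV_FLOAT_FORMAT = "%.17g"


class ManifestError(ValueError):
    """The manifest is syntactically or semantically invalid."""


class ScanLoadError(OSError):
    """A scan image named by the manifest could not be read."""


@dataclass(frozen=True)
class Calibration:
    """Pixel pitch of a B-scan (µm/pixel), axial (depth) and lateral."""

    axial_um_per_px: float
    lateral_um_per_px: float

    def __post_init__(self) -> None:
        for name in ("axial_um_per_px", "lateral_um_per_px"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass
class BScan:
    """One calibrated grayscale OCT cross-section.

    ``pixels`` rows are depth (row 0 anterior), columns are A-scans.
    ``center_col`` is the fovea column; ``angle_deg`` the en-face orientation
    of the line in [0, 180).  ``column_valid`` flags analysable columns.
    """

    pixels: np.ndarray
    calib: Calibration
    angle_deg: float
    center_col: int
    scan_width_um: float = NOMINAL_SCAN_WIDTH_UM
    column_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grayscale array")
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValueError(f"angle_deg must lie in [0, 180), got {self.angle_deg}")
        if not (0 <= self.center_col < self.n_cols):
            raise ValueError(
                f"center_col {self.center_col} outside [0, {self.n_cols})"
            )
        if self.column_valid is None:
            self.column_valid = np.ones(self.n_cols, dtype=bool)
        else:
            self.column_valid = np.asarray(self.column_valid, dtype=bool)
            if self.column_valid.shape != (self.n_cols,):
                raise ValueError("column_valid length must equal the column count")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class RadialScanSet:
    """The 12-line (by default) radial acquisition of one eye."""

    eye_id: str
    scans: list[BScan]
    corrections: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.scans:
            raise ManifestError("scan set is empty")
        angles = [s.angle_deg for s in self.scans]
        if len(set(angles)) != len(angles):
            raise ManifestError(f"duplicate scan angles in eye {self.eye_id!r}: {angles}")
        self.scans = sorted(self.scans, key=lambda s: s.angle_deg)
        if len(self.scans) == 1:
            warnings.warn(
                f"eye {self.eye_id!r} has a single scan line; en-face rendering "
                "needs at least 2 distinct angles"
            )

    @property
    def n_lines(self) -> int:
        return len(self.scans)

    @property
    def angles_deg(self) -> list[float]:
        return [s.angle_deg for s in self.scans]

    def corrections_for(self, angle_deg: float) -> list[tuple[int, float]]:
        """Manual (column, depth_px) re-plots for the scan at ``angle_deg``."""
        if self.corrections is None or self.corrections.empty:
            return []
        sel = self.corrections[np.isclose(self.corrections["angle_deg"], angle_deg)]
        return list(zip(sel["column"].astype(int), sel["depth_px"].astype(float)))


def _ranges_to_mask(ranges, n_cols: int) -> np.ndarray:
    mask = np.ones(n_cols, dtype=bool)
    for rng in ranges:
        if len(rng) != 2:
            raise ManifestError(f"invalid_columns range must be [start, stop), got {rng}")
        start, stop = int(rng[0]), int(rng[1])
        if not (0 <= start <= stop <= n_cols):
            raise ManifestError(f"invalid_columns range {rng} outside [0, {n_cols}]")
        mask[start:stop] = False
    return mask


def read_corrections(path: Path) -> pd.DataFrame:
    """Read a manual-correction CSV (angle_deg, column, depth_px)."""
    df = pd.read_csv(path)
    required = {"angle_deg", "column", "depth_px"}
    if not required.issubset(df.columns):
        raise ManifestError(
            f"corrections file {path} must have columns {sorted(required)}"
        )
    return df


def load_radial_set(manifest_path: str | Path) -> RadialScanSet:
    """Load a radial scan set from its JSON manifest.

    Image paths are resolved relative to the manifest's directory.  Scans come
    back sorted by angle; duplicate angles raise :class:`ManifestError` and a
    missing or unreadable image raises :class:`ScanLoadError` naming the entry.
    """
    manifest_path = Path(manifest_path)
    try:
        doc = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ManifestError(f"cannot parse manifest {manifest_path}: {exc}") from exc
    if not isinstance(doc, dict) or "scans" not in doc:
        raise ManifestError(f"manifest {manifest_path} lacks a 'scans' list")

    root = manifest_path.parent
    scans: list[BScan] = []
    for i, entry in enumerate(doc["scans"]):
        try:
            image_rel = entry["image"]
            calib = Calibration(
                axial_um_per_px=float(entry["axial_um_per_px"]),
                lateral_um_per_px=float(entry["lateral_um_per_px"]),
            )
            angle = float(entry["angle_deg"])
            center_col = int(entry["center_col"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ManifestError(f"manifest entry {i} invalid: {exc}") from exc
        image_path = root / image_rel
        try:
            pixels = iio.imread(image_path)
        except (OSError, ValueError) as exc:
            raise ScanLoadError(
                f"entry {i} ({image_rel!r}): cannot read image: {exc}"
            ) from exc
        if pixels.ndim == 3 and pixels.shape[2] == 1:
            pixels = pixels[:, :, 0]
        if pixels.ndim != 2:
            raise ScanLoadError(f"entry {i} ({image_rel!r}): image is not grayscale")
        column_valid = None
        if "invalid_columns" in entry:
            column_valid = _ranges_to_mask(entry["invalid_columns"], pixels.shape[1])
        scans.append(
            BScan(
                pixels=pixels,
                calib=calib,
                angle_deg=angle,
                center_col=center_col,
                scan_width_um=float(entry.get("scan_width_um", NOMINAL_SCAN_WIDTH_UM)),
                column_valid=column_valid,
            )
        )

    corrections = None
    if doc.get("corrections"):
        corrections = read_corrections(root / doc["corrections"])
    return RadialScanSet(
        eye_id=str(doc.get("eye_id", manifest_path.stem)),
        scans=scans,
        corrections=corrections,
    )


def write_radial_set(scan_set: RadialScanSet, out_dir: str | Path) -> Path:
    """Write a scan set as TIFF images plus a JSON manifest; returns its path.

    Images are stored with their in-memory dtype (8- or 16-bit preserved), so
    a load→write→load round trip is exact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, scan in enumerate(scan_set.scans):
        name = f"{scan_set.eye_id}_scan_{i:03d}.tiff"
        iio.imwrite(out_dir / name, scan.pixels)
        entry = {
            "image": name,
            "angle_deg": scan.angle_deg,
            "axial_um_per_px": scan.calib.axial_um_per_px,
            "lateral_um_per_px": scan.calib.lateral_um_per_px,
            "center_col": scan.center_col,
            "scan_width_um": scan.scan_width_um,
        }
        if not scan.column_valid.all():
            entry["invalid_columns"] = _mask_to_ranges(scan.column_valid)
        entries.append(entry)
    doc = {"eye_id": scan_set.eye_id, "scans": entries}
    if scan_set.corrections is not None and not scan_set.corrections.empty:
        corr_name = f"{scan_set.eye_id}_corrections.csv"
        scan_set.corrections.to_csv(
            out_dir / corr_name, index=False, float_format=_CSV_FLOAT_FORMAT
        )
        doc["corrections"] = corr_name
    manifest_path = out_dir / f"{scan_set.eye_id}.json"
    manifest_path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return manifest_path


def _mask_to_ranges(mask: np.ndarray) -> list[list[int]]:
    invalid = ~np.asarray(mask, dtype=bool)
    padded = np.concatenate(([False], invalid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [[int(edges[i]), int(edges[i + 1])] for i in range(0, edges.size, 2)]


def read_curvature_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-point curvature CSV with lossless float parsing."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"angle_deg", "position_um", "kappa_per_um", "valid"}
    if not required.issubset(df.columns):
        raise ManifestError(f"curvature CSV must have columns {sorted(required)}")
    return df


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV with lossless float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def curvature_frame(eye_map: "EyeCurvatureMap") -> pd.DataFrame:
    """Per-point curvature table: one row per (scan angle, position) sample."""
    rows = []
    for angle, profile in eye_map.profiles:
        rows.append(
            pd.DataFrame(
                {
                    "angle_deg": angle,
                    "position_um": profile.position_um,
                    "kappa_per_um": profile.kappa,
                    "valid": profile.valid.astype(int),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["angle_deg", "position_um", "kappa_per_um", "valid"]
        )
    return pd.concat(rows, ignore_index=True)


def write_outputs(
    metrics: "EyeMetrics",
    eye_map: "EyeCurvatureMap",
    out_dir: str | Path,
    eye_id: str = "eye",
) -> dict[str, Path]:
    """Write the per-eye artifact set; returns a name→path manifest.

    Writes ``<eye_id>_curvature.csv`` (angle, position, κ, valid flag),
    ``<eye_id>_metrics.csv`` (one row) and ``<eye_id>_map.png`` (RGBA en-face
    raster, invalid pixels transparent).  CSV floats are written with 17
    significant digits so re-reading reproduces the in-memory values exactly.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    paths = {
        "curvature_csv": out_dir / f"{eye_id}_curvature.csv",
        "metrics_csv": out_dir / f"{eye_id}_metrics.csv",
        "map_png": out_dir / f"{eye_id}_map.png",
    }
    curvature_frame(eye_map).to_csv(
        paths["curvature_csv"], index=False, float_format=_CSV_FLOAT_FORMAT
    )
    pd.DataFrame([{"eye_id": eye_id, **metrics.as_dict()}]).to_csv(
        paths["metrics_csv"], index=False, float_format=_CSV_FLOAT_FORMAT
    )
    iio.imwrite(paths["map_png"], eye_map.raster)
    return paths
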