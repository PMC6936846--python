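"""Ingestion and conditioning of traced OCT retinal contours.

A B scan's retinal contour arrives as a two-column text file of pixel
coordinates (x = lateral column, z = axial row, z increasing posteriorly,
i.e. downward in the displayed image).  Before any shape analysis the trace
is conditioned: duplicate x columns are collapsed to their mean z, gaps in
the x sequence are filled by linear interpolation, and the result is
converted to millimetres using the scan window geometry.  After
conditioning, x is uniformly sampled at one lateral pixel pitch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: shortest trace accepted for analysis (samples after gap filling)
MIN_TRACE_SAMPLES = 16

_DIRECTIONS = (
    "superior",
    "supero-temporal",
    "temporal",
    "infero-temporal",
    "inferior",
    "infero-nasal",
    "nasal",
    "supero-nasal",
)

#: the closed 17-label vocabulary of gaze regions: the macula plus a
#: posterior and an anterior cube in each of 8 directions of gaze.
REGIONS: tuple[str, ...] = ("macula",) + tuple(
    f"{ap} {d}" for ap in ("posterior", "anterior") for d in _DIRECTIONS
)

_REGION_SET = frozenset(REGIONS)


class ContourError(ValueError):
    """Base class for contour ingestion failures."""


class ContourParseError(ContourError):
    pass


class EmptyTraceError(ContourError):
    pass


class ShortTraceError(ContourError):
    pass


def canonical_region(label: str) -> str:
    """Canonicalize a gaze-region label (case, whitespace, separators).

    Raises ``ContourError`` for labels outside the closed 17-label
    vocabulary.
    """
    raw = label
    norm = " ".join(str(label).strip().lower().replace("_", " ").split())
    if norm not in _REGION_SET:
        raise ContourError(f"unknown region label: {raw!r}")
    if norm != str(label):
        logger.debug("canonicalized region label %r -> %r", raw, norm)
    return norm


@dataclass(frozen=True)
class ScanSpec:
    """Geometry of one OCT acquisition protocol.

    Defaults describe a 9 mm x 2 mm B-scan window sampled on a
    1024 x 1024 pixel grid, 21 scans per cube spaced 0.4 mm apart.
    """

    width_mm: float = 9.0
    depth_mm: float = 2.0
    lateral_px: int = 1024
    axial_px: int = 1024
    scans_per_cube: int = 21
    scan_spacing_mm: float = 0.4

    def __post_init__(self) -> None:
        for name in ("width_mm", "depth_mm", "lateral_px", "axial_px",
                     "scans_per_cube", "scan_spacing_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"ScanSpec.{name} must be strictly positive, got {v}")

    @property
    def dx_mm(self) -> float:
        """Lateral millimetres per pixel."""
        return self.width_mm / self.lateral_px

    @property
    def dz_mm(self) -> float:
        """Axial millimetres per pixel."""
        return self.depth_mm / self.axial_px


@dataclass(frozen=True)
class EyeRecord:
    """One study eye: identity, axial length and session."""

    eye_id: str
    axial_length_mm: float
    laterality: str = "right"
    session_id: str = "1"

    def __post_init__(self) -> None:
        al = self.axial_length_mm
        if not (15.0 <= al <= 40.0):
            raise ValueError(
                f"axial length {al} mm for eye {self.eye_id!r} outside the "
                "enforced 15-40 mm range"
            )
        if not (21.0 <= al <= 37.0):
            warnings.warn(
                f"axial length {al} mm for eye {self.eye_id!r} outside the "
                "typical 21-37 mm range",
                stacklevel=2,
            )
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")


@dataclass
class BScanContour:
    """A conditioned retinal contour for one B scan, in millimetres."""

    eye: EyeRecord
    region: str
    cube_id: str
    scan_index: int
    x_mm: np.ndarray
    z_mm: np.ndarray
    dx_mm: float
    n_samples: int = field(init=False)

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        if self.x_mm.shape != self.z_mm.shape or self.x_mm.ndim != 1:
            raise ContourError("x and z must be 1-D arrays of equal length")
        if self.x_mm.size < MIN_TRACE_SAMPLES:
            raise ShortTraceError(
                f"trace of {self.x_mm.size} samples is shorter than the "
                f"{MIN_TRACE_SAMPLES}-sample minimum"
            )
        if np.any(~np.isfinite(self.z_mm)):
            raise ContourError("z contains non-finite values")
        steps = np.diff(self.x_mm)
        if np.any(steps <= 0):
            raise ContourError("x must be strictly increasing")
        if not np.allclose(steps, self.dx_mm, rtol=0, atol=1e-9):
            raise ContourError("x spacing must equal one pixel pitch everywhere")
        self.n_samples = int(self.x_mm.size)
        self.region = canonical_region(self.region)

    @property
    def identity(self) -> tuple[str, str, str, int]:
        return (self.eye.eye_id, self.region, self.cube_id, self.scan_index)

    @property
    def retinal_length_mm(self) -> float:
        """Physical extent of the traced retina in the window."""
        return self.n_samples * self.dx_mm


def read_contour_file(path: str | Path, spec: ScanSpec) -> np.ndarray:
    """Read a two-column (x_px, z_px) trace file.

    Whitespace- or comma-delimited numeric text; returns an (n, 2) float
    array in file order.  Points outside the scan window are rejected.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) != 2:
                raise ContourParseError(
                    f"{path}: line {lineno}: expected two columns, got {len(parts)}"
                )
            try:
                x, z = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ContourParseError(
                    f"{path}: line {lineno}: non-numeric row {stripped!r}"
                ) from exc
            if not (0 <= x <= spec.lateral_px - 1) or not (0 <= z <= spec.axial_px - 1):
                raise ContourError(
                    f"{path}: line {lineno}: point ({x}, {z}) outside the "
                    f"{spec.lateral_px}x{spec.axial_px} px window"
                )
            rows.append((x, z))
    if not rows:
        raise EmptyTraceError(f"{path}: empty trace")
    return np.asarray(rows, dtype=float)


def collapse_duplicate_x(points: np.ndarray) -> np.ndarray:
    """Replace duplicate x values by a single point with the mean z.

    Output x values are unique and sorted ascending.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise EmptyTraceError("no points to collapse")
    pts = pts.reshape(-1, 2)
    xs, inverse = np.unique(pts[:, 0], return_inverse=True)
    zsum = np.bincount(inverse, weights=pts[:, 1])
    counts = np.bincount(inverse)
    return np.column_stack([xs, zsum / counts])


def fill_gaps(points: np.ndarray) -> np.ndarray:
    """Fill gaps in the integer x sequence by linear interpolation of z."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 2:
        raise ContourError("cannot interpolate a trace with fewer than two points")
    x = pts[:, 0]
    if not np.allclose(x, np.round(x), atol=1e-6):
        raise ContourError("x positions must be integer pixels before gap filling")
    x = np.round(x).astype(int)
    if np.any(np.diff(x) <= 0):
        raise ContourError("x must be unique and sorted before gap filling")
    grid = np.arange(x[0], x[-1] + 1)
    z = np.interp(grid, x, pts[:, 1])
    return np.column_stack([grid.astype(float), z])


def to_millimetres(
    points: np.ndarray,
    spec: ScanSpec,
    *,
    eye: EyeRecord,
    region: str,
    cube_id: str,
    scan_index: int,
) -> BScanContour:
    """Convert a conditioned pixel sequence to a millimetre-space contour."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    x_mm = pts[:, 0] * spec.dx_mm
    z_mm = pts[:, 1] * spec.dz_mm
    return BScanContour(
        eye=eye, region=region, cube_id=cube_id, scan_index=scan_index,
        x_mm=x_mm, z_mm=z_mm, dx_mm=spec.dx_mm,
    )


def condition_trace(
    points: np.ndarray,
    spec: ScanSpec,
    *,
    eye: EyeRecord,
    region: str,
    cube_id: str,
    scan_index: int,
) -> BScanContour:
    """Full conditioning chain: collapse duplicates, fill gaps, convert to mm."""
    return to_millimetres(
        fill_gaps(collapse_duplicate_x(points)), spec,
        eye=eye, region=region, cube_id=cube_id, scan_index=scan_index,
    )


#: columns required in a cohort manifest CSV
MANIFEST_COLUMNS = (
    "eye_id", "axial_length_mm", "laterality", "session_id",
    "region", "cube_id", "scan_index", "contour_path",
)


@dataclass
class Cohort:
    """A loaded cohort: eye records plus conditioned B-scan contours."""

    eyes: dict[str, EyeRecord]
    contours: list[BScanContour]
    spec: ScanSpec
    rejections: list[tuple[tuple, str]] = field(default_factory=list)

    @property
    def n_eyes(self) -> int:
        return len(self.eyes)

    @property
    def n_scans(self) -> int:
        return len(self.contours)

    def axial_lengths(self) -> pd.Series:
        return pd.Series(
            {eid: e.axial_length_mm for eid, e in self.eyes.items()},
            name="axial_length_mm",
        )


def load_cohort(manifest: str | Path, root: str | Path | None = None,
                spec: ScanSpec | None = None) -> Cohort:
    """Load a cohort of traced contours described by a manifest CSV.

    The manifest has one row per B scan with columns
    ``eye_id, axial_length_mm, laterality, session_id, region, cube_id,
    scan_index, contour_path`` (paths relative to ``root``, which defaults
    to the manifest's directory).  Scans that fail conditioning are dropped
    with a logged reason; a missing contour file, missing axial length or
    unknown region label is fatal.
    """
    manifest = Path(manifest)
    root = Path(root) if root is not None else manifest.parent
    spec = spec or ScanSpec()
    table = pd.read_csv(manifest)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ContourError(f"manifest missing columns: {sorted(missing)}")

    eyes: dict[str, EyeRecord] = {}
    contours: list[BScanContour] = []
    rejections: list[tuple[tuple, str]] = []
    for row in table.itertuples(index=False):
        eye_id = str(row.eye_id)
        if pd.isna(row.axial_length_mm):
            raise ContourError(f"missing axial length for eye {eye_id!r}")
        region = canonical_region(row.region)
        if eye_id not in eyes:
            eyes[eye_id] = EyeRecord(
                eye_id=eye_id,
                axial_length_mm=float(row.axial_length_mm),
                laterality=str(row.laterality),
                session_id=str(row.session_id),
            )
        path = root / str(row.contour_path)
        if not path.exists():
            raise FileNotFoundError(f"contour file not found: {path}")
        identity = (eye_id, region, str(row.cube_id), int(row.scan_index))
        try:
            points = read_contour_file(path, spec)
            contour = condition_trace(
                points, spec, eye=eyes[eye_id], region=region,
                cube_id=str(row.cube_id), scan_index=int(row.scan_index),
            )
        except ContourError as exc:
            logger.warning("dropping scan %s: %s", identity, exc)
            rejections.append((identity, str(exc)))
            continue
        contours.append(contour)

    cohort = Cohort(eyes=eyes, contours=contours, spec=spec, rejections=rejections)
    logger.info(
        "loaded cohort: %d eyes, %d B scans (%d rejected)",
        cohort.n_eyes, cohort.n_scans, len(rejections),
    )
    return cohort
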