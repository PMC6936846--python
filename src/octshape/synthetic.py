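"""Synthetic OCT contour cohorts with axial-length-linked irregularity.

The generator renders, for every eye x gaze region x cube x B scan, a
pixel-space retinal trace with the statistical structure the analysis
assumes: a quadratic base contour (per-cube vertex curvature drawn around
the cohort-typical macular value), plus low-frequency sinusoidal
irregularity whose per-bin amplitude grows linearly with axial length,
plus per-scan nuisance variation — random sinusoid phases, vertical
offset, a small linear tilt (emulating acquisition rotation), lateral
placement of a possibly partial-window retina, and axial sampling noise.

Because each sinusoid is injected at an integer DFT bin of the full
window, a noise-free full-window scan round-trips exactly: the descriptor
pipeline recovers the injected amplitude at the injected bin.  Partial
windows exercise the zero-padding and length-correction paths.  Ground
truth (per-eye axial length, per-eye x region design amplitudes, per-cube
base curvature, per-scan extent and offsets) is returned alongside the
cohort so recovery can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import (
    REGIONS,
    BScanContour,
    Cohort,
    EyeRecord,
    ScanSpec,
    condition_trace,
)

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition defaults for a synthetic cohort.

    70 eyes with axial lengths spanning 21.1-36.9 mm, all 17 gaze regions,
    one cube of 21 B scans per region.  Base vertex curvature is centred
    at 0.013 mm^-1 (so K is near the typical macular median of
    0.026 mm^-1).  Irregularity rides on bins 2-12: the per-eye design
    amplitude grows linearly with axial length
    (floor + slope * (AL - AL_low)), jittered multiplicatively per
    eye x region, and each B scan expresses it on a random subset of the
    bins (each active with ``bin_activation_prob``) with per-scan lognormal
    amplitude scatter — successive slices through a bumpy surface carry
    different low-frequency content.  Anterior regions show only part of
    the window.
    """

    n_eyes: int = 70
    al_range_mm: tuple[float, float] = (21.1, 36.9)
    base_curvature_mean: float = 0.013
    base_curvature_sd: float = 0.004
    irregularity_slope: float = 0.008
    base_irregularity_mm: float = 0.03
    irregularity_bins: tuple[int, ...] = tuple(range(2, 13))
    bin_activation_prob: float = 0.35
    amp_jitter_sd: float = 0.15
    scan_amp_jitter_sd: float = 0.3
    noise_sd_mm: float = 0.005
    tilt_sd: float = 0.02
    regions: tuple[str, ...] = REGIONS
    cubes_per_region: int = 1
    scans_per_cube: int = 21
    posterior_extent: tuple[float, float] = (0.8, 1.0)
    anterior_extent: tuple[float, float] = (0.45, 0.8)
    seed: int = 0
    spec: ScanSpec = field(default_factory=ScanSpec)

    def __post_init__(self) -> None:
        if self.n_eyes < 10:
            raise ValueError("synthetic cohorts need at least 10 eyes")
        if self.irregularity_slope < 0 or self.noise_sd_mm < 0 or self.amp_jitter_sd < 0:
            raise ValueError("slopes and standard deviations must be non-negative")
        if max(self.irregularity_bins, default=0) >= 30:
            raise ValueError("irregularity bins must lie below bin 30")


def design_amplitude(cfg: SynthConfig, axial_length_mm: float) -> float:
    """Noise-free per-bin amplitude law: floor + slope * (AL - AL_low)."""
    return cfg.base_irregularity_mm + cfg.irregularity_slope * (
        axial_length_mm - cfg.al_range_mm[0]
    )


def synth_contour(base_a: float, amplitudes: dict[int, float], *,
                  extent: float = 1.0, noise_sd: float = 0.0,
                  rng: np.random.Generator | None = None,
                  spec: ScanSpec | None = None,
                  eye: EyeRecord | None = None, region: str = "macula",
                  cube_id: str = "c0", scan_index: int = 0,
                  phases: dict[int, float] | None = None,
                  tilt: float = 0.0,
                  return_pixels: bool = False):
    """Render one synthetic B-scan contour.

    z(x) = z0 + tilt (x - xc) + base_a (x - x0)^2
           + sum_k A_k sin(2 pi k x / W + phi_k) + eps,

    sampled at pixel pitch over a sub-window covering ``extent`` of the
    lateral width, then passed through the standard ingest conditioning so
    the result is exactly what file-based ingestion would produce.  The
    sinusoid frequencies are cycles per full window width W, aligning bin k
    with DFT bin k for full-extent scans.
    """
    spec = spec or ScanSpec()
    rng = rng or np.random.default_rng(0)
    if not (0.2 < extent <= 1.0):
        raise ValueError(f"extent must be in (0.2, 1], got {extent}")
    eye = eye or EyeRecord(eye_id="synthetic", axial_length_mm=24.0)

    n = max(int(round(extent * spec.lateral_px)), 16)
    n = min(n, spec.lateral_px)
    i0 = int(rng.integers(0, spec.lateral_px - n + 1))
    i = np.arange(i0, i0 + n)
    x = i * spec.dx_mm
    w = spec.width_mm

    x0 = rng.uniform(x[0], x[-1])          # vertex somewhere in the visible span
    z = base_a * (x - x0) ** 2 + tilt * (x - x.mean())
    if phases is None:
        phases = {k: rng.uniform(0, TWO_PI) for k in sorted(amplitudes)}
    for k, amp in sorted(amplitudes.items()):
        z = z + amp * np.sin(TWO_PI * k * x / w + phases[k])
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=n)

    # place vertically inside the window with random translation headroom
    span = z.max() - z.min()
    if span >= spec.depth_mm:
        raise ValueError("synthetic contour exceeds the axial window depth")
    margin = spec.depth_mm - span
    z0 = rng.uniform(0.1, 0.9) * margin - z.min()
    z = z + z0

    points = np.column_stack([i.astype(float), z / spec.dz_mm])
    contour = condition_trace(points, spec, eye=eye, region=region,
                              cube_id=cube_id, scan_index=scan_index)
    if return_pixels:
        return contour, points
    return contour


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth and configuration."""

    cohort: Cohort
    ground_truth: pd.DataFrame
    config: SynthConfig
    amplitudes: dict[tuple[str, str], dict[int, float]]
    base_a: dict[tuple[str, str, str], float]
    session_id: str = "1"


def _extent_range(cfg: SynthConfig, region: str) -> tuple[float, float]:
    return cfg.anterior_extent if region.startswith("anterior") else cfg.posterior_extent


def _scan_amplitudes(rng: np.random.Generator, cfg: SynthConfig,
                     region_amps: dict[int, float]) -> dict[int, float]:
    """Per-scan expression of a region's design amplitudes.

    Each irregularity bin is active with probability
    ``bin_activation_prob`` and carries lognormal per-scan scatter, so
    successive B scans through the same region differ in which frequencies
    they show — the scan-to-scan variation the deviation features measure.
    """
    amps: dict[int, float] = {}
    for k in sorted(region_amps):
        active = rng.random() < cfg.bin_activation_prob
        scatter = float(np.exp(rng.normal(0.0, cfg.scan_amp_jitter_sd)))
        if active:
            amps[k] = region_amps[k] * scatter
    return amps


def _render_scan(rng: np.random.Generator, cfg: SynthConfig, base_a: float,
                 region_amps: dict[int, float], eye: EyeRecord, region: str,
                 cube_id: str, scan_index: int) -> tuple[BScanContour, float]:
    """Render one scan, redrawing nuisance variables if the trace would
    overflow the axial window (rare at default amplitudes)."""
    lo, hi = _extent_range(cfg, region)
    for _ in range(20):
        extent = float(rng.uniform(lo, hi))
        tilt = float(rng.normal(0.0, cfg.tilt_sd))
        amps = _scan_amplitudes(rng, cfg, region_amps)
        try:
            contour = synth_contour(
                base_a, amps, extent=extent, noise_sd=cfg.noise_sd_mm,
                rng=rng, spec=cfg.spec, eye=eye, region=region,
                cube_id=cube_id, scan_index=scan_index, tilt=tilt,
            )
            return contour, extent
        except ValueError:
            continue
    raise RuntimeError(
        f"could not render scan {eye.eye_id}/{region}/{scan_index} within "
        "the axial window; amplitudes are too large for the scan depth"
    )


def synth_cohort(cfg: SynthConfig) -> SyntheticCohort:
    """Generate a full cohort of contours with ground truth, in memory.

    Axial lengths are uniform on ``al_range_mm``; each eye x region gets
    design amplitude floor + slope * (AL - AL_low) per irregularity bin,
    times exp(N(0, amp_jitter_sd)) jitter shared across the region's
    scans.  Deterministic for a given config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.spec
    als = np.sort(rng.uniform(*cfg.al_range_mm, size=cfg.n_eyes))
    eyes: dict[str, EyeRecord] = {}
    contours: list[BScanContour] = []
    amplitudes: dict[tuple[str, str], dict[int, float]] = {}
    base_a_map: dict[tuple[str, str, str], float] = {}
    truth_rows = []

    for e, al in enumerate(als):
        eye_id = f"eye{e:03d}"
        eye = EyeRecord(eye_id=eye_id, axial_length_mm=float(al),
                        laterality="right" if e % 2 == 0 else "left")
        eyes[eye_id] = eye
        design = design_amplitude(cfg, al)
        for region in cfg.regions:
            jitter = float(np.exp(rng.normal(0.0, cfg.amp_jitter_sd))) \
                if cfg.amp_jitter_sd > 0 else 1.0
            amps = {k: design * jitter for k in cfg.irregularity_bins}
            amplitudes[(eye_id, region)] = amps
            for c in range(cfg.cubes_per_region):
                cube_id = f"{region.replace(' ', '_')}-c{c}"
                base_a = float(rng.normal(cfg.base_curvature_mean,
                                          cfg.base_curvature_sd))
                base_a_map[(eye_id, region, cube_id)] = base_a
                for s in range(cfg.scans_per_cube):
                    contour, extent = _render_scan(
                        rng, cfg, base_a, amps, eye, region, cube_id, s)
                    contours.append(contour)
                    truth_rows.append({
                        "eye_id": eye_id, "axial_length_mm": float(al),
                        "region": region, "cube_id": cube_id, "scan_index": s,
                        "base_a": base_a, "design_amplitude": design,
                        "jitter": jitter, "extent": extent,
                        "n_samples": contour.n_samples,
                    })

    cohort = Cohort(eyes=eyes, contours=contours, spec=spec)
    return SyntheticCohort(cohort=cohort, ground_truth=pd.DataFrame(truth_rows),
                           config=cfg, amplitudes=amplitudes, base_a=base_a_map)


def synth_repeat_session(synth: SyntheticCohort, seed: int,
                         *, session_id: str = "2",
                         amplitude_scale: float = 1.0) -> SyntheticCohort:
    """Re-render the same eyes as a second scanning session.

    Eye identities, design amplitudes (optionally scaled) and cube base
    curvatures are preserved; phases, window placement, extents, tilts and
    noise are redrawn, emulating re-imaging the same retina on another day.
    """
    cfg = synth.config
    rng = np.random.default_rng(seed)
    eyes = {
        eid: replace(eye, session_id=session_id)
        for eid, eye in synth.cohort.eyes.items()
    }
    contours: list[BScanContour] = []
    truth_rows = []
    for (eye_id, region, cube_id), base_a in synth.base_a.items():
        eye = eyes[eye_id]
        amps = {k: a * amplitude_scale
                for k, a in synth.amplitudes[(eye_id, region)].items()}
        for s in range(cfg.scans_per_cube):
            contour, extent = _render_scan(
                rng, cfg, base_a, amps, eye, region, cube_id, s)
            contours.append(contour)
            truth_rows.append({
                "eye_id": eye_id, "region": region, "cube_id": cube_id,
                "scan_index": s, "extent": extent,
            })
    cohort = Cohort(eyes=eyes, contours=contours, spec=cfg.spec)
    return SyntheticCohort(cohort=cohort, ground_truth=pd.DataFrame(truth_rows),
                           config=cfg, amplitudes=synth.amplitudes,
                           base_a=synth.base_a, session_id=session_id)


def write_cohort(synth: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a synthetic cohort as contour files plus a manifest CSV.

    Produces the exact layout ``contours.load_cohort`` consumes:
    ``manifest.csv``, ``ground_truth.csv`` and one two-column text file per
    B scan under ``contours/``.  Pixel coordinates are written at full
    precision so a file round trip is lossless.
    """
    out = Path(out_dir)
    (out / "contours").mkdir(parents=True, exist_ok=True)
    spec = synth.cohort.spec
    rows = []
    for contour in synth.cohort.contours:
        eye_id, region, cube_id, scan_index = contour.identity
        rel = Path("contours") / eye_id / f"{cube_id}_s{scan_index:02d}.txt"
        (out / rel).parent.mkdir(parents=True, exist_ok=True)
        x_px = contour.x_mm / spec.dx_mm
        z_px = contour.z_mm / spec.dz_mm
        np.savetxt(out / rel, np.column_stack([x_px, z_px]), fmt="%.17g")
        eye = contour.eye
        rows.append({
            "eye_id": eye_id, "axial_length_mm": eye.axial_length_mm,
            "laterality": eye.laterality, "session_id": eye.session_id,
            "region": region, "cube_id": cube_id, "scan_index": scan_index,
            "contour_path": rel.as_posix(),
        })
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    synth.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return out / "manifest.csv"
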