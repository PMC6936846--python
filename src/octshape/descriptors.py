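"""Per-B-scan shape descriptors: vertex curvature and residual spectrum.

Each conditioned contour z(x) is summarised by two orientation-robust
quantities:

* ``K`` — the curvature at the vertex of the best-fit quadratic
  z = a x^2 + b x + c, which for a parabola is simply 2a (the vertex is
  where the slope vanishes, so the full curvature expression
  z'' / (1 + z'^2)^{3/2} reduces to z'' = 2a).  Longer eyes distort the
  measured curvature optically, so K is corrected via the radius of
  curvature: r = 1/K_raw, r' = r - dr(AL), K = 1/r', with dr taken from a
  second-order polynomial through a table of per-axial-length corrections.

* a 30-bin Fourier modulus vector of the residual z - fit.  The residual is
  padded with zeros (or symmetrically cut) to 1024 samples, transformed
  with a 1024-point DFT, and the moduli of the 30 lowest frequency bins are
  scaled by 2/n_signal so that a full-window sinusoid of amplitude A mm at
  an integer bin reads as a modulus of A mm regardless of how much of the
  window the retina crosses.

Because the DFT modulus ignores phase and the quadratic fit absorbs
vertical offset and tilt, the descriptor is invariant to where in the scan
window the retina sits and to small rotations of the acquisition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .contours import BScanContour

logger = logging.getLogger(__name__)

N_FFT = 1024
N_BINS = 30

#: supported length-correction variants for the spectrum moduli:
#: multiplier applied to the raw DFT modulus |Z_k|.
NORMALIZATIONS = ("amplitude", "inverse_n", "fft_length")


class DescriptorError(ValueError):
    pass


class SingularCorrectionError(DescriptorError):
    """Raised when the corrected radius of curvature passes through zero."""


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic z = a x^2 + b x + c (mm units)."""

    a: float
    b: float
    c: float
    rss: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c


def fit_quadratic(contour: BScanContour) -> QuadraticFit:
    """Ordinary least-squares quadratic fit to a contour, in mm."""
    x, z = contour.x_mm, contour.z_mm
    if np.ptp(x) == 0:
        raise DescriptorError("degenerate contour: all x equal")
    coeffs = np.polyfit(x, z, 2)
    resid = z - np.polyval(coeffs, x)
    return QuadraticFit(a=float(coeffs[0]), b=float(coeffs[1]),
                        c=float(coeffs[2]), rss=float(resid @ resid))


def vertex_curvature(fit: QuadraticFit) -> float:
    """Curvature of the fitted parabola at its vertex: K_raw = 2a.

    Positive when the contour is concave toward the vitreous (a > 0 with z
    increasing posteriorly); negative curvature means convex into the eye,
    as at the edge of a staphyloma.
    """
    return 2.0 * fit.a


class CurvatureCorrection:
    """Axial-length-dependent radius-of-curvature correction.

    Built from a table of (axial length mm, delta r mm) pairs, typically at
    integer axial lengths 21-28 mm; evaluation at arbitrary axial length
    uses a second-order polynomial fitted to the table, with extrapolation
    outside the tabulated range logged.  ``CurvatureCorrection.zero()``
    gives the identity correction (all delta r = 0) — a documented
    placeholder: real analyses should supply a device-appropriate table.
    """

    def __init__(self, table: list[tuple[float, float]]):
        if len(table) < 3:
            raise DescriptorError("correction table needs at least 3 entries")
        self.table = [(float(al), float(dr)) for al, dr in sorted(table)]
        als = np.array([al for al, _ in self.table])
        drs = np.array([dr for _, dr in self.table])
        if np.any(np.diff(als) <= 0):
            raise DescriptorError("correction table axial lengths must be unique")
        self.poly = np.polyfit(als, drs, 2)
        self._al_range = (als[0], als[-1])
        fitted = np.polyval(self.poly, als)
        self.fit_rms = float(np.sqrt(np.mean((fitted - drs) ** 2)))

    @classmethod
    def zero(cls) -> "CurvatureCorrection":
        """Identity correction (delta r = 0 at every axial length)."""
        return cls([(21.0, 0.0), (24.0, 0.0), (28.0, 0.0)])

    @classmethod
    def from_csv(cls, path) -> "CurvatureCorrection":
        frame = pd.read_csv(path)
        return cls(list(zip(frame["axial_length_mm"], frame["delta_r_mm"])))

    def delta_r(self, axial_length_mm: float) -> float:
        """Radius correction dr (mm) at the given axial length."""
        al = float(axial_length_mm)
        if not (15.0 <= al <= 40.0):
            raise DescriptorError(f"axial length {al} mm outside supported range")
        lo, hi = self._al_range
        if al < lo or al > hi:
            logger.debug("extrapolating curvature correction to AL %.2f mm", al)
        return float(np.polyval(self.poly, al))


def correct_curvature(k_raw: float, axial_length_mm: float,
                      corr: CurvatureCorrection) -> float:
    """Apply the axial-length correction to a raw vertex curvature.

    Converts to radius of curvature, deducts the correction, and converts
    back.  K_raw = 0 (infinite radius) is returned unchanged.
    """
    if k_raw == 0.0:
        return 0.0
    r = 1.0 / k_raw
    denom = r - corr.delta_r(axial_length_mm)
    if abs(denom) < 1e-9 * max(1.0, abs(r)):
        raise SingularCorrectionError(
            f"corrected radius vanished (r = {r}, AL = {axial_length_mm})"
        )
    return 1.0 / denom


def residual_signal(contour: BScanContour, fit: QuadraticFit) -> np.ndarray:
    """Residual of the contour about its best-fit quadratic (mm).

    Subtracting the fit before the DFT avoids spectral contamination from
    endpoint mismatch; the least-squares residual is zero-mean.
    """
    return contour.z_mm - fit.predict(contour.x_mm)


def condition_signal(residual: np.ndarray, n_fft: int = N_FFT) -> tuple[np.ndarray, int]:
    """Pad (trailing zeros) or symmetrically cut a residual to ``n_fft``.

    Returns the fixed-length signal and the real-sample count n_signal.
    Short signals keep all samples followed by zeros; long signals lose
    floor(excess/2) samples from the start and the remainder from the end.
    """
    residual = np.asarray(residual, dtype=float)
    n = residual.size
    if n < MIN_SIGNAL:
        raise DescriptorError(f"residual of {n} samples is too short")
    if n <= n_fft:
        out = np.zeros(n_fft)
        out[:n] = residual
        return out, n
    excess = n - n_fft
    start = excess // 2
    return residual[start:start + n_fft].copy(), n_fft


MIN_SIGNAL = 16


@dataclass(frozen=True)
class ShapeSpectrum:
    """Length-corrected moduli of the 30 lowest DFT frequency bins (mm)."""

    moduli: np.ndarray
    n_signal: int
    n_fft: int = N_FFT

    def __post_init__(self) -> None:
        object.__setattr__(self, "moduli", np.asarray(self.moduli, dtype=float))
        if self.moduli.shape != (N_BINS,):
            raise DescriptorError(f"expected {N_BINS} moduli, got {self.moduli.shape}")
        if np.any(~np.isfinite(self.moduli)) or np.any(self.moduli < 0):
            raise DescriptorError("moduli must be finite and non-negative")
        if self.n_signal > self.n_fft:
            raise DescriptorError("n_signal cannot exceed n_fft")

    @property
    def nyquist_bins(self) -> int:
        return self.n_fft // 2

    @property
    def sum_bins(self) -> float:
        """Total irregularity: sum of the 30 bin moduli (mm)."""
        return float(self.moduli.sum())


def _length_factor(n_signal: int, n_fft: int, normalization: str) -> float:
    if normalization == "amplitude":
        return 2.0 / n_signal
    if normalization == "inverse_n":
        return 1.0 / n_signal
    if normalization == "fft_length":
        return n_fft / n_signal
    raise DescriptorError(
        f"unknown normalization {normalization!r}; choose from {NORMALIZATIONS}"
    )


def spectrum(signal: np.ndarray, n_signal: int, *,
             normalization: str = "amplitude") -> ShapeSpectrum:
    """DFT modulus spectrum of a conditioned (length-1024) residual.

    The raw 1024-point DFT moduli of bins 0..29 are multiplied by a
    length-correction factor (default 2/n_signal) so that scans in which
    the retina crosses only part of the window remain comparable to
    full-window scans.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size != N_FFT:
        raise DescriptorError(f"signal must have length {N_FFT}, got {signal.size}")
    if n_signal < MIN_SIGNAL:
        raise DescriptorError(f"n_signal must be at least {MIN_SIGNAL}")
    raw = np.abs(np.fft.rfft(signal)[:N_BINS])
    factor = _length_factor(n_signal, N_FFT, normalization)
    return ShapeSpectrum(moduli=factor * raw, n_signal=int(n_signal))


@dataclass(frozen=True)
class ShapeDescriptor:
    """Shape summary of one B scan: corrected K plus the residual spectrum."""

    identity: tuple[str, str, str, int]
    K: float
    K_raw: float
    spectrum: ShapeSpectrum
    retinal_length_mm: float
    axial_length_mm: float


def describe_bscan(contour: BScanContour, corr: CurvatureCorrection,
                   *, normalization: str = "amplitude") -> ShapeDescriptor:
    """Run the full descriptor chain on one conditioned contour."""
    fit = fit_quadratic(contour)
    k_raw = vertex_curvature(fit)
    al = contour.eye.axial_length_mm
    k = correct_curvature(k_raw, al, corr)
    signal, n_signal = condition_signal(residual_signal(contour, fit))
    spec = spectrum(signal, n_signal, normalization=normalization)
    return ShapeDescriptor(
        identity=contour.identity,
        K=k, K_raw=k_raw,
        spectrum=spec,
        retinal_length_mm=contour.retinal_length_mm,
        axial_length_mm=al,
    )


MODULUS_COLUMNS = tuple(f"m{k}" for k in range(N_BINS))

DESCRIPTOR_COLUMNS = (
    "eye_id", "region", "cube_id", "scan_index",
    "axial_length_mm", "K_raw", "K", "retinal_length_mm", "sum_bins",
) + MODULUS_COLUMNS


class ContourShapeTransformer(BaseEstimator, TransformerMixin):
    """Transform conditioned contours into a per-B-scan descriptor table.

    Parameters
    ----------
    correction : CurvatureCorrection or None
        Axial-length curvature correction; ``None`` means the identity
        (zero) correction.
    normalization : str
        Spectrum length-correction variant (see ``NORMALIZATIONS``).

    The transformer is stateless (``fit`` only validates); ``transform``
    accepts an iterable of ``BScanContour`` and returns a DataFrame with
    identity columns, K_raw, K, retinal_length_mm, sum_bins and m0..m29.
    Scans whose correction is singular are dropped with a log entry.
    """

    def __init__(self, correction: CurvatureCorrection | None = None,
                 normalization: str = "amplitude"):
        self.correction = correction
        self.normalization = normalization

    def fit(self, X, y=None):
        _length_factor(N_FFT, N_FFT, self.normalization)  # validate choice
        self.correction_ = self.correction or CurvatureCorrection.zero()
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "correction_")
        rows = []
        for contour in X:
            try:
                d = describe_bscan(contour, self.correction_,
                                   normalization=self.normalization)
            except SingularCorrectionError as exc:
                logger.warning("dropping scan %s: %s", contour.identity, exc)
                continue
            eye_id, region, cube_id, scan_index = d.identity
            rows.append(
                (eye_id, region, cube_id, scan_index, d.axial_length_mm,
                 d.K_raw, d.K, d.retinal_length_mm, d.spectrum.sum_bins,
                 *d.spectrum.moduli)
            )
        return pd.DataFrame(rows, columns=list(DESCRIPTOR_COLUMNS))


def describe_cohort(contours, correction: CurvatureCorrection | None = None,
                    *, normalization: str = "amplitude") -> pd.DataFrame:
    """Descriptor table for an iterable of contours (functional wrapper)."""
    return ContourShapeTransformer(
        correction=correction, normalization=normalization
    ).fit(None).transform(contours)
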