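"""The spectral invasion phenotype of a closed organoid boundary.

A traced boundary is a closed polygon of V vertices.  The pipeline is:

1. contour length  L = sum of Euclidean edge lengths with periodic wrap;
2. resampling to M points with equal arc spacing L/M by linear interpolation
   along the polyline (M = 256 by default);
3. an unnormalized forward DFT of the x and y coordinate sequences
   separately, giving complex half-spectra x̂_k, ŷ_k for k = 0 … M/2;
4. per-mode power P_k = |x̂_k|² + |ŷ_k|², with P_0 (the centroid term)
   discarded and all modes normalized by the first-harmonic power P_1
   (a unit circle has all its power in mode 1);
5. the weighted spectral power

       w = Σ_{k=2}^{M/2} (M/π)² sin²(πk/M) cos²(πk/M) · P_k / P_1,

   where the sin² factor acts as a smoothing (low-pass) filter suppressing
   pixelation artifacts near the Nyquist mode and the cos²·(M/π)² factor is
   a discrete derivative emphasizing curvature; at small k the combined
   weight approaches k².

The phenotype w is invariant to translation (P_0 dropped), rotation (P_k is
a squared modulus of both coordinates), uniform scaling (P_1 normalization)
and choice of starting vertex (cyclic shifts only rotate Fourier phases).
Higher w means a more convoluted, invasive boundary; downstream statistics
use y = log10 w, which is undefined for a mathematically perfect circle
(w = 0) — such shapes are flagged and excluded from log-scale analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from invaspect.exceptions import DegenerateBoundaryError, UndefinedPhenotypeError
from invaspect.io import RawBoundary

__all__ = [
    "ResampledContour",
    "BoundarySpectrum",
    "SpectralPhenotype",
    "contour_length",
    "resample_equal_arc",
    "polygon_area",
    "effective_diameter",
    "boundary_spectrum",
    "spectral_weight",
    "weighted_spectral_power",
    "log_phenotype",
    "phenotype",
]

DEFAULT_M = 256


@dataclass(frozen=True)
class ResampledContour:
    """M equally arc-spaced points along a closed boundary of length L."""

    points: np.ndarray  # (M, 2), pixel units
    source_length: float  # L, pixel units

    @property
    def m(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class BoundarySpectrum:
    """Half-spectrum DFT amplitudes of the resampled contour and per-mode power."""

    xhat: np.ndarray  # complex, k = 0 … M/2
    yhat: np.ndarray
    power: np.ndarray  # P_k = |x̂_k|² + |ŷ_k|²
    m: int  # number of resampled points


@dataclass(frozen=True)
class SpectralPhenotype:
    """The per-organoid phenotype record: weighted power plus size measures."""

    w: float
    log10_w: float  # NaN when w == 0
    area_px2: float
    effective_diameter_px: float
    contour_length_px: float
    n_vertices: int
    mode_k: np.ndarray  # k = 2 … M/2
    mode_weighted_power: np.ndarray  # weight(k) · P_k / P_1, the fingerprint


def _closed_edges(vertices: np.ndarray) -> np.ndarray:
    """Edge vectors of the closed polygon, including the wrap-around edge."""
    return np.roll(vertices, -1, axis=0) - vertices


def contour_length(boundary: RawBoundary | np.ndarray) -> float:
    """Total perimeter of the closed polygon (periodic wrap included)."""
    v = boundary.vertices if isinstance(boundary, RawBoundary) else np.asarray(boundary, float)
    if len(v) < 3:
        raise DegenerateBoundaryError("contour length requires at least 3 vertices")
    return float(np.linalg.norm(_closed_edges(v), axis=1).sum())


def resample_equal_arc(boundary: RawBoundary | np.ndarray, m: int = DEFAULT_M) -> ResampledContour:
    """Resample the closed polyline at M points with equal arc spacing L/M.

    Point j sits at arc-length position j·L/M from vertex 0, linearly
    interpolated between the bracketing trace vertices.
    """
    if m < 4 or m % 2:
        raise ValueError("M must be an even integer >= 4")
    v = boundary.vertices if isinstance(boundary, RawBoundary) else np.asarray(boundary, float)
    if len(v) < 3:
        raise DegenerateBoundaryError("resampling requires at least 3 vertices")
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = s[-1]
    if length == 0.0:
        raise DegenerateBoundaryError("zero contour length")
    targets = np.arange(m) * (length / m)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return ResampledContour(points=np.column_stack([x, y]), source_length=length)


def polygon_area(contour: ResampledContour | np.ndarray) -> float:
    """Absolute shoelace area of the closed polygon (orientation-independent)."""
    pts = contour.points if isinstance(contour, ResampledContour) else np.asarray(contour, float)
    x, y = pts[:, 0], pts[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed))


def effective_diameter(area: float) -> float:
    """Diameter of the circle with the given area: 2·sqrt(area/π)."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return float(2.0 * np.sqrt(area / np.pi))


def boundary_spectrum(contour: ResampledContour | np.ndarray) -> BoundarySpectrum:
    """Unnormalized forward DFT half-spectrum of the x and y coordinate signals."""
    pts = contour.points if isinstance(contour, ResampledContour) else np.asarray(contour, float)
    m = len(pts)
    if m % 2:
        raise ValueError("spectrum requires an even number of points")
    xhat = np.fft.rfft(pts[:, 0])
    yhat = np.fft.rfft(pts[:, 1])
    power = np.abs(xhat) ** 2 + np.abs(yhat) ** 2
    return BoundarySpectrum(xhat=xhat, yhat=yhat, power=power, m=m)


def spectral_weight(k: np.ndarray | float, m: int) -> np.ndarray | float:
    """Mode weight (M/π)² sin²(πk/M) cos²(πk/M).

    Product of a smoothing filter and a discrete-derivative filter applied in
    the spectral domain; ~k² for k ≪ M and exactly 0 at the Nyquist mode.
    """
    phase = np.pi * np.asarray(k, dtype=float) / m
    return (m / np.pi) ** 2 * np.sin(phase) ** 2 * np.cos(phase) ** 2


def weighted_spectral_power(spectrum: BoundarySpectrum) -> float:
    """Weighted sum of normalized mode powers for k = 2 … M/2.

    P_0 (centroid) is discarded for translation invariance and each mode is
    normalized by P_1 for scale invariance.
    """
    p1 = spectrum.power[1]
    if p1 <= 0.0:
        raise UndefinedPhenotypeError("no first-harmonic power; phenotype undefined")
    k = np.arange(2, spectrum.m // 2 + 1)
    return float(np.sum(spectral_weight(k, spectrum.m) * spectrum.power[2:] / p1))


def log_phenotype(w: float) -> float:
    """Base-10 logarithm of the weighted spectral power; requires w > 0."""
    if w <= 0:
        raise UndefinedPhenotypeError("log10 phenotype undefined for w <= 0")
    return float(np.log10(w))


def phenotype(boundary: RawBoundary | np.ndarray, m: int = DEFAULT_M) -> SpectralPhenotype:
    """Full phenotype record for one boundary: w, log10 w, area and size.

    A perfectly circular boundary has w = 0; its log phenotype is NaN and a
    warning is emitted so it can be excluded from log-scale statistics.
    """
    contour = resample_equal_arc(boundary, m)
    spectrum = boundary_spectrum(contour)
    w = weighted_spectral_power(spectrum)
    if w > 0:
        log_w = float(np.log10(w))
    else:
        warnings.warn("weighted spectral power is 0 (circle-perfect shape); "
                      "log phenotype undefined", stacklevel=2)
        log_w = float("nan")
    area = polygon_area(contour)
    k = np.arange(2, spectrum.m // 2 + 1)
    n_vertices = boundary.n_vertices if isinstance(boundary, RawBoundary) else len(boundary)
    return SpectralPhenotype(
        w=w,
        log10_w=log_w,
        area_px2=area,
        effective_diameter_px=effective_diameter(area),
        contour_length_px=contour.source_length,
        n_vertices=n_vertices,
        mode_k=k,
        mode_weighted_power=spectral_weight(k, spectrum.m) * spectrum.power[2:] / spectrum.power[1],
    )
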