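"""The spectral phenotype: geometry, DFT power, weighting, and invariances."""

import cmath

import numpy as np
import pytest

from invaspect.exceptions import DegenerateBoundaryError, UndefinedPhenotypeError
from invaspect.io import RawBoundary
from invaspect.spectral import (
    boundary_spectrum,
    contour_length,
    effective_diameter,
    log_phenotype,
    phenotype,
    polygon_area,
    resample_equal_arc,
    spectral_weight,
    weighted_spectral_power,
)


def _circle_points(m: int) -> np.ndarray:
    j = np.arange(m)
    return np.column_stack([np.cos(2 * np.pi * j / m), np.sin(2 * np.pi * j / m)])


def _weighted_power_oracle(points: np.ndarray) -> float:
    """Term-by-term evaluation from a separately coded DFT (independent oracle)."""
    m = len(points)
    x, y = points[:, 0], points[:, 1]
    power = []
    for k in range(m // 2 + 1):
        xh = sum(x[j] * cmath.exp(-2j * cmath.pi * j * k / m) for j in range(m))
        yh = sum(y[j] * cmath.exp(-2j * cmath.pi * j * k / m) for j in range(m))
        power.append(abs(xh) ** 2 + abs(yh) ** 2)
    return sum(
        (m / np.pi) ** 2 * np.sin(np.pi * k / m) ** 2 * np.cos(np.pi * k / m) ** 2
        * power[k] / power[1]
        for k in range(2, m // 2 + 1)
    )


class TestContourLength:
    def test_unit_square(self, unit_square):
        assert contour_length(unit_square) == pytest.approx(4.0)

    def test_triangle(self, right_triangle):
        assert contour_length(right_triangle) == pytest.approx(2 + np.sqrt(2))

    def test_regular_polygon_closed_form(self):
        n = 1000
        theta = 2 * np.pi * np.arange(n) / n
        poly = np.column_stack([np.cos(theta), np.sin(theta)])
        assert contour_length(poly) == pytest.approx(2 * n * np.sin(np.pi / n))

    def test_degenerate(self):
        with pytest.raises(DegenerateBoundaryError):
            contour_length(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestResampling:
    def test_unit_square_m8_hits_corners_and_midpoints(self, unit_square):
        c = resample_equal_arc(unit_square, 8)
        expected = [[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1], [0.5, 1], [0, 1], [0, 0.5]]
        np.testing.assert_allclose(c.points, expected, atol=1e-12)

    def test_equal_arc_spacing_defining_property(self, star_shape):
        """Consecutive sample points sit L/M apart in arc length along the polyline."""
        c = resample_equal_arc(star_shape, 256)
        v = star_shape.vertices
        closed = np.vstack([v, v[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        # arc-length position of each sample: locate its bracketing source edge
        positions = []
        for p in c.points:
            d = closed[:-1]
            e = np.diff(closed, axis=0)
            tt = np.einsum("ij,ij->i", p - d, e) / np.maximum(np.einsum("ij,ij->i", e, e), 1e-300)
            tt = np.clip(tt, 0, 1)
            proj = d + tt[:, None] * e
            i = int(np.argmin(np.linalg.norm(proj - p, axis=1)))
            positions.append(cum[i] + tt[i] * seg[i])
        gaps = np.diff(np.array(positions))
        np.testing.assert_allclose(gaps, c.source_length / 256, rtol=1e-9)

    def test_dense_circle_points_on_circle(self, dense_circle):
        c = resample_equal_arc(dense_circle, 256)
        radii = np.linalg.norm(c.points, axis=1)
        np.testing.assert_allclose(radii, 1.0, atol=1e-4)

    @pytest.mark.parametrize("m", [3, 7, 2])
    def test_bad_m_rejected(self, unit_square, m):
        with pytest.raises(ValueError):
            resample_equal_arc(unit_square, m)


class TestAreaAndDiameter:
    def test_unit_square_area(self, unit_square):
        assert polygon_area(resample_equal_arc(unit_square, 256)) == pytest.approx(1.0)

    def test_triangle_resampled_area(self, right_triangle):
        area = polygon_area(resample_equal_arc(right_triangle, 256))
        assert area == pytest.approx(0.5, abs=1e-3)

    def test_orientation_invariance(self, unit_square):
        reversed_square = RawBoundary(unit_square.vertices[::-1].copy())
        a1 = polygon_area(resample_equal_arc(unit_square, 64))
        a2 = polygon_area(resample_equal_arc(reversed_square, 64))
        assert a1 == pytest.approx(a2)

    @pytest.mark.parametrize("area,expected", [(np.pi, 2.0), (0.0, 0.0), (1.0, 1.1283791671)])
    def test_effective_diameter(self, area, expected):
        assert effective_diameter(area) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            effective_diameter(-1.0)


class TestSpectrum:
    def test_pure_first_harmonic(self):
        m = 256
        s = boundary_spectrum(_circle_points(m))
        assert s.power[1] == pytest.approx(m**2 / 2)
        assert np.all(s.power[2:] <= 1e-12 * s.power[1])

    def test_constant_points_have_no_power(self):
        s = boundary_spectrum(np.full((64, 2), 3.7))
        assert np.all(s.power[1:] == pytest.approx(0.0, abs=1e-18))

    def test_parseval(self, star_shape):
        c = resample_equal_arc(star_shape, 256)
        s = boundary_spectrum(c)
        m = s.m
        # expand half-spectrum by conjugate symmetry: interior modes count twice
        full = s.power.copy()
        full[1:-1] *= 2
        lhs = full.sum() / m
        rhs = float((c.points**2).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestWeightedPower:
    def test_exact_circle_w_zero(self):
        for m in (64, 256):
            s = boundary_spectrum(_circle_points(m))
            assert weighted_spectral_power(s) == pytest.approx(0.0, abs=1e-10)

    def test_weight_zero_at_nyquist(self):
        assert spectral_weight(128, 256) == pytest.approx(0.0, abs=1e-20)

    def test_weight_at_quarter_band(self):
        # (M/π)²·sin²(π/4)·cos²(π/4) = (M/π)²/4
        assert spectral_weight(64, 256) == pytest.approx(16384 / np.pi**2)

    def test_small_k_weight_ratio_approaches_k_squared(self):
        for k in range(1, 5):
            assert spectral_weight(k, 4096) / k**2 == pytest.approx(1.0, rel=0.01)

    def test_star_matches_independent_oracle(self, star_shape):
        c = resample_equal_arc(star_shape, 256)
        w = weighted_spectral_power(boundary_spectrum(c))
        assert w == pytest.approx(_weighted_power_oracle(c.points), rel=1e-6)

    def test_undefined_without_first_harmonic(self):
        s = boundary_spectrum(np.full((64, 2), 1.0))
        with pytest.raises(UndefinedPhenotypeError):
            weighted_spectral_power(s)


class TestLogPhenotype:
    @pytest.mark.parametrize("w,expected", [(1.0, 0.0), (100.0, 2.0)])
    def test_values(self, w, expected):
        assert log_phenotype(w) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(UndefinedPhenotypeError):
            log_phenotype(0.0)

    def test_star_log_matches_oracle(self, star_shape):
        c = resample_equal_arc(star_shape, 256)
        expected = np.log10(_weighted_power_oracle(c.points))
        assert phenotype(star_shape).log10_w == pytest.approx(expected, rel=1e-6)


class TestInvariances:
    """w is invariant to translation, rotation, scaling and start point."""

    def _w(self, vertices: np.ndarray) -> float:
        return phenotype(vertices).w

    def test_translation(self, star_shape):
        w0 = self._w(star_shape.vertices)
        w1 = self._w(star_shape.vertices + [123.4, -56.7])
        assert w1 == pytest.approx(w0, rel=1e-9)

    def test_rotation(self, star_shape):
        angle = 0.7
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        center = np.array([10.0, 20.0])
        moved = (star_shape.vertices - center) @ rot.T + center
        assert self._w(moved) == pytest.approx(self._w(star_shape.vertices), rel=1e-9)

    def test_scale(self, star_shape):
        assert self._w(star_shape.vertices * 37.5) == pytest.approx(
            self._w(star_shape.vertices), rel=1e-9)

    def test_start_point_cyclic_shift_exact(self, star_shape):
        c = resample_equal_arc(star_shape, 256)
        shifted = np.roll(c.points, 100, axis=0)
        p0 = boundary_spectrum(c.points).power
        p1 = boundary_spectrum(shifted).power
        # identical up to FFT round-off (absolute tolerance scaled to the spectrum)
        np.testing.assert_allclose(p1, p0, rtol=1e-9, atol=1e-12 * p0.max())

    def test_resolution_robustness_m256_vs_m128(self, star_shape):
        w256 = phenotype(star_shape, m=256).w
        w128 = phenotype(star_shape, m=128).w
        assert abs(w256 - w128) / w256 < 0.05

    def test_monotone_in_amplitude_and_mode(self):
        theta = 2 * np.pi * np.arange(4000) / 4000

        def w_of(a, m):
            r = 1 + a * np.cos(m * theta)
            return phenotype(np.column_stack([r * np.cos(theta), r * np.sin(theta)])).w

        amps = [w_of(a, 6) for a in (0.01, 0.02, 0.05, 0.1)]
        assert amps == sorted(amps)
        modes = [w_of(0.05, m) for m in (3, 5, 8, 12)]
        assert modes == sorted(modes)
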