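"""Reference densities: kernel UDs, isopleths, overlaps, buffers, areas."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from remcam.reference import (
    buffer_width,
    effective_area,
    fit_ud,
    isopleth,
    overlap_proportion,
    reference_density,
)
from remcam.types import UtilizationDistribution, ValidationError

GAUSS_75_AREA = 2 * math.log(4) * math.pi  # ~8.710 km^2 for sigma = 1 km


class TestUD:
    def test_mass_normalised(self, rng):
        ud = fit_ud(rng.standard_normal((50, 2)))
        assert ud.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_mode_near_true_mean(self, rng):
        pts = np.array([3.0, -2.0]) + rng.standard_normal((1000, 2))
        ud = fit_ud(pts)
        i, j = np.unravel_index(np.argmax(ud.mass), ud.mass.shape)
        x = ud.x0 + (i + 0.5) * ud.cell
        y = ud.y0 + (j + 0.5) * ud.cell
        assert math.hypot(x - 3.0, y + 2.0) < 0.2

    def test_translation_equivariance(self, rng):
        pts = rng.standard_normal((200, 2))
        ud1 = fit_ud(pts)
        ud2 = fit_ud(pts + np.array([5.0, -7.0]))
        assert np.allclose(ud1.mass, ud2.mass)
        assert ud2.x0 - ud1.x0 == pytest.approx(5.0)

    def test_identical_points_rejected(self):
        with pytest.raises(ValidationError, match="bandwidth"):
            fit_ud(np.zeros((10, 2)))

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValidationError, match=">= 5"):
            fit_ud(rng.standard_normal((4, 2)))


class TestIsopleth:
    def test_gaussian_closed_form_within_10_percent(self, rng):
        """75% region of a sigma=1 bivariate normal is a disc of area
        2*ln(4)*pi; the KDE reproduces it within 10% (reference-bandwidth
        smoothing inflates the area by about a factor 1 + n^(-1/3))."""
        pts = rng.standard_normal((1000, 2))
        hr = isopleth(fit_ud(pts), 0.75)
        assert abs(hr.area - GAUSS_75_AREA) / GAUSS_75_AREA < 0.10

    def test_nesting(self, rng):
        ud = fit_ud(rng.standard_normal((500, 2)))
        hr50 = isopleth(ud, 0.50)
        hr75 = isopleth(ud, 0.75)
        assert hr50.area < hr75.area
        assert hr50.polygon.within(hr75.polygon.buffer(1e-9))

    def test_uniform_square(self):
        mass = np.full((100, 100), 1e-4)
        ud = UtilizationDistribution(mass=mass, x0=0.0, y0=0.0, cell=0.1, bandwidth=0.4)
        hr = isopleth(ud, 0.75)
        assert hr.area == pytest.approx(75.0, rel=0.01)

    def test_bad_level_rejected(self, rng):
        ud = fit_ud(rng.standard_normal((50, 2)))
        with pytest.raises(ValidationError):
            isopleth(ud, 1.5)

    def test_cell_size_insensitivity(self, rng):
        """Halving the grid cell moves the Gaussian isopleth area by < 1%."""
        pts = rng.standard_normal((1000, 2))
        h = fit_ud(pts).bandwidth
        a1 = isopleth(fit_ud(pts, cell=h / 4), 0.75).area
        a2 = isopleth(fit_ud(pts, cell=h / 8), 0.75).area
        assert abs(a2 - a1) / a1 < 0.01


class TestOverlap:
    def test_fully_inside(self, rng):
        hr = isopleth(fit_ud(rng.standard_normal((200, 2))), 0.75)
        assert overlap_proportion(hr, box(-50, -50, 50, 50)) == pytest.approx(1.0)

    def test_symmetric_straddle(self):
        from remcam.types import HomeRange

        hr = HomeRange(pride_id="p", level=0.75, polygon=box(-2, -2, 2, 2), area=16.0)
        assert overlap_proportion(hr, box(0, -100, 100, 100)) == pytest.approx(0.5)

    def test_partition_sums_to_one(self, rng):
        hr = isopleth(fit_ud(rng.standard_normal((300, 2))), 0.75)
        west = box(-1000, -1000, 0.3, 1000)
        east = box(0.3, -1000, 1000, 1000)
        p = overlap_proportion(hr, west) + overlap_proportion(hr, east)
        assert p == pytest.approx(1.0, abs=1e-9)


class TestBufferWidth:
    @pytest.mark.parametrize(
        "mean_area,w_printed",
        [(49.1, 4.0), (46.6, 3.9), (78.0, 5.0), (51.6, 4.1)],
    )
    def test_circular_equivalent_radius_of_mean_area(self, mean_area, w_printed):
        # two areas with the required mean; w depends only on the mean
        areas = [mean_area - 5.0, mean_area + 5.0]
        bw = buffer_width(areas)
        assert round(bw.w, 1) == w_printed

    def test_unit_circle(self):
        assert buffer_width([math.pi]).w == pytest.approx(1.0)

    def test_ci_brackets_mean_radius(self):
        areas = [30.0, 50.0, 70.0]
        bw = buffer_width(areas)
        rho = np.sqrt(np.array(areas) / math.pi)
        assert bw.w_low < rho.mean() < bw.w_high
        bw_t = buffer_width(areas, quantile="t")
        assert bw_t.w_high > bw.w_high  # t wider than normal at n=3

    def test_mean_of_radii_option(self):
        areas = [10.0, 90.0]
        got = buffer_width(areas, method="mean_of_radii").w
        assert got == pytest.approx(np.sqrt(np.array(areas) / math.pi).mean())

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValidationError):
            buffer_width([10.0, -1.0])


class TestEffectiveArea:
    SQUARE = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])

    def test_unbuffered_square(self):
        assert effective_area(self.SQUARE, 0.0) == pytest.approx(100.0)

    def test_buffered_square_closed_form(self):
        a = effective_area(self.SQUARE, 1.0)
        assert a == pytest.approx(100.0 + 40.0 + math.pi, rel=1e-3)

    def test_habitat_intersection_halves(self):
        a_full = effective_area(self.SQUARE, 1.0)
        a_half = effective_area(self.SQUARE, 1.0, box(-10, -10, 5, 20))
        assert a_half == pytest.approx(a_full / 2, rel=1e-3)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValidationError, match="collinear"):
            effective_area(np.array([[0, 0], [1, 1], [2, 2]]), 1.0)


class TestReferenceDensity:
    def test_arithmetic(self):
        res = reference_density([(10, 0.5), (20, 1.0)], a=100.0)
        assert res.d_ref == pytest.approx(0.25)

    def test_all_zero_overlap(self):
        assert reference_density([(10, 0.0)], a=50.0).d_ref == 0.0

    def test_doubling_area_halves_density(self):
        d1 = reference_density([(10, 1.0)], a=100.0).d_ref
        d2 = reference_density([(10, 1.0)], a=200.0).d_ref
        assert d2 == pytest.approx(d1 / 2)

    def test_ci_monotone_in_buffer_width(self):
        """Larger buffer -> larger area -> smaller density, so the density CI
        comes from the buffer-width limits with endpoints swapped."""
        pts = TestEffectiveArea.SQUARE
        bw = buffer_width([40.0, 60.0])
        a = effective_area(pts, bw.w)
        a_lo = effective_area(pts, bw.w_low)
        a_hi = effective_area(pts, bw.w_high)
        assert a_lo < a < a_hi
        res = reference_density([(12, 1.0)], a, a_low=a_lo, a_high=a_hi)
        assert res.ci_low == pytest.approx(12 / a_hi)
        assert res.ci_high == pytest.approx(12 / a_lo)
        assert res.ci_low <= res.d_ref <= res.ci_high

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValidationError):
            reference_density([(10, 1.5)], a=10.0)
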