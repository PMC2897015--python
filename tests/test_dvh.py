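"""Core DVH machinery: rasterization, histograms, statistics, smoothing,
and the NRMSD/DTA comparison metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dvhkit.dvh import (
    CumulativeDVH,
    DifferentialDVH,
    StructureMask,
    compute_ddvh,
    cumulate,
    dta,
    dvh_statistics,
    nrmsd,
    rasterize_structure,
    smooth_cdvh,
)
from dvhkit.errors import (
    CurveTooShortError,
    DegenerateContourError,
    EmptyStructureError,
    StructureOutsideGridError,
)
from dvhkit.grid import DoseGrid, StructureContours
from dvhkit.phantom import analytic_cdvh
from dvhkit.plan_io import parse_poi_token

from conftest import pip_ray_casting


def _flat_grid(nx=20, ny=20, nz=1, spacing=1.0, origin=(0.5, 0.5, 0.0), dose=None):
    if dose is None:
        dose = np.zeros((nz, ny, nx))
    return DoseGrid(origin=np.array(origin), spacing=np.full(3, spacing), dose=dose)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

class TestRasterize:
    def test_axis_aligned_square_counts_100_voxels(self):
        """A 10x10 mm square with edges on integer mm contains exactly the
        100 voxels whose half-offset centres fall inside."""
        ring = np.array([[5.0, 5.0], [15.0, 5.0], [15.0, 15.0], [5.0, 15.0]])
        contours = StructureContours("sq", [(0.0, [ring])])
        grid = _flat_grid()
        mask = rasterize_structure(contours, grid)
        assert mask.member.sum() == 100
        assert mask.volume_cc == pytest.approx(100 * grid.voxel_volume_cc)

    def test_matches_ray_casting_oracle(self):
        """Membership equals an independent pure-Python ray-casting oracle
        over every voxel centre (non-convex polygon)."""
        ring = np.array([[3.2, 3.1], [16.7, 4.4], [14.9, 9.8], [8.3, 7.2],
                        [12.1, 15.6], [4.4, 13.9]])
        contours = StructureContours("poly", [(0.0, [ring])])
        grid = _flat_grid()
        mask = rasterize_structure(contours, grid)
        xs = grid.axis_centers(0)
        ys = grid.axis_centers(1)
        oracle = np.array([[pip_ray_casting([ring], x, y) for x in xs] for y in ys])
        assert np.array_equal(mask.member[0], oracle)

    def test_empty_contour_rejected(self):
        grid = _flat_grid()
        with pytest.raises(DegenerateContourError):
            rasterize_structure(StructureContours("e", []), grid)

    def test_two_point_ring_rejected(self):
        grid = _flat_grid()
        ring = np.array([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DegenerateContourError):
            rasterize_structure(StructureContours("seg", [(0.0, [ring])]), grid)

    def test_structure_outside_grid(self):
        grid = _flat_grid()
        ring = np.array([[5.0, 5.0], [15.0, 5.0], [10.0, 15.0]])
        with pytest.raises(StructureOutsideGridError):
            rasterize_structure(StructureContours("far", [(50.0, [ring])]), grid)

    def test_supersampled_circle_area_within_1pct(self):
        """Circle of radius 10 mm on a 1 mm grid, supersample 4: fractional
        membership recovers the polygon area to better than 1%."""
        theta = 2 * np.pi * np.arange(256) / 256
        ring = np.column_stack([15 + 10 * np.cos(theta), 15 + 10 * np.sin(theta)])
        contours = StructureContours("circ", [(0.0, [ring])])
        grid = _flat_grid(nx=30, ny=30)
        mask = rasterize_structure(contours, grid, supersample=4)
        area_mm2 = mask.frac.sum() * grid.spacing[0] * grid.spacing[1]
        assert area_mm2 == pytest.approx(np.pi * 100.0, rel=0.01)

    def test_inner_ring_carves_hole(self):
        outer = np.array([[2.0, 2.0], [18.0, 2.0], [18.0, 18.0], [2.0, 18.0]])
        inner = np.array([[8.0, 8.0], [12.0, 8.0], [12.0, 12.0], [8.0, 12.0]])
        grid = _flat_grid()
        mask = rasterize_structure(
            StructureContours("ann", [(0.0, [outer, inner])]), grid)
        assert mask.member.sum() == 16 * 16 - 4 * 4


# ---------------------------------------------------------------------------
# Differential DVH
# ---------------------------------------------------------------------------

class TestDifferential:
    def test_uniform_dose_single_bin(self):
        dose = np.full((2, 10, 10), 5000.0)
        grid = _flat_grid(nx=10, ny=10, nz=2, dose=dose)
        mask = StructureMask(grid=grid, frac=np.ones_like(dose))
        ddvh = compute_ddvh(grid, mask, bin_width=10.0)
        nz = np.nonzero(ddvh.bin_volumes)[0]
        assert nz.size == 1
        assert ddvh.bin_centers[nz[0]] == pytest.approx(5000.0)
        assert ddvh.bin_volumes[nz[0]] == pytest.approx(200 * grid.voxel_volume_cc)

    def test_two_level_equal_bins(self):
        dose = np.zeros((1, 10, 10))
        dose[0, :5] = 1000.0
        dose[0, 5:] = 2000.0
        grid = _flat_grid(nx=10, ny=10, dose=dose)
        mask = StructureMask(grid=grid, frac=np.ones_like(dose))
        ddvh = compute_ddvh(grid, mask, bin_width=100.0)
        occupied = ddvh.bin_volumes[ddvh.bin_volumes > 0]
        assert occupied.size == 2
        assert occupied[0] == pytest.approx(occupied[1])

    def test_empty_mask_rejected(self):
        grid = _flat_grid()
        mask = StructureMask(grid=grid, frac=np.zeros_like(grid.dose))
        with pytest.raises(EmptyStructureError):
            compute_ddvh(grid, mask)

    @given(st.integers(0, 2**31 - 1))
    def test_mass_conservation(self, seed):
        """Sum of bin volumes equals the fractional mask volume exactly."""
        rng = np.random.default_rng(seed)
        dose = rng.uniform(0, 6000, size=(3, 8, 8))
        frac = rng.uniform(0, 1, size=dose.shape) * (rng.random(dose.shape) < 0.7)
        if not (frac > 0).any():
            frac[0, 0, 0] = 1.0
        grid = _flat_grid(nx=8, ny=8, nz=3, dose=dose)
        mask = StructureMask(grid=grid, frac=frac)
        ddvh = compute_ddvh(grid, mask, bin_width=37.0)
        assert ddvh.total_volume_cc == pytest.approx(mask.volume_cc, abs=1e-12)


# ---------------------------------------------------------------------------
# Cumulative DVH
# ---------------------------------------------------------------------------

class TestCumulative:
    def _two_level(self):
        dose = np.zeros((1, 10, 10))
        dose[0, :5] = 1000.0
        dose[0, 5:] = 2000.0
        grid = _flat_grid(nx=10, ny=10, dose=dose)
        mask = StructureMask(grid=grid, frac=np.ones_like(dose))
        return cumulate(compute_ddvh(grid, mask, bin_width=4.0))

    def test_two_level_curve_values(self):
        cdvh = self._two_level()
        total = cdvh.total_volume_cc
        assert cdvh.volume_at_dose(0.0) == pytest.approx(total)
        assert cdvh.volume_at_dose(1500.0) == pytest.approx(0.5 * total)
        assert cdvh.volume_at_dose(2500.0) == 0.0

    def test_monotone_non_increasing(self):
        cdvh = self._two_level()
        assert np.all(np.diff(cdvh.volume_cc) <= 0)

    def test_default_sampling_gives_501_points(self, falloff_bundle, falloff_masks):
        grid = falloff_bundle.grids["PTV1"]
        cdvh = cumulate(compute_ddvh(grid, falloff_masks["PTV"]))
        assert cdvh.dose_points.size == 501


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

class TestStatistics:
    def test_uniform_dose_collapses_all_statistics(self):
        dose = np.full((1, 10, 10), 4000.0)
        grid = _flat_grid(nx=10, ny=10, dose=dose)
        mask = StructureMask(grid=grid, frac=np.ones_like(dose))
        ddvh = compute_ddvh(grid, mask)  # default width: 4000/500, centre-aligned
        stats = dvh_statistics(cumulate(ddvh), ddvh)
        for v in (stats.min_dose, stats.max_dose, stats.mean_dose, stats.median_dose):
            assert v == pytest.approx(4000.0)

    def test_linear_curve_d50(self):
        cdvh = CumulativeDVH(dose_points=np.linspace(0, 100, 101),
                             volume_cc=np.linspace(100, 0, 101))
        assert cdvh.dose_at_volume(50.0) == pytest.approx(50.0)

    def test_normalized_coverage_rounds_like_report(self):
        """652.7 cc above threshold out of 1391.5 cc renders as 47%."""
        from dvhkit.plan_io import round_half_up_pct
        assert round_half_up_pct(652.7 / 1391.5) == 47

    def test_queries_answered_from_curve(self):
        dose = np.zeros((1, 10, 10))
        dose[0, :5] = 1000.0
        dose[0, 5:] = 2000.0
        grid = _flat_grid(nx=10, ny=10, dose=dose)
        mask = StructureMask(grid=grid, frac=np.ones_like(dose))
        ddvh = compute_ddvh(grid, mask, bin_width=4.0)
        q_vol = parse_poi_token("V15")  # 1500 cGy
        q_rel = parse_poi_token(">0.50PD").resolve(2000.0)
        stats = dvh_statistics(cumulate(ddvh), ddvh, [q_vol, q_rel])
        assert stats.answers[0].volume_pct == pytest.approx(50.0)
        assert stats.answers[1].volume_pct == pytest.approx(100.0)

    def test_out_of_range_query_clamped_and_flagged(self):
        cdvh = CumulativeDVH(dose_points=np.linspace(0, 100, 101),
                             volume_cc=np.linspace(100, 0, 101))
        ddvh = DifferentialDVH(bin_edges=np.array([-0.5, 0.5, 1.5]),
                               bin_volumes=np.array([50.0, 50.0]))
        q = parse_poi_token("V2")  # 200 cGy, beyond the curve
        stats = dvh_statistics(cdvh, ddvh, [q])
        assert stats.answers[0].clamped


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_reproduces_samples(self, falloff_bundle, falloff_masks, falloff_spec):
        grid = falloff_bundle.grids["PTV1"]
        cdvh = cumulate(compute_ddvh(grid, falloff_masks["OAR"]))
        sm = smooth_cdvh(cdvh)
        vals = sm(cdvh.dose_points)
        assert np.max(np.abs(vals - cdvh.volume_cc)) < 1e-6 * cdvh.total_volume_cc

    def test_fit_tracks_analytic_curve_within_1pct(self, falloff_bundle,
                                                   falloff_masks, falloff_spec):
        """Smoothed fit of a dense linear-falloff cDVH stays within 1% NRMSD
        of the closed-form curve, probed off the sample lattice."""
        grid = falloff_bundle.grids["PTV1"]
        cdvh = cumulate(compute_ddvh(grid, falloff_masks["OAR"]))
        sm = smooth_cdvh(cdvh)
        ana = analytic_cdvh(falloff_spec, "OAR")
        rng = np.random.default_rng(7)
        probes = rng.uniform(0.0, falloff_spec.d0, size=400)
        assert nrmsd(sm, ana, probes) < 1.0

    def test_monotone_at_dense_probes(self, falloff_bundle, falloff_masks):
        grid = falloff_bundle.grids["PTV1"]
        cdvh = cumulate(compute_ddvh(grid, falloff_masks["OAR"]))
        sm = smooth_cdvh(cdvh)
        probes = np.linspace(cdvh.dose_points[0], cdvh.dose_points[-1], 10_000)
        vals = sm(probes)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_short_curve_rejected(self):
        cdvh = CumulativeDVH(dose_points=np.arange(5.0),
                             volume_cc=np.array([10.0, 8, 6, 4, 2]))
        with pytest.raises(CurveTooShortError):
            smooth_cdvh(cdvh)


# ---------------------------------------------------------------------------
# Comparison metrics
# ---------------------------------------------------------------------------

class _StubCurve:
    """Minimal curve object for closed-form metric checks."""

    def __init__(self, fn, total, inv=None):
        self._fn = fn
        self.total_volume_cc = total
        self._inv = inv

    def volume_at_dose(self, d):
        return self._fn(np.asarray(d, dtype=float))

    def dose_at_volume(self, v):
        return self._inv(v)


class TestMetrics:
    def _linear(self, shift=0.0):
        return _StubCurve(lambda d: np.clip(100.0 - (d - shift), 0, 100), 100.0,
                          inv=lambda v: 100.0 - v + shift)

    def test_identical_curves_zero(self):
        a = self._linear()
        probes = np.linspace(0, 100, 33)
        assert nrmsd(a, a, probes) == 0.0
        assert dta(a, a, 0.5, pd=5000.0) == 0.0

    def test_constant_offset_of_1pct_gives_1pct(self):
        a = self._linear()
        b = _StubCurve(lambda d: np.clip(100.0 - d, 0, 100) - 1.0, 100.0)
        probes = np.linspace(5, 90, 18)
        assert nrmsd(a, b, probes) == pytest.approx(1.0)

    def test_symmetry(self):
        a = self._linear()
        b = _StubCurve(lambda d: np.clip(100.0 - 1.1 * d, 0, 100), 100.0)
        probes = np.linspace(0, 80, 21)
        assert nrmsd(a, b, probes) == pytest.approx(nrmsd(b, a, probes))

    def test_empty_probes_rejected(self):
        a = self._linear()
        with pytest.raises(ValueError):
            nrmsd(a, a, [])

    def test_dose_shift_normalized_to_pd(self):
        """A +50 cGy dose-axis shift at PD 5000 cGy is a 1% DTA."""
        a = self._linear()
        b = self._linear(shift=50.0)
        assert dta(a, b, 0.5, pd=5000.0) == pytest.approx(1.0)

    def test_invalid_fraction_rejected(self):
        a = self._linear()
        with pytest.raises(ValueError):
            dta(a, a, 1.5, pd=5000.0)
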