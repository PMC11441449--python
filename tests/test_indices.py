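import math

import numpy as np
import pytest

from scotoperim import (
    Color, DifferenceClass, NON_SEEN, build_grid, classify_difference,
    hemifield_means, mean_sensitivity, normative_lower_bounds,
    pointwise_difference, summary_difference_indices, volume_sensitivity,
)
from scotoperim.grid import Grid, Locus

from conftest import make_exam


def raster_volume_oracle(grid, values, n=2000):
    """Brute-force quadrature of the piecewise-linear interpolant:
    midpoint raster on n scanlines, each clipped exactly to the convex
    hull of the loci."""
    from scipy.interpolate import LinearNDInterpolator
    from scipy.spatial import ConvexHull

    xy = grid.xy
    poly = xy[ConvexHull(xy).vertices]
    interp = LinearNDInterpolator(xy, np.asarray(values, float))
    ymin, ymax = poly[:, 1].min(), poly[:, 1].max()
    hy = (ymax - ymin) / n
    ys = ymin + (np.arange(n) + 0.5) * hy
    # exact hull x-extent per scanline
    edges = list(zip(poly, np.roll(poly, -1, axis=0)))
    total = 0.0
    pts_x, pts_y, widths = [], [], []
    for y in ys:
        xs = [x1 + (y - y1) / (y2 - y1) * (x2 - x1)
              for (x1, y1), (x2, y2) in edges
              if (y1 - y) * (y2 - y) <= 0 and y1 != y2]
        if not xs:
            continue
        x0, x1 = min(xs), max(xs)
        if x1 <= x0:
            continue
        hx = (x1 - x0) / n
        pts_x.append(x0 + (np.arange(n) + 0.5) * hx)
        pts_y.append(np.full(n, y))
        widths.append(hx)
    f = interp(np.concatenate(pts_x), np.concatenate(pts_y))
    f = np.nan_to_num(f).reshape(len(widths), n)
    return float(np.sum(f.sum(axis=1) * np.asarray(widths) * hy))


class TestMeanSensitivity:
    def test_constant_field(self, default_grid):
        exam = make_exam(default_grid, [20.0] * 37)
        assert mean_sensitivity(exam) == 20.0

    def test_all_non_seen_maps_to_zero(self, default_grid):
        exam = make_exam(default_grid, [NON_SEEN] * 37)
        assert mean_sensitivity(exam) == 0.0

    def test_single_seeing_locus(self, default_grid):
        thresholds = [0.0] * 36 + [36.0]
        exam = make_exam(default_grid, thresholds)
        assert mean_sensitivity(exam) == pytest.approx(36.0 / 37.0)

    def test_central_exclusion(self, default_grid):
        thresholds = [20.0] * 37
        thresholds[default_grid.central_index()] = 0.0
        exam = make_exam(default_grid, thresholds)
        assert mean_sensitivity(exam, central_excluded=True) == 20.0
        assert mean_sensitivity(exam) == pytest.approx(20.0 * 36 / 37)

    def test_radial_grid_mean_is_spatially_weighted(self, default_grid):
        """On the radial grid the plain mean of the field S(r) = r is not
        the area-weighted mean: the dense center drags it down."""
        r = np.hypot(*default_grid.xy.T)
        exam = make_exam(default_grid, tuple(r))
        ms = mean_sensitivity(exam)
        area_weighted = volume_sensitivity(exam) / default_grid.hull_area()
        assert ms == pytest.approx(r.mean())
        assert ms < area_weighted  # documents the sampling-density bias


class TestVolumeSensitivity:
    def test_flat_field_is_sensitivity_times_hull_area(self, default_grid):
        exam = make_exam(default_grid, [20.6] * 37)
        assert volume_sensitivity(exam) == pytest.approx(20.6 * 147.0, rel=1e-12)

    def test_all_non_seen_is_zero(self, default_grid):
        exam = make_exam(default_grid, [NON_SEEN] * 37)
        assert volume_sensitivity(exam) == 0.0

    def test_radial_cone_matches_raster_oracle(self, default_grid):
        r = np.hypot(*default_grid.xy.T)
        values = np.maximum(0.0, 30.0 - 3.0 * r)
        exam = make_exam(default_grid, tuple(values))
        oracle = raster_volume_oracle(default_grid, values, n=1200)
        assert volume_sensitivity(exam) == pytest.approx(oracle, rel=1e-5)

    def test_additive_in_the_surface(self, default_grid, rng):
        f = rng.uniform(0, 18, 37)
        g = rng.uniform(0, 18, 37)
        vf = volume_sensitivity(make_exam(default_grid, tuple(f)))
        vg = volume_sensitivity(make_exam(default_grid, tuple(g)))
        vfg = volume_sensitivity(make_exam(default_grid, tuple(f + g)))
        assert vfg == pytest.approx(vf + vg, rel=1e-9)

    def test_invariant_to_locus_ordering_and_rotation(self, rng):
        # a jittered grid puts the loci in generic position, where the
        # Delaunay triangulation (hence the interpolant) is unique; the
        # perfectly regular grid has cyclic inter-ring trapezoids whose
        # diagonal choice is a documented tie-break degeneracy
        base_grid = build_grid()
        jittered = Grid(tuple(
            Locus(l.id, l.x + rng.normal(0, 0.05), l.y + rng.normal(0, 0.05),
                  l.ring_index) for l in base_grid.loci))
        values = rng.uniform(0, 36, 37)
        base = volume_sensitivity(make_exam(jittered, tuple(values)))
        perm = rng.permutation(37)
        shuffled = Grid(tuple(
            Locus(i, jittered.loci[p].x, jittered.loci[p].y,
                  jittered.loci[p].ring_index)
            for i, p in enumerate(perm)))
        assert volume_sensitivity(make_exam(shuffled, tuple(values[perm]))) \
            == pytest.approx(base, rel=1e-9)
        theta = 0.37
        c, s = math.cos(theta), math.sin(theta)
        rotated = Grid(tuple(
            Locus(l.id, c * l.x - s * l.y, s * l.x + c * l.y, l.ring_index)
            for l in jittered.loci))
        assert volume_sensitivity(make_exam(rotated, tuple(values))) \
            == pytest.approx(base, rel=1e-6)

    def test_bounded_by_dynamic_range_times_hull(self, default_grid, rng):
        values = rng.uniform(0, 36, 37)
        v = volume_sensitivity(make_exam(default_grid, tuple(values)))
        assert 0.0 <= v <= 36.0 * default_grid.hull_area()

    def test_degenerate_geometry_rejected(self):
        collinear = Grid(tuple(Locus(i, float(i), 0.0, -1) for i in range(5)))
        exam = make_exam(collinear, [10.0] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            volume_sensitivity(exam)


class TestPointwiseDifference:
    def test_identical_maps(self, default_grid):
        cy = make_exam(default_grid, [10.0] * 37, color="cyan_505nm")
        rd = make_exam(default_grid, [10.0] * 37, color="red_627nm")
        diff = pointwise_difference(cy, rd)
        assert all(d == 0.0 for d in diff.cyan_minus_red)

    def test_difference_arithmetic_and_undefined(self, default_grid):
        c = [10.0] * 37
        r = [15.0] * 37
        c[3] = NON_SEEN
        cy = make_exam(default_grid, c, color="cyan_505nm")
        rd = make_exam(default_grid, r, color="red_627nm")
        diff = pointwise_difference(cy, rd)
        assert diff.cyan_minus_red[0] == -5.0
        assert np.isnan(diff.cyan_minus_red[3])

    def test_grid_mismatch_rejected(self, default_grid):
        other = build_grid("custom", ring_radii=[2.0], points_per_ring=36)
        cy = make_exam(default_grid, [10.0] * 37, color="cyan_505nm")
        rd = make_exam(other, [10.0] * 37, color="red_627nm")
        with pytest.raises(ValueError, match="grid"):
            pointwise_difference(cy, rd)


class TestClassifyDifference:
    def _pair(self, grid, c_val, r_val):
        return (make_exam(grid, [c_val] * 37, color="cyan_505nm"),
                make_exam(grid, [r_val] * 37, color="red_627nm"))

    def test_rod_dysfunction_at_device_limit(self, default_grid):
        cy, rd = self._pair(default_grid, 10.0, 15.0)  # diff -5
        dm = classify_difference(cy, rd, threshold=4.0)
        assert all(c is DifferenceClass.ROD_DYSFUNCTION for c in dm.classes)

    def test_same_diff_equal_at_trtv_limit(self, default_grid):
        cy, rd = self._pair(default_grid, 10.0, 15.0)
        dm = classify_difference(cy, rd, threshold=13.0)
        assert all(c in (DifferenceClass.EQUAL_NORMAL,
                         DifferenceClass.EQUAL_REDUCED) for c in dm.classes)

    def test_cone_dysfunction(self, default_grid):
        cy, rd = self._pair(default_grid, 20.0, 10.0)  # diff +10
        dm = classify_difference(cy, rd, threshold=4.0)
        assert all(c is DifferenceClass.CONE_DYSFUNCTION for c in dm.classes)

    def test_equal_reduced_below_normative(self, default_grid):
        cy, rd = self._pair(default_grid, 5.0, 5.0)
        normative = np.full(37, 16.0)  # healthy mean - 2 SD well above 5 dB
        dm = classify_difference(cy, rd, threshold=4.0,
                                 normative_pointwise=normative)
        assert all(c is DifferenceClass.EQUAL_REDUCED for c in dm.classes)

    def test_both_non_seen_is_equal_reduced(self, default_grid):
        cy, rd = self._pair(default_grid, NON_SEEN, NON_SEEN)
        dm = classify_difference(cy, rd, threshold=4.0)
        assert all(c is DifferenceClass.EQUAL_REDUCED for c in dm.classes)

    def test_threshold_zero_partitions_by_sign(self, default_grid, rng):
        c = rng.uniform(0, 36, 37)
        r = rng.uniform(0, 36, 37)
        cy = make_exam(default_grid, tuple(c), color="cyan_505nm")
        rd = make_exam(default_grid, tuple(r), color="red_627nm")
        dm = classify_difference(cy, rd, threshold=0.0)
        for d, cls in zip(dm.cyan_minus_red, dm.classes):
            if d < 0:
                assert cls is DifferenceClass.ROD_DYSFUNCTION
            elif d > 0:
                assert cls is DifferenceClass.CONE_DYSFUNCTION
            else:
                assert cls in (DifferenceClass.EQUAL_NORMAL,
                               DifferenceClass.EQUAL_REDUCED)

    def test_raising_threshold_never_adds_dysfunction_loci(self, default_grid, rng):
        c = rng.uniform(0, 36, 37)
        r = rng.uniform(0, 36, 37)
        cy = make_exam(default_grid, tuple(c), color="cyan_505nm")
        rd = make_exam(default_grid, tuple(r), color="red_627nm")
        dysfunction = {DifferenceClass.ROD_DYSFUNCTION,
                       DifferenceClass.CONE_DYSFUNCTION}
        counts = []
        for thr in (0.0, 4.0, 13.0):
            dm = classify_difference(cy, rd, thr)
            counts.append(sum(cls in dysfunction for cls in dm.classes))
        assert counts == sorted(counts, reverse=True)

    def test_normative_bounds_from_reference_cohort(self, default_grid):
        exams = [make_exam(default_grid, [20.0 + i] * 37) for i in range(5)]
        lower = normative_lower_bounds(exams, n_sd=2.0)
        expected = 22.0 - 2.0 * np.std([20, 21, 22, 23, 24], ddof=1)
        np.testing.assert_allclose(lower, expected)


class TestHemifields:
    def test_symmetric_field(self, default_grid):
        exam = make_exam(default_grid, [12.0] * 37)
        t, n = hemifield_means(exam)
        assert t == n == 12.0

    def test_temporal_only_field(self, default_grid):
        thresholds = [v if l.x > 0 else 0.0
                      for l, v in zip(default_grid.loci, [15.0] * 37)]
        exam = make_exam(default_grid, thresholds)
        t, n = hemifield_means(exam)
        assert n == 0.0 and t == 15.0

    def test_os_exam_hemifields_match_mirrored_od(self, default_grid):
        thresholds = tuple(20.0 if l.x > 0 else 5.0 for l in default_grid.loci)
        od = make_exam(default_grid, thresholds, eye="OD")
        os_exam = make_exam(default_grid, thresholds, eye="OS")
        t_od, n_od = hemifield_means(od)
        t_os, n_os = hemifield_means(os_exam)
        # the same retinal loci in an OS exam are nasal/temporal swapped
        assert (t_os, n_os) == (n_od, t_od)

    def test_temporal_sparing_in_simulated_disease(self, small_cohort):
        from scotoperim import Group

        chm = [r for r in small_cohort if r.group is Group.CHOROIDEREMIA]
        wins = 0
        for rec in chm:
            t, n = hemifield_means(rec.get("scotopic", Color.RED))
            wins += t > n
        assert wins >= 0.9 * len(chm)


class TestSummaryDifference:
    def test_identical_inputs(self, default_grid):
        cy = make_exam(default_grid, [10.0] * 37, color="cyan_505nm")
        rd = make_exam(default_grid, [10.0] * 37, color="red_627nm")
        assert summary_difference_indices(cy, rd) == (0.0, 0.0)

    def test_mean_difference_arithmetic(self, default_grid):
        cy = make_exam(default_grid, [2.3] * 37, color="cyan_505nm")
        rd = make_exam(default_grid, [4.9] * 37, color="red_627nm")
        ms_diff, _ = summary_difference_indices(cy, rd)
        assert ms_diff == pytest.approx(-2.6)
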