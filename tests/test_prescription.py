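"""Segmentation, DPBN/DPBC prescription maps and robust stacking."""

import numpy as np
import pytest

from paintbox import (ConfigurationError, EmptySegmentationError, GridSpec,
                      ImageVolume, OARConstraint, Shape, combine_robust, dpbc_map,
                      dpbn_map, segment_suv)


@pytest.fixture
def grid():
    return GridSpec((30, 30, 30), (1.0, 1.0, 1.0), (-14.5, -14.5, -14.5))


@pytest.fixture
def sphere_suv(grid):
    # SUV 10 sphere of radius 6 mm on zero background
    mask = Shape("sphere", (0, 0, 0), (6.0,)).rasterize(grid)
    return ImageVolume(grid, np.where(mask, 10.0, 0.0), "suv"), mask


def brute_force_components(mask):
    """Flood-fill 26-connectivity labeling, independent of scipy."""
    mask = mask.astype(bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            p = stack.pop()
            for off in offsets:
                q = tuple(p[a] + off[a] for a in range(3))
                if all(0 <= q[a] < mask.shape[a] for a in range(3)):
                    if mask[q] and not labels[q]:
                        labels[q] = current
                        stack.append(q)
    return labels, current


class TestSegmentSUV:
    def test_uniform_sphere_recovered_at_half_threshold(self, sphere_suv):
        suv, mask = sphere_suv
        seg = segment_suv(suv, 0.5)
        np.testing.assert_array_equal(seg.mask.values, mask.astype(float))
        assert seg.threshold == pytest.approx(5.0)
        assert seg.component_count == 1

    def test_two_disjoint_lesions_two_components(self, grid):
        vals = np.zeros(grid.shape)
        vals[2:5, 2:5, 2:5] = 8.0
        vals[20:24, 20:24, 20:24] = 10.0
        seg = segment_suv(ImageVolume(grid, vals, "suv"), 0.4)
        assert seg.component_count == 2

    def test_small_component_removal_matches_bruteforce_labels(self, grid):
        vals = np.zeros(grid.shape)
        vals[2:8, 2:8, 2:8] = 10.0       # 216 voxels
        vals[20, 20, 20] = 10.0          # single voxel speck
        seg = segment_suv(ImageVolume(grid, vals, "suv"), 0.5,
                          min_component_voxels=5)
        labels, n = brute_force_components(vals >= 5.0)
        sizes = np.bincount(labels.ravel())[1:]
        survivors = (sizes >= 5).sum()
        assert seg.component_count == survivors == 1
        assert seg.mask.values.sum() == sizes[sizes >= 5].sum()

    def test_all_zero_suv_signals_empty(self, grid):
        with pytest.raises(EmptySegmentationError):
            segment_suv(ImageVolume(grid, np.zeros(grid.shape), "suv"), 0.5)


class TestDPBN:
    @pytest.fixture
    def hetero(self, grid):
        # SUV ramp 2..10 inside a box target
        vals = np.zeros(grid.shape)
        vals[5:25, 5:25, 5:25] = np.linspace(2, 10, 20)[:, None, None]
        suv = ImageVolume(grid, vals, "suv")
        mask = ImageVolume(grid, (vals > 0).astype(float), "mask")
        return suv, mask

    def test_endpoints_and_midpoint(self, hetero):
        suv, mask = hetero
        pmap = dpbn_map(suv, mask)
        m = mask.values > 0
        s = suv.values[m]
        d = pmap.dose.values[m]
        assert d[np.argmin(s)] == pytest.approx(70.0)
        assert d[np.argmax(s)] == pytest.approx(82.0)
        mid = np.abs(s - 6.0) < 1e-9  # midpoint of the 2..10 range
        assert np.allclose(d[mid], 76.0)

    def test_affine_in_suv(self, hetero):
        suv, mask = hetero
        pmap = dpbn_map(suv, mask)
        m = mask.values > 0
        corr = np.corrcoef(suv.values[m], pmap.dose.values[m])[0, 1]
        assert corr == pytest.approx(1.0)

    def test_constant_suv_gets_base_dose(self, sphere_suv):
        suv, mask_arr = sphere_suv
        mask = ImageVolume(suv.grid, mask_arr.astype(float), "mask")
        pmap = dpbn_map(suv, mask)
        assert np.allclose(pmap.dose.values[mask_arr], 70.0)

    def test_inverted_endpoints_rejected(self, hetero):
        suv, mask = hetero
        with pytest.raises(ConfigurationError):
            dpbn_map(suv, mask, d_low=82.0, d_high=70.0)


class TestDPBC:
    @pytest.fixture
    def nested(self, grid):
        vals = np.zeros(grid.shape)
        for r, level in ((10.0, 4.0), (7.0, 7.0), (4.0, 10.0)):
            vals[Shape("sphere", (0, 0, 0), (r,)).rasterize(grid)] = level
        suv = ImageVolume(grid, vals, "suv")
        mask = ImageVolume(grid, (vals > 0).astype(float), "mask")
        return suv, mask

    def test_three_levels_make_nested_btvs(self, nested):
        suv, mask = nested
        pmap = dpbc_map(suv, mask, [0.3, 0.6, 0.9])
        assert len(pmap.btv_masks) == 3
        for outer, inner in zip(pmap.btv_masks, pmap.btv_masks[1:]):
            assert not np.any((inner.values > 0) & (outer.values == 0))

    def test_piecewise_constant_with_at_most_n_values(self, nested):
        suv, mask = nested
        pmap = dpbc_map(suv, mask, [0.3, 0.6, 0.9])
        doses = np.unique(pmap.dose.values[pmap.target_mask.values > 0])
        assert len(doses) <= 3
        for k, (btv, expect) in enumerate(zip(pmap.btv_masks, sorted(doses))):
            shell = (btv.values > 0)
            for higher in pmap.btv_masks[k + 1:]:
                shell &= higher.values == 0
            assert np.allclose(pmap.dose.values[shell], expect)

    def test_single_low_level_is_uniform_conventional_plan(self, nested):
        suv, mask = nested
        pmap = dpbc_map(suv, mask, [0.01])
        m = pmap.target_mask.values > 0
        assert np.allclose(pmap.dose.values[m], pmap.dose.values[m][0])

    def test_default_level_doses_match_dpbn_at_thresholds(self, nested):
        suv, mask = nested
        fr = [0.3, 0.6, 0.9]
        pmap = dpbc_map(suv, mask, fr)
        m = mask.values > 0
        smin, smax = suv.values[m].min(), suv.values[m].max()
        for k, (btv, f) in enumerate(zip(pmap.btv_masks, fr)):
            dpbn_at_threshold = max(
                70.0, 70.0 + (f * smax - smin) / (smax - smin) * 12.0)
            innermost = btv.values > 0
            for higher in pmap.btv_masks[k + 1:]:
                innermost &= higher.values == 0
            assert np.allclose(pmap.dose.values[innermost], dpbn_at_threshold)

    def test_nonascending_doses_rejected(self, nested):
        suv, mask = nested
        with pytest.raises(ConfigurationError):
            dpbc_map(suv, mask, [0.3, 0.6], level_doses=[76.0, 72.0])


class TestCombineRobust:
    @pytest.fixture
    def setup(self, grid):
        vals = np.zeros(grid.shape)
        vals[Shape("sphere", (0, 0, 0), (7.0,)).rasterize(grid)] = 5.0
        vals[Shape("sphere", (0, 0, 0), (4.0,)).rasterize(grid)] = 9.0
        suv = ImageVolume(grid, vals, "suv")
        mask = ImageVolume(grid, (vals > 0).astype(float), "mask")
        dose_grid = GridSpec((15, 15, 15), (2.0, 2.0, 2.0), (-14.0, -14.0, -14.0))
        return suv, mask, dose_grid

    def test_single_map_one_constraint_pair_per_voxel(self, setup):
        suv, mask, dose_grid = setup
        pmap = dpbn_map(suv, mask)
        rp = combine_robust([pmap], [], dose_grid)
        assert len(rp.maps) == 1
        assert rp.n_target == int((rp.maps[0].target_mask.values > 0).sum())

    def test_duplicate_maps_stack_identical_constraints(self, setup):
        suv, mask, dose_grid = setup
        pmap = dpbn_map(suv, mask)
        rp = combine_robust([pmap, pmap], [], dose_grid)
        a, b = rp.maps
        np.testing.assert_array_equal(a.dose.values, b.dose.values)
        np.testing.assert_array_equal(a.target_mask.values, b.target_mask.values)
        assert rp.n_target == int((a.target_mask.values > 0).sum())

    def test_dpbn_plus_dpbc_overlap_counts_match_mask_algebra(self, setup):
        suv, mask, dose_grid = setup
        m_n = dpbn_map(suv, mask)
        m_c = dpbc_map(suv, mask, [0.3, 0.8])
        rp = combine_robust([m_n, m_c], [], dose_grid)
        both = ((rp.maps[0].target_mask.values > 0)
                & (rp.maps[1].target_mask.values > 0))
        pairs = sum(int((m.target_mask.values > 0).sum()) for m in rp.maps)
        union = int(((rp.maps[0].target_mask.values > 0)
                     | (rp.maps[1].target_mask.values > 0)).sum())
        assert pairs == union + int(both.sum())
        assert rp.n_target == union

    def test_stacking_never_loosens_single_map_interval(self, setup):
        suv, mask, dose_grid = setup
        m1 = dpbn_map(suv, mask, delta=(0.97, 1.03))
        m2 = dpbc_map(suv, mask, [0.3, 0.8], delta=(0.98, 1.02))
        rp = combine_robust([m1, m2], [], dose_grid)
        for m in rp.maps:
            sel = m.target_mask.values > 0
            lo = m.d_min[sel] * m.delta[0]
            hi = m.d_max[sel] * m.delta[1]
            # the stacked feasible interval at any voxel lies inside this
            # map's own interval by construction (intersection semantics)
            assert (lo <= hi).all()

    def test_oar_voxels_overlapping_target_excluded(self, setup):
        suv, mask, dose_grid = setup
        pmap = dpbn_map(suv, mask)
        oar_mask = ImageVolume(suv.grid,
                               Shape("sphere", (2.0, 0, 0), (6.0,)
                                     ).rasterize(suv.grid).astype(float), "mask")
        rp = combine_robust([pmap], [OARConstraint(oar_mask, 50.0, "oar")],
                            dose_grid)
        target = rp.maps[0].target_mask.values > 0
        for oar in rp.oars:
            assert not np.any((oar.mask.values > 0) & target)

    def test_empty_map_list_rejected(self, setup):
        _, _, dose_grid = setup
        with pytest.raises(ConfigurationError):
            combine_robust([], [], dose_grid)
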