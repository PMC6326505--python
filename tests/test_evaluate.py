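"""Quality-index metrics, DVH/CI, isodose masks and dose accumulation."""

import numpy as np
import pytest
from scipy import sparse

from paintbox import (ConfigurationError, DoseInfluenceMatrix, GridSpec,
                      ImageVolume, LPSolution, PaintboxError, PencilKernel,
                      PrescriptionMap, RobustPrescription, TreatmentPhase,
                      accumulate, conformity_index, dvh, fraction_within,
                      isodose_mask, q_map, qf, quality_report, qvh)


@pytest.fixture
def grid():
    return GridSpec((6, 6, 6), (2.0, 2.0, 2.0))


def make_rx(grid, rx_values, mask=None):
    rx = np.asarray(rx_values, dtype=float)
    m = (rx > 0) if mask is None else np.asarray(mask, bool)
    return PrescriptionMap(
        grid=grid, target_mask=ImageVolume(grid, m.astype(float), "mask"),
        dose=ImageVolume(grid, rx, "dose-Gy"), d_min=rx.copy(), d_max=rx.copy())


class TestQMetrics:
    def test_q_is_one_when_dose_matches_prescription(self, grid):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        qm = q_map(ImageVolume(grid, rx.copy(), "dose-Gy"), pmap)
        assert np.allclose(qm.values[~np.isnan(qm.values)], 1.0)
        assert qf(qm, pmap.target_mask) == pytest.approx(0.0)

    def test_uniform_two_percent_overdose(self, grid):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        qm = q_map(ImageVolume(grid, 1.02 * rx, "dose-Gy"), pmap)
        assert qf(qm, pmap.target_mask) == pytest.approx(2.0)

    def test_qf_scaling_identity(self, grid, rng):
        rx = np.where(rng.random(grid.shape) > 0.5, 70.0 + 12.0
                      * rng.random(grid.shape), 0.0)
        if not (rx > 0).any():
            rx[0, 0, 0] = 70.0
        pmap = make_rx(grid, rx)
        for alpha in (0.9, 0.97, 1.0, 1.04):
            qm = q_map(ImageVolume(grid, alpha * rx, "dose-Gy"), pmap)
            assert qf(qm, pmap.target_mask) == pytest.approx(100 * abs(alpha - 1))

    def test_qf_matches_mean_abs_oracle(self, grid, rng):
        rx = np.full(grid.shape, 75.0)
        pmap = make_rx(grid, rx)
        dose = rx * (1.0 + 0.05 * rng.standard_normal(grid.shape))
        qm = q_map(ImageVolume(grid, np.clip(dose, 0, None), "dose-Gy"), pmap)
        expect = 100.0 * np.abs(dose / rx - 1.0).mean()
        assert qf(qm, pmap.target_mask) == pytest.approx(expect)

    def test_zero_prescription_on_target_rejected(self, grid):
        rx = np.zeros(grid.shape)
        mask = np.zeros(grid.shape, bool)
        mask[0, 0, 0] = True
        pmap = make_rx(grid, rx, mask=mask)
        with pytest.raises(PaintboxError, match="positive"):
            q_map(ImageVolume(grid, rx, "dose-Gy"), pmap)

    def test_q_differs_between_two_prescription_maps(self, grid, rng):
        rx_a = np.full(grid.shape, 70.0)
        rx_b = np.full(grid.shape, 76.0)
        dose = ImageVolume(grid, np.full(grid.shape, 72.0), "dose-Gy")
        qa = q_map(dose, make_rx(grid, rx_a)).values
        qb = q_map(dose, make_rx(grid, rx_b)).values
        assert np.nanmean(qa) != pytest.approx(np.nanmean(qb))


class TestQVH:
    def test_uniform_q_steps_at_one(self, grid):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        qm = q_map(ImageVolume(grid, rx.copy(), "dose-Gy"), pmap)
        bins, pct = qvh(qm, pmap.target_mask)
        assert pct[0] == 100.0
        assert pct[np.searchsorted(bins, 1.0)] == 100.0
        assert pct[-1] == 0.0

    def test_two_value_q_has_fifty_percent_plateau(self, grid):
        rx = np.full(grid.shape, 70.0)
        dose = np.full(grid.shape, 0.9 * 70.0)
        dose[:3] = 1.1 * 70.0
        pmap = make_rx(grid, rx)
        qm = q_map(ImageVolume(grid, dose, "dose-Gy"), pmap)
        bins, pct = qvh(qm, pmap.target_mask)
        assert pct[np.searchsorted(bins, 1.0)] == pytest.approx(50.0)

    def test_matches_sorted_array_oracle(self, grid, rng):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        dose = rx * (1 + 0.1 * rng.standard_normal(grid.shape))
        qm = q_map(ImageVolume(grid, np.clip(dose, 0, None), "dose-Gy"), pmap)
        bins, pct = qvh(qm, pmap.target_mask, bin_width=0.02)
        q = np.sort(qm.values.ravel())
        for b, p in zip(bins[::5], pct[::5]):
            assert p == pytest.approx(100.0 * (q >= b).mean())


class TestFractionWithin:
    def test_perfect_q_is_100_at_any_tolerance(self, grid):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        qm = q_map(ImageVolume(grid, rx.copy(), "dose-Gy"), pmap)
        for tol in (0.03, 0.04, 0.05):
            assert fraction_within(qm, pmap.target_mask, tol) == 100.0

    def test_boundary_is_strict(self, grid):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        qm = q_map(ImageVolume(grid, 1.05 * rx, "dose-Gy"), pmap)
        assert fraction_within(qm, pmap.target_mask, 0.05) == 0.0

    def test_nesting_across_tolerances(self, grid, rng):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        dose = rx * (1 + 0.04 * rng.standard_normal(grid.shape))
        qm = q_map(ImageVolume(grid, np.clip(dose, 0, None), "dose-Gy"), pmap)
        f3 = fraction_within(qm, pmap.target_mask, 0.03)
        f4 = fraction_within(qm, pmap.target_mask, 0.04)
        f5 = fraction_within(qm, pmap.target_mask, 0.05)
        assert f3 <= f4 <= f5


class TestDVHAndCI:
    def test_uniform_dose_step_dvh(self, grid):
        mask = ImageVolume(grid, np.ones(grid.shape), "mask")
        dose = ImageVolume(grid, np.full(grid.shape, 50.0), "dose-Gy")
        bins, pct = dvh(dose, mask, bin_width=1.0)
        assert pct[np.searchsorted(bins, 50.0)] == 100.0
        assert pct[-1] == 0.0

    def test_empty_mask_rejected(self, grid):
        mask = ImageVolume(grid, np.zeros(grid.shape), "mask")
        dose = ImageVolume(grid, np.zeros(grid.shape), "dose-Gy")
        with pytest.raises(PaintboxError, match="empty"):
            dvh(dose, mask)

    def test_dvh_matches_sort_oracle(self, grid, rng):
        mask = ImageVolume(grid, np.ones(grid.shape), "mask")
        vals = 80.0 * rng.random(grid.shape)
        dose = ImageVolume(grid, vals, "dose-Gy")
        bins, pct = dvh(dose, mask, bin_width=0.5)
        for b, p in zip(bins[::10], pct[::10]):
            assert p == pytest.approx(100.0 * (vals >= b).mean())

    def test_ci_full_and_zero_coverage(self, grid):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        full = ImageVolume(grid, rx.copy(), "dose-Gy")
        zero = ImageVolume(grid, np.zeros(grid.shape), "dose-Gy")
        assert conformity_index(full, pmap, pmap.target_mask) == 100.0
        assert conformity_index(zero, pmap, pmap.target_mask) == 0.0

    def test_ci_half_covered_slab(self, grid):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        dose = np.zeros(grid.shape)
        dose[:3] = 70.0
        ci = conformity_index(ImageVolume(grid, dose, "dose-Gy"), pmap,
                              pmap.target_mask)
        assert ci == pytest.approx(50.0)

    def test_ci_monotone_in_dose(self, grid, rng):
        rx = np.full(grid.shape, 70.0)
        pmap = make_rx(grid, rx)
        base = 70.0 * rng.random(grid.shape)
        extra = 10.0 * rng.random(grid.shape)
        ci0 = conformity_index(ImageVolume(grid, base, "dose-Gy"), pmap,
                               pmap.target_mask)
        ci1 = conformity_index(ImageVolume(grid, base + extra, "dose-Gy"), pmap,
                               pmap.target_mask)
        assert ci1 >= ci0


class TestIsodose:
    def test_uniform_dose_full_and_empty_levels(self, grid):
        dose = ImageVolume(grid, np.full(grid.shape, 70.0), "dose-Gy")
        assert isodose_mask(dose, 100.0, 70.0).values.all()
        assert not isodose_mask(dose, 101.0, 70.0).values.any()

    def test_nested_levels_give_nested_masks(self, grid, rng):
        dose = ImageVolume(grid, 90.0 * rng.random(grid.shape), "dose-Gy")
        prev = None
        for level in (50.0, 80.0, 100.0):
            m = isodose_mask(dose, level, 70.0).values > 0
            if prev is not None:
                assert not np.any(m & ~prev)
            prev = m


def make_phase(grid, rx_vals, dose_vals, first, last):
    pmap = make_rx(grid, rx_vals)
    rp = RobustPrescription(grid=grid, maps=[pmap])
    dose = ImageVolume(grid, np.asarray(dose_vals, float), "dose-Gy")
    n = int(np.prod(grid.shape))
    dim = DoseInfluenceMatrix(matrix=sparse.csr_matrix(
        np.asarray(dose_vals, float).reshape(-1, 1)), grid=grid, apertures=[None],
        kernel=PencilKernel())
    sol = LPSolution(weights=np.ones(1), x_target=np.zeros(n),
                     y_target=np.zeros(n), x_oar=np.zeros(0), objective=0.0,
                     status="optimal", dose=dose)
    return TreatmentPhase(first_fraction=first, last_fraction=last,
                          prescription=rp, apertures=[None], solution=sol,
                          influence=dim)


class TestAccumulate:
    def test_single_phase_total_equals_phase_dose(self, grid):
        rx = np.full(grid.shape, 70.0)
        ph = make_phase(grid, rx, rx * 1.01, 1, 30)
        total, rep = accumulate([ph], 30)
        np.testing.assert_allclose(total.values, rx * 1.01)
        assert rep.qf_pct == pytest.approx(1.0)

    def test_two_identical_phases_equal_either_plan(self, grid):
        rx = np.full(grid.shape, 70.0)
        p1 = make_phase(grid, rx, rx.copy(), 1, 17)
        p2 = make_phase(grid, rx, rx.copy(), 18, 30)
        total, rep = accumulate([p1, p2], 30)
        np.testing.assert_allclose(total.values, rx)
        assert rep.qf_pct == pytest.approx(0.0, abs=1e-12)

    def test_17_13_blend_matches_hand_arithmetic(self):
        grid = GridSpec((2, 1, 1), (1.0, 1.0, 1.0))
        rx1 = np.array([70.0, 82.0]).reshape(2, 1, 1)
        rx2 = np.array([70.0, 76.0]).reshape(2, 1, 1)
        d1 = np.array([71.0, 80.0]).reshape(2, 1, 1)
        d2 = np.array([69.0, 77.0]).reshape(2, 1, 1)
        p1 = make_phase(grid, rx1, d1, 1, 17)
        p2 = make_phase(grid, rx2, d2, 18, 30)
        total, rep = accumulate([p1, p2], 30)
        expect = 17.0 / 30.0 * d1 + 13.0 / 30.0 * d2
        np.testing.assert_allclose(total.values, expect)
        rx_blend = 17.0 / 30.0 * rx1 + 13.0 / 30.0 * rx2
        expect_qf = 100.0 * np.abs(expect / rx_blend - 1.0).mean()
        assert rep.qf_pct == pytest.approx(expect_qf)

    def test_overlapping_fraction_ranges_rejected(self, grid):
        rx = np.full(grid.shape, 70.0)
        p1 = make_phase(grid, rx, rx.copy(), 1, 20)
        p2 = make_phase(grid, rx, rx.copy(), 18, 30)
        with pytest.raises(ConfigurationError, match="overlap"):
            accumulate([p1, p2], 30)

    def test_gap_in_fraction_coverage_rejected(self, grid):
        rx = np.full(grid.shape, 70.0)
        p1 = make_phase(grid, rx, rx.copy(), 1, 10)
        p2 = make_phase(grid, rx, rx.copy(), 18, 30)
        with pytest.raises(ConfigurationError, match="partition"):
            accumulate([p1, p2], 30)


class TestQualityReport:
    def test_summary_bundles_consistent_metrics(self, grid, rng):
        rx = np.full(grid.shape, 72.0)
        pmap = make_rx(grid, rx)
        dose = ImageVolume(grid, rx * (1 + 0.02 * rng.standard_normal(grid.shape)),
                           "dose-Gy")
        rep = quality_report(dose, pmap)
        s = rep.summary()
        assert s["within_3pct"] <= s["within_4pct"] <= s["within_5pct"]
        assert rep.qf_pct == pytest.approx(
            qf(q_map(dose, pmap), pmap.target_mask))
        assert 0.0 <= s["CI_target"] <= 100.0
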