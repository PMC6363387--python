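"""Tests for population fluorescence statistics, Feret morphometry, and
storage-structure event analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from recastate.foci import _cell_masks
from recastate.kinetics import (
    classify_structure_events,
    detect_storage_structures,
    event_time_cdf,
    feret_diameter,
    fold_increase,
    population_mean_intensity,
    track_storage_events,
)
from recastate.synthetic import (
    CellFieldConfig,
    EventTimeDistribution,
    InductionCurve,
    StorageStructureParams,
    TimelapseConfig,
    simulate_timelapse,
)


def brute_force_population_stats(cells):
    """Direct evaluation of the printed formulas (independent oracle)."""
    a = np.array([c[0] for c in cells])
    i = np.array([c[1] for c in cells])
    k = len(cells)
    prods = a * i
    F = prods.sum() / k
    sigma = np.sqrt(((prods - a.mean() * i.mean()) ** 2).sum() / (k - 1))
    return F, sigma, sigma / k


class TestPopulationIntensity:
    def test_homogeneous_population(self):
        s = population_mean_intensity([np.array([[2.0, 10.0]] * 5)])
        assert s.F[0] == pytest.approx(20.0)
        assert s.sigma_F[0] == pytest.approx(0.0)
        assert s.delta_F[0] == pytest.approx(0.0)

    def test_worked_example_against_direct_evaluation(self):
        cells = [(2.0, 10.0), (3.0, 20.0), (5.0, 30.0)]
        s = population_mean_intensity([np.array(cells)])
        F, sigma, delta = brute_force_population_stats(cells)
        assert F == pytest.approx((20 + 60 + 150) / 3)
        assert s.F[0] == pytest.approx(F)
        assert s.sigma_F[0] == pytest.approx(sigma)
        assert s.delta_F[0] == pytest.approx(delta)

    @given(c=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_intensity(self, c):
        cells = np.array([[2.0, 10.0], [3.0, 20.0], [5.0, 30.0]])
        base = population_mean_intensity([cells])
        scaled_cells = cells.copy()
        scaled_cells[:, 1] *= c
        scaled = population_mean_intensity([scaled_cells])
        assert scaled.F[0] == pytest.approx(c * base.F[0])
        assert scaled.sigma_F[0] == pytest.approx(c * base.sigma_F[0])
        assert scaled.delta_F[0] == pytest.approx(c * base.delta_F[0])

    def test_oracle_equivalence_on_random_inputs(self, rng):
        for _ in range(1000):
            k = rng.integers(2, 12)
            cells = np.column_stack(
                [rng.uniform(0.5, 8, k), rng.uniform(100, 5000, k)]
            )
            s = population_mean_intensity([cells])
            F, sigma, delta = brute_force_population_stats(cells)
            assert s.F[0] == pytest.approx(F)
            assert s.sigma_F[0] == pytest.approx(sigma)
            assert s.delta_F[0] == pytest.approx(delta)

    def test_single_cell_flagged(self):
        s = population_mean_intensity([np.array([[2.0, 10.0]])])
        assert s.spread_undefined[0]
        assert np.isnan(s.sigma_F[0])


class TestFoldIncrease:
    def test_constant_series(self):
        s = population_mean_intensity([np.array([[2.0, 10.0]] * 3)] * 4)
        s = fold_increase(s)
        np.testing.assert_allclose(s.FI, 1.0)

    def test_zero_reference_rejected(self):
        s = population_mean_intensity([np.array([[2.0, 0.0]] * 3)])
        with pytest.raises(ValueError):
            fold_increase(s)

    def test_additive_error_convention(self):
        tp = [np.array([[1.0, 10.0], [1.0, 12.0]]), np.array([[1.0, 20.0], [1.0, 26.0]])]
        s = fold_increase(population_mean_intensity(tp))
        assert s.delta_FI[1] == pytest.approx(s.delta_F[1] + s.delta_F[0])

    def test_logistic_induction_recovered_from_rendered_stack(self):
        """FI peak from a rendered time-lapse matches the generating curve."""
        fc = CellFieldConfig(n_cells=25, seed=3)
        tc = TimelapseConfig(
            induction_curve=InductionCurve(amplitude=1.0),
            appearance_probability=0.0,
            seed=3,
        )
        res = simulate_timelapse(tc, fc)
        labels = _cell_masks([c.polygon_px for c in res.field.cells], res.field.shape)
        tp = [
            np.array(
                [
                    (c.area_um2, res.stack[t][labels == c.cell_id + 1].mean())
                    for c in res.field.cells
                ]
            )
            for t in range(res.stack.shape[0])
        ]
        s = fold_increase(population_mean_intensity(tp, tc.times_min))
        curve_peak = tc.induction_curve(tc.times_min).max()
        assert s.FI.max() == pytest.approx(curve_peak, rel=0.05)


class TestFeret:
    def test_single_pixel_diagonal(self):
        assert feret_diameter(np.array([[4, 7]]), 0.1067) == pytest.approx(
            np.sqrt(2) * 0.1067
        )

    def test_horizontal_run(self):
        run = np.array([[0, c] for c in range(10)])
        assert feret_diameter(run, 0.1067) == pytest.approx(
            np.sqrt(10 ** 2 + 1 ** 2) * 0.1067
        )

    def test_rasterized_disc(self):
        rr, cc = np.mgrid[0:81, 0:81]
        mask = (rr - 40) ** 2 + (cc - 40) ** 2 <= 30 ** 2
        px = np.argwhere(mask)
        assert feret_diameter(px, 1.0) == pytest.approx(60.0, abs=2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            feret_diameter(np.empty((0, 2)))

    def test_brute_force_oracle_on_random_masks(self, rng):
        """Convex-hull calipers equal all-pairs corner distances."""
        offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
        for _ in range(60):
            n = rng.integers(1, 200)
            px = np.unique(rng.integers(0, 30, (n, 2)), axis=0)
            corners = (px[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
            d2 = ((corners[:, None, :] - corners[None, :, :]) ** 2).sum(-1)
            brute = np.sqrt(d2.max())
            assert feret_diameter(px, 1.0) == pytest.approx(brute, rel=1e-9)


class TestStorageStructures:
    def test_rendered_structures_detected_at_threshold(self, small_field,
                                                       small_field_labels):
        img = small_field.channels["gfp"]
        dets = detect_storage_structures(
            img, small_field_labels, 4000.0, small_field.config.pixel_size
        )
        truth = small_field.structures
        assert len(dets) == len(truth)
        det_cells = sorted(d.cell_id for d in dets)
        assert det_cells == sorted(s.cell_id for s in truth)
        # Feret diameters track the generating targets
        by_cell = {s.cell_id: s.target_feret_um for s in truth}
        for d in dets:
            assert d.feret_diameter_um == pytest.approx(by_cell[d.cell_id], abs=0.3)

    def test_all_below_threshold_empty(self):
        img = np.full((40, 40), 100.0)
        labels = np.ones((40, 40), dtype=np.int32)
        assert detect_storage_structures(img, labels, 4000.0) == []

    def test_zero_threshold_spans_cells(self):
        img = np.full((20, 20), 50.0)
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        dets = detect_storage_structures(img, labels, 0.0)
        assert len(dets) == 1
        assert len(dets[0].pixels) == 100


class TestEventTracking:
    def test_recovers_generator_event_times(self):
        fc = CellFieldConfig(
            n_cells=40, seed=4, storage_structure_params=StorageStructureParams()
        )
        tc = TimelapseConfig(seed=4)
        res = simulate_timelapse(tc, fc)
        labels = _cell_masks([c.polygon_px for c in res.field.cells], res.field.shape)
        tracked = track_storage_events(res.stack, labels, 4000.0, 5.0, fc.pixel_size)
        truth = res.events

        n_checked = n_ok = 0
        for kind in ("dissolved", "appeared"):
            t = truth[truth.event == kind]
            m = t.merge(
                tracked[tracked.event == kind], on="cell_id", suffixes=("_t", "_m")
            )
            n_checked += len(t)
            n_ok += (np.abs(m.event_frame_t - m.event_frame_m) <= 1).sum()
        assert n_checked > 20
        assert n_ok >= 0.95 * n_checked
        # persistent structures carry no event time
        pers = tracked[tracked.event == "persistent"]
        assert pers.event_time_min.isna().all()

    def test_single_frame_stack_rejected(self):
        with pytest.raises(ValueError):
            track_storage_events(np.zeros((1, 10, 10)), np.ones((10, 10), int))

    def test_bookkeeping_invariants(self):
        events = pd.DataFrame(
            {"event": ["dissolved"] * 7 + ["persistent"] * 3 + ["appeared"] * 5}
        )
        counts = classify_structure_events(events)
        assert counts["initial"] == counts["dissolved"] + counts["persistent"]
        assert counts["total"] == counts["initial"] + counts["appeared"]
        assert counts["dissolving_fraction"] == pytest.approx(0.7)


class TestEventTimeCDF:
    def test_degenerate_single_value(self):
        cdf = event_time_cdf(np.full(50, 45.0), seed=0)
        assert cdf.half_time_min == 45.0
        np.testing.assert_allclose(cdf.bootstrap_sd, 0.0)
        assert cdf.cdf[-1] == 1.0

    def test_cdf_monotone_bounded(self, rng):
        cdf = event_time_cdf(rng.exponential(30, 200), seed=1)
        assert np.all(np.diff(cdf.cdf) >= 0)
        assert cdf.cdf[0] >= 0 and cdf.cdf[-1] == pytest.approx(1.0)

    def test_half_time_of_frame_quantized_sample(self, rng):
        """272 lognormal event times, median 45 min, on a 5-min grid."""
        times = EventTimeDistribution(45.0, 0.5).sample(272, rng)
        quantized = np.round(times / 5.0) * 5.0  # frame-resolution event times
        cdf = event_time_cdf(quantized, seed=2)
        assert abs(cdf.half_time_min - 45.0) <= 5.0

    def test_bootstrap_sd_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        sds = []
        for n in (50, 200, 800):
            t = rng.exponential(30, n)
            cdf = event_time_cdf(t, n_bootstrap=300, seed=4)
            sds.append(np.median(cdf.bootstrap_sd))
        assert sds[0] > sds[1] > sds[2]

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            event_time_cdf([45.0])
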