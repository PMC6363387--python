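"""Unit tests for the smFRET analysis chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recastate.fret import (
    DwellSegment,
    analyze_titration,
    bound_fraction,
    compute_fret,
    empirical_survival,
    fit_fret_mixture,
    fit_fret_mixture_histogram,
    fit_hill,
    fit_survival_biexp,
    hill_curve,
    segment_states,
)
from recastate.synthetic import sample_biexponential_dwells, simulate_titration


class TestComputeFret:
    @pytest.mark.parametrize(
        "donor, acceptor, crosstalk, expected",
        [
            (300.0, 100.0, 0.0, 0.25),
            (300.0, 130.0, 0.1, 0.25),  # corrected acceptor 100
            (300.0, 30.0, 0.1, 0.0),  # corrected acceptor exactly 0
        ],
    )
    def test_efficiency_formula(self, donor, acceptor, crosstalk, expected):
        traj = compute_fret(np.full(5, donor), np.full(5, acceptor), crosstalk)
        assert traj.fret == pytest.approx(expected)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            compute_fret(np.ones(5), np.ones(4))

    def test_nonpositive_total_flagged_invalid(self):
        traj = compute_fret(np.array([0.0, 100.0]), np.array([0.0, 100.0]))
        assert not traj.valid[0] and traj.valid[1]

    @given(
        scale=st.floats(0.01, 100.0),
        donor=st.floats(10.0, 1000.0),
        acceptor=st.floats(10.0, 1000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, donor, acceptor):
        """Multiplying both channels by a constant leaves E unchanged."""
        base = compute_fret(np.array([donor]), np.array([acceptor]))
        scaled = compute_fret(np.array([donor * scale]), np.array([acceptor * scale]))
        assert scaled.fret[0] == pytest.approx(base.fret[0], rel=1e-9)


class TestMixture:
    def test_single_gaussian_recovery(self, rng):
        x = rng.normal(0.43, 0.07, 10_000)
        fit = fit_fret_mixture(x, n_components=1)
        assert fit.component_means[0] == pytest.approx(0.43, abs=0.01)

    def test_two_state_recovery(self, rng):
        x = np.concatenate(
            [rng.normal(0.20, 0.07, 5000), rng.normal(0.43, 0.07, 5000)]
        )
        fit = fit_fret_mixture(x, init=(0.20, 0.43))
        assert fit.component_means == pytest.approx([0.20, 0.43], abs=0.02)
        assert fit.component_weights == pytest.approx([0.5, 0.5], abs=0.05)
        # histogram least-squares alternative agrees
        hfit = fit_fret_mixture_histogram(x, init=(0.20, 0.43))
        assert hfit.component_means == pytest.approx([0.20, 0.43], abs=0.02)
        assert hfit.component_weights == pytest.approx([0.5, 0.5], abs=0.05)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_fret_mixture(np.full(500, 0.3))

    def test_bound_fraction_is_low_component_weight(self, rng):
        x = np.concatenate(
            [rng.normal(0.20, 0.07, 3500), rng.normal(0.43, 0.07, 6500)]
        )
        fit = fit_fret_mixture(x, init=(0.20, 0.43))
        assert bound_fraction(fit) == pytest.approx(0.35, abs=0.03)
        one = fit_fret_mixture(rng.normal(0.4, 0.05, 500), n_components=1)
        with pytest.raises(ValueError):
            bound_fraction(one)


class TestHill:
    def test_noise_free_inversion(self):
        c = np.array([10.0, 36.0, 100.0, 300.0, 1000.0, 3000.0])
        fit = fit_hill(c, hill_curve(c, 36.0, 2.4))
        assert fit.kd == pytest.approx(36.0, rel=1e-4)
        assert fit.hill_n == pytest.approx(2.4, rel=1e-4)

    def test_midpoint_identity(self):
        for n in (0.5, 1.0, 2.4, 4.0):
            assert hill_curve(np.array([36.0]), 36.0, n)[0] == pytest.approx(0.5)

    def test_non_identifiable_rejected(self):
        with pytest.raises(ValueError, match="not identifiable"):
            fit_hill([1.0, 10.0, 100.0, 1000.0], [0.4, 0.4, 0.4, 0.4])

    @given(
        kd=st.floats(1.0, 1000.0),
        n=st.floats(0.5, 4.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_on_curve_recovery_any_parameters(self, kd, n):
        """Noise-free on-curve data inverts across the parameter space."""
        c = kd * np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
        fit = fit_hill(c, hill_curve(c, kd, n))
        assert fit.kd == pytest.approx(kd, rel=1e-3)
        assert fit.hill_n == pytest.approx(n, rel=1e-3)

    def test_titration_analysis_recovers_binding_parameters(self):
        concs = [0.0, 10.0, 100.0, 300.0, 1000.0, 3000.0]
        counts = [179, 139, 77, 70, 172, 68]
        kds, ns = [], []
        rng = np.random.default_rng(42)
        for _ in range(25):
            data = simulate_titration(36.0, 2.4, concs, counts, rng=rng)
            _, fit = analyze_titration(concs, data.fret_values)
            kds.append(fit.kd)
            ns.append(fit.hill_n)
        assert np.median(kds) == pytest.approx(36.0, abs=10.0)
        assert np.median(ns) == pytest.approx(2.4, abs=0.2)


class TestSegmentStates:
    def test_constant_bound_trace(self):
        traj = compute_fret(
            np.full(100, 800.0), np.full(100, 200.0), frame_interval=0.1
        )  # E = 0.2
        segs = segment_states(traj)
        assert len(segs) == 1
        assert segs[0].state == "bound"
        assert segs[0].duration == pytest.approx(10.0)
        assert segs[0].censored

    def test_interior_dwell_uncensored(self):
        e = np.concatenate([np.full(10, 0.4), np.full(20, 0.2), np.full(10, 0.4)])
        donor = (1 - e) * 1000
        acceptor = e * 1000
        segs = segment_states(compute_fret(donor, acceptor, frame_interval=0.1))
        bound = [s for s in segs if s.state == "bound"]
        assert len(bound) == 1
        assert bound[0].duration == pytest.approx(2.0)
        assert not bound[0].censored
        assert segs[0].censored and segs[-1].censored

    def test_threshold_is_strict(self):
        e = np.array([0.3, 0.29999, 0.3])
        traj = compute_fret((1 - e) * 1000, e * 1000, frame_interval=0.1)
        segs = segment_states(traj, threshold=0.3)
        assert [s.state for s in segs] == ["unbound", "bound", "unbound"]

    @given(st.lists(st.floats(0.0, 0.6), min_size=2, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_segments_tile_trace(self, values):
        e = np.asarray(values)
        traj = compute_fret((1 - e) * 1000, e * 1000, frame_interval=0.1)
        segs = segment_states(traj)
        assert sum(s.duration for s in segs) == pytest.approx(traj.duration)
        # idempotence: re-thresholding per-segment states reproduces them
        starts = np.array([s.start_time for s in segs])
        assert np.all(np.diff(starts) > 0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            compute_fret(np.array([]), np.array([]))


class TestSurvival:
    def test_survival_starts_at_one(self, rng):
        d = rng.exponential(5.0, 100)
        t, s = empirical_survival(d)
        assert t[0] == 0.0 and s[0] == 1.0

    def test_single_exponential_collapses(self, rng):
        d = rng.exponential(10.0, 5000)
        fit = fit_survival_biexp(d)
        assert fit.prefers_single or fit.k_off_fast / fit.k_off_slow < 1.2

    @pytest.mark.parametrize("f_slow", [0.35, 0.65, 0.91])
    def test_parameter_recovery(self, f_slow):
        """Median recovery across replicate 2000-event samples."""
        kf, ks, fs = [], [], []
        rng = np.random.default_rng(7)
        for _ in range(75):
            d = sample_biexponential_dwells(2000, 0.23, 0.044, f_slow, rng)
            fit = fit_survival_biexp(d)
            kf.append(fit.k_off_fast)
            ks.append(fit.k_off_slow)
            fs.append(fit.fraction_slow)
        assert np.median(kf) == pytest.approx(0.23, rel=0.10)
        assert np.median(ks) == pytest.approx(0.044, rel=0.10)
        assert np.median(fs) == pytest.approx(f_slow, abs=0.05)

    def test_insufficient_events_rejected(self):
        with pytest.raises(ValueError, match="dwell times"):
            fit_survival_biexp(np.ones(10))


class TestFrameIntervalBias:
    def test_fast_rate_underestimated_as_interval_grows(self):
        """Frame quantization biases the recovered rate low, monotonically."""
        from recastate.fret import bound_dwell_times
        from recastate.synthetic import TwoStateKineticModel, simulate_fret_trajectory

        k_true = 0.5
        recovered = []
        for dt in (0.1, 0.6, 1.5):
            model = TwoStateKineticModel(
                k_bind=0.5, k_off_fast=k_true, k_off_slow=k_true, f_slow=0.0,
                frame_interval=dt, seed=5,
            )
            rng = np.random.default_rng(5)
            dwells = []
            while len(dwells) < 1500:
                sim = simulate_fret_trajectory(model, 300.0, rng)
                segs = segment_states(sim.trajectory)
                dwells.extend(bound_dwell_times(segs))
            fit = fit_survival_biexp(np.asarray(dwells))
            recovered.append(fit.k_single)
        assert recovered[0] > recovered[1] > recovered[2]
        assert recovered[2] < k_true
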