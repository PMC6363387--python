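"""Tests of the synthetic generators against their own ground truth."""

import numpy as np
import pytest
from scipy import stats

from recastate.synthetic import (
    CellFieldConfig,
    EventTimeDistribution,
    InductionCurve,
    PlacementError,
    StorageStructureParams,
    TimelapseConfig,
    TwoStateKineticModel,
    sample_biexponential_dwells,
    simulate_cell_field,
    simulate_fret_trajectory,
    simulate_timelapse,
    simulate_titration,
)


class TestFretGenerator:
    def test_seeded_determinism(self):
        model = TwoStateKineticModel(seed=3)
        a = simulate_fret_trajectory(model, 60.0)
        b = simulate_fret_trajectory(model, 60.0)
        np.testing.assert_array_equal(
            a.trajectory.donor_intensity, b.trajectory.donor_intensity
        )
        np.testing.assert_array_equal(
            a.trajectory.acceptor_intensity, b.trajectory.acceptor_intensity
        )

    def test_no_binding_stays_unbound(self):
        model = TwoStateKineticModel(k_bind=0.0, seed=1)
        sim = simulate_fret_trajectory(model, 120.0)
        assert set(sim.frame_states) == {"unbound"}
        n = len(sim.trajectory.fret)
        se = model.fret_unbound_sd / np.sqrt(n)
        assert abs(sim.trajectory.fret.mean() - model.fret_unbound_mean) < 3 * se

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_fret_trajectory(TwoStateKineticModel(), -1.0)

    def test_true_dwells_follow_biexponential_mixture(self):
        """Pooled bound dwells match the closed-form mixture survival."""
        model = TwoStateKineticModel(k_bind=0.5, seed=9)
        rng = np.random.default_rng(9)
        dwells = []
        while len(dwells) < 5000:
            sim = simulate_fret_trajectory(model, 600.0, rng)
            dwells += [
                s.duration
                for s in sim.segments
                if s.state == "bound" and not s.censored
            ]
        dwells = np.asarray(dwells[:5000])

        def mixture_cdf(t):
            return 1 - (0.09 * np.exp(-0.23 * t) + 0.91 * np.exp(-0.044 * t))

        ks = stats.kstest(dwells, mixture_cdf).statistic
        assert ks < 0.03

    def test_emission_matches_configured_gaussian(self):
        """Pure-state FRET histogram passes a chi-square test vs the model."""
        model = TwoStateKineticModel(k_bind=0.0, frame_interval=0.1, seed=21)
        sim = simulate_fret_trajectory(model, 1000.0)
        edges = np.linspace(0.43 - 4 * 0.07, 0.43 + 4 * 0.07, 21)
        x = np.clip(sim.trajectory.fret, edges[0], edges[-1] - 1e-9)
        obs, _ = np.histogram(x, bins=edges)
        cdf = stats.norm(0.43, 0.07).cdf(edges)
        p = np.diff(cdf)
        # fold tail mass into end bins
        p[0] += cdf[0]
        p[-1] += 1 - cdf[-1]
        chi2, pval = stats.chisquare(obs, f_exp=p * len(x))
        assert pval > 0.01

    def test_crosstalk_roundtrip(self):
        """Crosstalk-corrected FRET reproduces the drawn emission exactly."""
        clean = simulate_fret_trajectory(TwoStateKineticModel(seed=4), 60.0)
        leaky = simulate_fret_trajectory(
            TwoStateKineticModel(crosstalk=0.15, seed=4), 60.0
        )
        np.testing.assert_allclose(
            clean.trajectory.fret, leaky.trajectory.fret, rtol=1e-9
        )


class TestTitrationGenerator:
    def test_midpoint_and_zero(self, rng):
        data = simulate_titration(36.0, 2.4, [0.0, 36.0], [2000, 2000], rng=rng)
        assert data.bound_labels[0].sum() == 0
        assert data.bound_labels[1].mean() == pytest.approx(0.5, abs=0.04)

    def test_hill_probability_at_high_concentration(self, rng):
        p = 3000.0 ** 2.4 / (3000.0 ** 2.4 + 36.0 ** 2.4)
        data = simulate_titration(36.0, 2.4, [3000.0], [1000], rng=rng)
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(data.bound_labels[0].mean() - p) < 3 * max(se, 1e-3)

    def test_invalid_kd_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_titration(-1.0, 2.4, [10.0], [10], rng=rng)

    def test_dwell_sampler_mixture_fractions(self, rng):
        d = sample_biexponential_dwells(20000, 0.23, 0.044, 0.5, rng)
        # mean of an even mixture: 0.5/0.23 + 0.5/0.044
        assert d.mean() == pytest.approx(0.5 / 0.23 + 0.5 / 0.044, rel=0.05)


class TestCellFieldGenerator:
    def test_seeded_determinism(self):
        cfg = CellFieldConfig(n_cells=10, seed=5)
        a = simulate_cell_field(cfg)
        b = simulate_cell_field(cfg)
        np.testing.assert_array_equal(a.brightfield, b.brightfield)
        np.testing.assert_array_equal(a.channels["a"], b.channels["a"])
        assert a.foci.equals(b.foci)

    def test_empty_field(self):
        field = simulate_cell_field(CellFieldConfig(n_cells=0, seed=1))
        assert field.cells == []
        assert len(field.foci) == 0
        assert field.brightfield.std() < 20  # pure background + noise

    def test_full_colocalization(self):
        cfg = CellFieldConfig(n_cells=40, colocalized_fraction=1.0, seed=2)
        field = simulate_cell_field(cfg)
        foci = field.foci
        a = foci[foci.channel == "a"][["x_um", "y_um"]].to_numpy()
        b = foci[foci.channel == "b"]
        eligible = b[b.cell_id.isin(foci[foci.channel == "a"].cell_id)]
        assert eligible.colocalized.all()
        for _, f in eligible.iterrows():
            d = np.hypot(a[:, 0] - f.x_um, a[:, 1] - f.y_um)
            assert d.min() <= cfg.colocalization_radius

    def test_poisson_focus_counts(self):
        """Empirical mean counts match the configured Poisson means."""
        cfg = CellFieldConfig(
            n_cells=200,
            foci_per_cell_channel_a=4.0,
            foci_per_cell_channel_b=1.5,
            seed=8,
        )
        field = simulate_cell_field(cfg)
        n_a = (field.foci.channel == "a").sum() / 200
        n_b = (field.foci.channel == "b").sum() / 200
        assert abs(n_a - 4.0) < 3 * np.sqrt(4.0 / 200)
        assert abs(n_b - 1.5) < 3 * np.sqrt(1.5 / 200)

    def test_foci_conserved_between_truth_and_render(self):
        """Every ground-truth focus produces a local brightening."""
        cfg = CellFieldConfig(n_cells=20, seed=3)
        field = simulate_cell_field(cfg)
        for _, f in field.foci.iterrows():
            img = field.channels[f.channel]
            r, c = int(round(f.y_px)), int(round(f.x_px))
            assert img[r, c] > cfg.cytosol_level + 0.5 * cfg.focus_amplitude

    def test_infeasible_cell_length_errors(self):
        cfg = CellFieldConfig(n_cells=4, box_px=20, seed=1)
        with pytest.raises(PlacementError, match="grid box"):
            simulate_cell_field(cfg)


class TestTimelapseGenerator:
    def test_flat_curve_is_flat(self):
        tc = TimelapseConfig(
            induction_curve=InductionCurve(amplitude=0.0), seed=2
        )
        fi = tc.induction_curve(tc.times_min)
        np.testing.assert_allclose(fi, 1.0)

    def test_fixed_dissolution_time_clears_structure(self):
        fc = CellFieldConfig(
            n_cells=6, seed=4, storage_structure_params=StorageStructureParams()
        )
        tc = TimelapseConfig(
            dissolution_time_distribution=EventTimeDistribution(45.0, kind="fixed"),
            dissolving_fraction=1.0,
            appearance_probability=0.0,
            seed=4,
        )
        res = simulate_timelapse(tc, fc)
        frame_at_45 = int(np.ceil(45.0 / 5.0))
        assert (res.events.event == "dissolved").all()
        assert (res.events.event_frame == frame_at_45).all()
        for s in res.structures:
            r, c = s.mask_indices(res.field.shape)
            before = res.stack[frame_at_45 - 1][r, c].mean()
            after = res.stack[frame_at_45][r, c].mean()
            assert before > 4500 and after < 4000

    def test_event_time_distribution_median(self, rng):
        d = EventTimeDistribution(45.0, 0.5)
        t = d.sample(20000, rng)
        assert np.median(t) == pytest.approx(45.0, rel=0.03)
        assert (t >= 0).all()
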