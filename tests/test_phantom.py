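"""Bolus generation, compartment simulation, noise and volume rendering."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import flowphantom as fp
from flowphantom.units import decay_constant, ml_min_to_ml_s, per_min_to_per_s


@pytest.fixture(scope="module")
def settings():
    return fp.PhantomSettings.from_nominal(150.0, 0.2)


@pytest.fixture(scope="module")
def bolus():
    return fp.generate_bolus(500.0)


class TestGenerateBolus:
    def test_calibrated_to_requested_activity(self, bolus):
        assert bolus.injected_activity == pytest.approx(500.0)
        integral = np.trapezoid(bolus.activity_rate, bolus.time_grid)
        assert integral == pytest.approx(500.0, rel=1e-3)
        assert bolus.within_spec

    def test_dispense_error_reproducible_and_bounded(self):
        b1 = fp.generate_bolus(500.0, dispense_error_fraction=0.15, seed=42)
        b2 = fp.generate_bolus(500.0, dispense_error_fraction=0.15, seed=42)
        assert b1 == b2
        assert abs(b1.injected_activity - 500.0) <= 0.15 * 500.0
        b3 = fp.generate_bolus(500.0, dispense_error_fraction=0.15, seed=43)
        assert b3.injected_activity != b1.injected_activity

    def test_zero_amplitude_cannot_be_calibrated(self):
        with pytest.raises(ValueError, match="calibrate"):
            fp.generate_bolus(500.0, amplitude=0.0)

    def test_negative_requested_rejected(self):
        with pytest.raises(ValueError):
            fp.generate_bolus(-1.0)


class TestSimulatePhantom:
    def test_no_inflow_no_spillover_gives_zero_tissue(self, settings, bolus):
        truth = fp.GroundTruth(qin_true=0.0, qout_true=0.5, isf_true=0.0)
        _, tissue = fp.simulate_phantom(settings, truth, bolus)
        np.testing.assert_allclose(tissue.values, 0.0)

    def test_curves_nonnegative(self, settings, bolus):
        truth = fp.GroundTruth.ideal(settings, isf=0.1, delay=5.0)
        cin, tissue = fp.simulate_phantom(settings, truth, bolus)
        assert np.all(cin.values >= 0.0)
        assert np.all(tissue.values >= 0.0)

    def test_mass_balance_without_decay(self, settings, bolus):
        truth = fp.GroundTruth.ideal(settings, isf=0.1, delay=5.0)
        mb = fp.mass_balance(settings, truth, bolus)
        assert mb["relative_error"] < 0.005

    def test_agrees_with_independent_ode_integration(self, settings, bolus):
        # same equations through scipy's stiff integrator, physical (decaying) form
        truth = fp.GroundTruth.ideal(settings, isf=0.0, delay=0.0)
        lam = decay_constant(122.24)
        flush = ml_min_to_ml_s(settings.qpump) / settings.v_input
        qin_s = per_min_to_per_s(truth.qin_true)
        qout_s = per_min_to_per_s(truth.qout_true)
        t, r = bolus.time_grid, bolus.activity_rate

        def rhs(tt, y):
            b = np.interp(tt, t, r) * 1000.0 / settings.v_input
            cin, ct = y
            return [b - (flush + lam) * cin, qin_s * cin - (qout_s + lam) * ct]

        eval_t = np.arange(0.0, 280.0 + 0.5, 1.0)
        sol = solve_ivp(rhs, (0.0, 280.0), [0.0, 0.0], method="LSODA",
                        t_eval=eval_t, rtol=1e-10, atol=1e-8)
        cin, tissue = fp.simulate_phantom(settings, truth, bolus)
        for curve, ref in ((cin, sol.y[0]), (tissue, sol.y[1])):
            mine = np.interp(eval_t, curve.time_grid, curve.values)
            assert np.max(np.abs(mine - ref)) < 1e-3 * np.max(np.abs(ref))

    def test_higher_washout_lowers_tissue_tail(self, settings, bolus):
        tails = []
        for qout in (0.2, 0.4, 0.8):
            truth = fp.GroundTruth(qin_true=0.625, qout_true=qout, isf_true=0.0)
            _, tissue = fp.simulate_phantom(settings, truth, bolus)
            tails.append(tissue.values[-1])
        assert tails[0] > tails[1] > tails[2]

    def test_end_to_end_recovery_at_qref_100(self):
        # Qref = 100 ml/min, Vcyl = 160 ml -> rates 0.625 /min; the fitted
        # flows must come back as Qin = Qout = 100 (ideal phantom identity)
        settings = fp.PhantomSettings.from_nominal(200.0, 0.5)
        assert settings.qref == pytest.approx(100.0)
        truth = fp.GroundTruth.ideal(settings, isf=0.1, delay=5.0)
        assert truth.qin_true == pytest.approx(0.625)
        bolus = fp.generate_bolus(500.0)
        cin, tissue = fp.simulate_phantom(settings, truth, bolus)
        sched = fp.build_frame_schedule(fp.default_frame_spec())
        input_dc = fp.decay_correct(fp.sample_frames(cin, sched))
        tissue_dc = fp.decay_correct(fp.sample_frames(tissue, sched))
        fit = fp.fit_model(input_dc, tissue_dc, vcyl=160.0)
        assert fit.Qin == pytest.approx(100.0, rel=0.01)
        assert fit.Qout == pytest.approx(100.0, rel=0.01)

    def test_zero_chamber_volume_rejected(self):
        with pytest.raises(ValueError):
            fp.PhantomSettings.from_nominal(150.0, 0.2, v_input=0.0)


class TestAddNoise:
    def test_zero_scale_is_identity(self, schedule):
        tac = fp.SampledTAC(schedule, np.linspace(5, 100, 24))
        out = fp.add_noise(tac, 0.0, seed=1)
        assert out == tac

    def test_seeded_reproducibility(self, schedule):
        tac = fp.SampledTAC(schedule, np.linspace(5, 100, 24))
        a = fp.add_noise(tac, 2.5, seed=9)
        b = fp.add_noise(tac, 2.5, seed=9)
        assert a == b
        c = fp.add_noise(tac, 2.5, seed=10)
        assert not np.array_equal(a.values, c.values)

    def test_empirical_sd_matches_variance_model(self, schedule):
        # 1000 replicates of one frame; SD must match the formula within 10%
        value, frame = 200.0, 5
        tac = fp.SampledTAC(schedule, np.full(24, value))
        reps = np.array([fp.add_noise(tac, 2.5, seed=s).values[frame] for s in range(1000)])
        lam = decay_constant(122.24)
        t0 = schedule.frame_starts[frame]
        d = schedule.frame_durations[frame]
        df = np.exp(-lam * t0) * (1 - np.exp(-lam * d)) / (lam * d)
        expected_sd = 2.5 * np.sqrt(value / (d * df))
        assert np.std(reps, ddof=1) == pytest.approx(expected_sd, rel=0.10)


class TestVolumeRendering:
    def test_round_trip_recovers_tacs_exactly(self, schedule):
        rng = np.random.default_rng(5)
        input_tac = fp.SampledTAC(schedule, rng.uniform(0, 100, 24))
        tissue_tac = fp.SampledTAC(schedule, rng.uniform(0, 50, 24))
        vol, m_in, m_tis = fp.render_volume_series(input_tac, tissue_tac)
        got_in = fp.extract_voi_tac(vol, m_in, schedule)
        got_tis = fp.extract_voi_tac(vol, m_tis, schedule)
        # uniform fill: the VOI mean reproduces each value up to summation rounding
        np.testing.assert_allclose(got_in.values, input_tac.values, rtol=1e-12)
        np.testing.assert_allclose(got_tis.values, tissue_tac.values, rtol=1e-12)

    def test_single_voxel_mask_equals_full_mask_for_uniform_fill(self, schedule):
        input_tac = fp.SampledTAC(schedule, np.linspace(1, 24, 24))
        tissue_tac = fp.SampledTAC(schedule, np.linspace(24, 1, 24))
        vol, m_in, _ = fp.render_volume_series(input_tac, tissue_tac)
        one = np.zeros_like(m_in)
        idx = np.argwhere(m_in)[0]
        one[tuple(idx)] = True
        np.testing.assert_allclose(
            fp.extract_voi_tac(vol, one, schedule).values,
            fp.extract_voi_tac(vol, m_in, schedule).values,
        )

    def test_empty_mask_rejected(self, schedule):
        tac = fp.SampledTAC(schedule, np.ones(24))
        vol, m_in, _ = fp.render_volume_series(tac, tac.with_values(2 * tac.values))
        with pytest.raises(ValueError, match="empty"):
            fp.extract_voi_tac(vol, np.zeros_like(m_in), schedule)

    def test_overlapping_masks_rejected(self, schedule):
        tac = fp.SampledTAC(schedule, np.ones(24))
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[2:5] = True
        with pytest.raises(ValueError, match="disjoint"):
            fp.render_volume_series(tac, tac, masks=(mask, mask))
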