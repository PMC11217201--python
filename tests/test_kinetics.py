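"""Decay correction, the one-tissue forward model, AUC and model fitting."""

import numpy as np
import pytest

import flowphantom as fp
from flowphantom._conv import expconv_pl
from flowphantom.fileio import RunConfig
from flowphantom.pipeline import fit_measurement, simulate_measurement


def _smooth_input(t_end=280.0, step=0.1):
    t = np.arange(0.0, t_end + step / 2, step)
    tau = np.clip(t - 3.0, 0.0, None)
    return fp.ContinuousCurve(t, 500.0 * tau ** 2 * np.exp(-tau / 5.0) / 100.0)


class TestDecayCorrect:
    def test_infinite_half_life_is_identity(self, schedule):
        tac = fp.SampledTAC(schedule, np.linspace(1, 10, 24))
        out = fp.decay_correct(tac, half_life_s=np.inf)
        np.testing.assert_allclose(out.values, tac.values)
        assert out.decay_corrected

    def test_instantaneous_value_doubles_after_one_half_life(self):
        # value 100 measured around t = T1/2 corrects to ~200 (2^(t/T1/2));
        # a very short frame approximates an instantaneous sample
        half = 122.24
        sched = fp.FrameSchedule(np.array([half - 5e-4]), np.array([1e-3]))
        tac = fp.SampledTAC(sched, np.array([100.0]))
        out = fp.decay_correct(tac, half_life_s=half)
        assert out.values[0] == pytest.approx(200.0, rel=1e-5)

    def test_round_trip_is_exact(self, schedule):
        rng = np.random.default_rng(7)
        tac = fp.SampledTAC(schedule, rng.uniform(1.0, 500.0, 24))
        back = fp.decay_correct(fp.decay_correct(tac), direction="remove")
        assert np.max(np.abs(back.values - tac.values) / tac.values) < 1e-9

    def test_double_correction_rejected(self, schedule):
        tac = fp.SampledTAC(schedule, np.ones(24))
        corrected = fp.decay_correct(tac)
        with pytest.raises(ValueError):
            fp.decay_correct(corrected)
        with pytest.raises(ValueError):
            fp.decay_correct(tac, direction="remove")


class TestForwardModel:
    def test_null_response(self):
        cin = _smooth_input()
        model = fp.forward_model(fp.KineticParams(qin=0.0, qout=0.5, isf=0.0), cin)
        np.testing.assert_allclose(model.values, 0.0)

    def test_pure_spillover_reproduces_input(self):
        cin = _smooth_input()
        model = fp.forward_model(fp.KineticParams(qin=0.0, qout=0.5, isf=1.0, delay=0.0), cin)
        np.testing.assert_allclose(model.values, cin.values, rtol=1e-12)

    def test_steady_state_closed_form(self):
        # constant input c: model -> c (isf + qin/qout) as t -> infinity
        t = np.arange(0.0, 5000.0, 0.5)
        c = 10.0
        cin = fp.ContinuousCurve(t, np.full_like(t, c))
        p = fp.KineticParams(qin=0.4, qout=0.8, isf=0.2)
        model = fp.forward_model(p, cin)
        assert model.values[-1] == pytest.approx(c * (p.isf + p.qin / p.qout), rel=1e-4)

    def test_agrees_with_riemann_convolution(self):
        # brute-force Riemann sum on a 0.01 s grid, smooth input
        t = np.arange(0.0, 120.0001, 0.01)
        tau = np.clip(t - 2.0, 0.0, None)
        c = tau ** 2 * np.exp(-tau / 6.0)
        p = fp.KineticParams(qin=0.625, qout=0.625, isf=0.1, delay=4.0)
        model = fp.forward_model(p, fp.ContinuousCurve(t, c))
        cs = np.interp(t - p.delay, t, c, left=0.0)
        k = p.qout / 60.0
        idx = np.arange(0, t.size, 400)
        brute = np.array([np.sum(cs[: i + 1] * np.exp(-k * (t[i] - t[: i + 1]))) * 0.01 for i in idx])
        ref = p.isf * cs[idx] + p.qin / 60.0 * brute
        err = np.max(np.abs(model.values[idx] - ref)) / np.max(np.abs(ref))
        assert err < 5e-4

    def test_scaled_spillover_mode(self):
        cin = _smooth_input()
        p = fp.KineticParams(qin=0.5, qout=0.5, isf=0.3)
        additive = fp.forward_model(p, cin, spillover_mode="additive")
        scaled = fp.forward_model(p, cin, spillover_mode="scaled")
        conv_term = additive.values - p.isf * cin.values
        np.testing.assert_allclose(scaled.values, p.isf * cin.values + 0.7 * conv_term, rtol=1e-10)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            fp.KineticParams(qin=-0.1, qout=0.5)


class TestToFlowAndAuc:
    def test_rate_times_volume(self):
        assert fp.to_flow(0.625, 160.0) == pytest.approx(100.0)
        assert fp.to_flow(0.0, 160.0) == 0.0
        assert fp.to_flow(1.0, 160.0) == 160.0

    def test_vcyl_must_be_positive(self):
        with pytest.raises(ValueError):
            fp.to_flow(0.5, 0.0)

    def test_sampled_auc_constant(self):
        sched = fp.build_frame_schedule([(1, 10.0)])
        assert fp.auc(fp.SampledTAC(sched, np.array([2.0]))) == pytest.approx(20.0)

    def test_auc_is_linear(self, schedule):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 50, 24)
        tac = fp.SampledTAC(schedule, v)
        assert fp.auc(tac.with_values(3.0 * v)) == pytest.approx(3.0 * fp.auc(tac))

    def test_constant_one_on_clinical_schedule_gives_scan_duration(self, schedule):
        assert fp.auc(fp.SampledTAC(schedule, np.ones(24))) == pytest.approx(280.0)


class TestFitModel:
    def test_noiseless_recovery_at_reference_condition(self, noiseless_measurement):
        # qin = qout = 0.625 /min (Qref 100 ml/min at Vcyl 160), ISF 0.1, delay 5 s
        cfg, meas = noiseless_measurement
        fit = fit_measurement(meas, cfg)
        truth = meas.truth
        assert fit.converged
        assert fit.params.qin == pytest.approx(truth.qin_true, rel=0.01)
        assert fit.params.qout == pytest.approx(truth.qout_true, rel=0.01)
        assert fit.params.isf == pytest.approx(truth.isf_true, rel=0.01)
        assert fit.params.delay == pytest.approx(truth.delay_true, abs=0.2)
        assert fit.Qin == pytest.approx(100.0, rel=0.01)
        assert fit.Qout == pytest.approx(100.0, rel=0.01)

    def test_pure_spillover_tissue_fits_near_zero_qin(self, noiseless_measurement):
        cfg, meas = noiseless_measurement
        input_dc = fp.decay_correct(meas.input_tac)
        isf = 0.25
        tissue = input_dc.with_values(isf * input_dc.values)
        fit = fp.fit_model(input_dc, tissue, vcyl=160.0, delay_grid=[0.0])
        assert fit.params.qin < 0.005
        assert fit.params.isf == pytest.approx(isf, rel=0.01)

    def test_zero_tissue_flagged_low_signal(self, noiseless_measurement):
        cfg, meas = noiseless_measurement
        input_dc = fp.decay_correct(meas.input_tac)
        tissue = input_dc.with_values(np.zeros(24))
        fit = fp.fit_model(input_dc, tissue, vcyl=160.0, delay_grid=[0.0])
        assert fit.low_signal
        assert fit.converged
        assert fit.params.qin == pytest.approx(0.0, abs=1e-6)

    def test_mismatched_schedules_rejected(self, noiseless_measurement):
        cfg, meas = noiseless_measurement
        input_dc = fp.decay_correct(meas.input_tac)
        other = fp.build_frame_schedule([(28, 10.0)])
        tissue = fp.SampledTAC(other, np.ones(28), decay_corrected=True)
        with pytest.raises(ValueError, match="schedule"):
            fp.fit_model(input_dc, tissue, vcyl=160.0)

    def test_uncorrected_tacs_rejected(self, noiseless_measurement):
        cfg, meas = noiseless_measurement
        with pytest.raises(ValueError, match="decay corrected"):
            fp.fit_model(meas.input_tac, meas.tissue_tac, vcyl=160.0)

    def test_fit_deterministic(self, noiseless_measurement):
        cfg, meas = noiseless_measurement
        f1 = fit_measurement(meas, cfg)
        f2 = fit_measurement(meas, cfg)
        assert f1.params == f2.params
        assert f1.rss == f2.rss

    def test_fitted_flow_invariant_to_global_rescaling(self, noiseless_measurement):
        cfg, meas = noiseless_measurement
        input_dc = fp.decay_correct(meas.input_tac)
        tissue_dc = fp.decay_correct(meas.tissue_tac)
        base = fp.fit_model(input_dc, tissue_dc, vcyl=160.0)
        scaled = fp.fit_model(
            input_dc.with_values(5.0 * input_dc.values),
            tissue_dc.with_values(5.0 * tissue_dc.values),
            vcyl=160.0,
        )
        assert scaled.Qin == pytest.approx(base.Qin, rel=1e-6)
        assert scaled.Qout == pytest.approx(base.Qout, rel=1e-6)

    def test_vcyl_scales_flow_conversion_linearly(self, noiseless_measurement):
        cfg, meas = noiseless_measurement
        input_dc = fp.decay_correct(meas.input_tac)
        tissue_dc = fp.decay_correct(meas.tissue_tac)
        f160 = fp.fit_model(input_dc, tissue_dc, vcyl=160.0)
        f80 = fp.fit_model(input_dc, tissue_dc, vcyl=80.0)
        assert f80.params.qin == pytest.approx(f160.params.qin, rel=1e-9)
        assert f80.Qin == pytest.approx(f160.Qin / 2.0, rel=1e-9)


class TestExpconv:
    def test_zero_rate_is_running_integral(self):
        t = np.arange(0.0, 10.5, 0.5)
        c = np.sin(t) + 1.5
        y = expconv_pl(t, c, 0.0)
        expected = np.concatenate([[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t))])
        np.testing.assert_allclose(y, expected, rtol=1e-12)

    def test_nonuniform_grid_matches_uniform(self):
        t_u = np.arange(0.0, 20.0001, 0.01)
        c_u = np.exp(-((t_u - 5) / 2.0) ** 2)
        y_u = expconv_pl(t_u, c_u, 0.3)
        t_n = np.unique(np.concatenate([t_u[::7], [20.0]]))
        y_n = expconv_pl(t_n, np.interp(t_n, t_u, c_u), 0.3)
        ref = np.interp(t_n, t_u, y_u)
        assert np.max(np.abs(y_n - ref)) < 2e-4 * np.max(y_u)
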