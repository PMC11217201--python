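"""End-to-end simulated measurement: config -> noisy framed TACs + ground truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .fileio import RunConfig
from .frames import SampledTAC, build_frame_schedule, default_frame_spec
from .kinetics import KineticFit, decay_correct, fit_model
from .phantom import BolusRecord, GroundTruth, PhantomSettings, add_noise, generate_bolus, simulate_phantom, sample_frames

__all__ = ["SimulatedMeasurement", "simulate_measurement", "fit_measurement", "derive_seeds"]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2^31) from one master seed."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass(frozen=True)
class SimulatedMeasurement:
    """One simulated phantom scan with its full provenance."""

    settings: PhantomSettings
    truth: GroundTruth
    bolus: BolusRecord
    input_tac: SampledTAC    # physical (decaying), noisy if noise_scale > 0
    tissue_tac: SampledTAC


def simulate_measurement(cfg: RunConfig, seed: int | None = None) -> SimulatedMeasurement:
    """Simulate one measurement under a run configuration.

    The bolus dispense error and the frame noise of the two TACs use
    independent seeds derived from the master seed, so repeated calls with
    one seed are bit-identical and different seeds are independent.
    """
    master = cfg.seed if seed is None else seed
    s_bolus, s_in, s_tis = derive_seeds(master, 3)
    settings = PhantomSettings.from_nominal(
        qpump=cfg.qpump,
        constriction_fraction=cfg.constriction_fraction,
        vcyl=cfg.vcyl,
        v_input=cfg.v_input,
        flowmeter_calibration=cfg.flowmeter_calibration,
    )
    truth = GroundTruth.ideal(settings, isf=cfg.isf_true, delay=cfg.delay_true_s)
    bolus = generate_bolus(
        cfg.requested_activity_MBq,
        dispense_error_fraction=cfg.dispense_error_fraction,
        seed=s_bolus,
    )
    schedule = build_frame_schedule(default_frame_spec())
    cin, tissue = simulate_phantom(
        settings, truth, bolus, decay_half_life=cfg.half_life_s, spillover_mode=cfg.spillover_mode
    )
    input_tac = sample_frames(cin, schedule)
    tissue_tac = sample_frames(tissue, schedule)
    if cfg.noise_scale > 0:
        input_tac = add_noise(input_tac, cfg.noise_scale, cfg.half_life_s, seed=s_in)
        tissue_tac = add_noise(tissue_tac, cfg.noise_scale, cfg.half_life_s, seed=s_tis)
    return SimulatedMeasurement(settings, truth, bolus, input_tac, tissue_tac)


def fit_measurement(meas: SimulatedMeasurement, cfg: RunConfig | None = None) -> KineticFit:
    """Decay-correct a simulated measurement's TACs and fit the kinetic model."""
    cfg = cfg or RunConfig()
    input_dc = decay_correct(meas.input_tac, cfg.half_life_s)
    tissue_dc = decay_correct(meas.tissue_tac, cfg.half_life_s)
    return fit_model(
        input_dc,
        tissue_dc,
        vcyl=meas.settings.vcyl,
        spillover_mode=cfg.spillover_mode,
        delay_grid=np.arange(0.0, cfg.delay_grid_max_s + cfg.delay_grid_step_s / 2, cfg.delay_grid_step_s),
        bounds={"qin_max": cfg.qin_max, "qout_max": cfg.qout_max},
    )
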