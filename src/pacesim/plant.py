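"""Synthetic respiratory plant: the in-silico anesthetized rat.

The plant stands in for the animal in closed-loop pacing experiments.  It
combines:

* piecewise-linear current-to-activation recruitment per muscle, zero below
  the twitch threshold and saturating at roughly twice it;
* a first-order charge-driven fatigue state per muscle — delivered charge
  pushes fatigue up, rest lets it recover — that scales the muscle's
  effective activation by ``(1 - F)``;
* first-order lung mechanics whose inspiratory drive sums the intrinsic
  respiratory drive, the two paced muscles, and a diaphragm-intercostal
  synergy term (co-activation yields more volume than the sum of the parts);
* an intrinsic breathing oscillator (central pattern generator) with a
  Hering-Breuer volume threshold: inflation past the threshold during
  intrinsic inspiration terminates the intrinsic breath and resets the
  oscillator to expiration, which is the mechanism by which pacing entrains
  the intrinsic rhythm;
* a breath-volume sensor with per-cycle baseline re-zeroing and Gaussian
  noise.

Everything integrates with explicit Euler at a 1 ms plant step (40 substeps
per 40 ms control step).  :func:`simulate_trial` runs the full protocol:
spontaneous baseline, target derivation at 120% of the baseline tidal
volume, then the adaptive closed loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .config import RunConfig
from .controller import (
    PGClock,
    PSState,
    SighSchedule,
    StimChannel,
    apply_sigh,
    channel_amplitude,
    encode_charge,
    inspiratory_window,
    ps_output,
    ps_update,
    volume_error,
)
from .records import TrialRecord

__all__ = [
    "MusclePlant",
    "LungModel",
    "IntrinsicCPG",
    "SensorModel",
    "recruit",
    "fatigue_step",
    "lung_step",
    "cpg_step",
    "measure",
    "calibrate_intrinsic_drive",
    "derive_baseline",
    "simulate_trial",
    "BaselineError",
]

MODES = ("spontaneous", "dia_only", "combined")


class BaselineError(RuntimeError):
    """Baseline phase could not be characterized (too few breath cycles)."""


# ---------------------------------------------------------------------------
# plant components
# ---------------------------------------------------------------------------

@dataclass
class MusclePlant:
    """One paced muscle: recruitment range and charge-driven fatigue."""

    twitch_threshold_mA: float
    saturation_mA: float
    k_f_per_mC: float = 0.06
    rho_per_s: float = 0.0025
    fatigue: float = 0.0

    def __post_init__(self) -> None:
        if self.saturation_mA <= self.twitch_threshold_mA:
            raise ValueError("saturation current must exceed the twitch threshold")


def recruit(amplitude_mA: float, muscle: MusclePlant) -> float:
    """Fraction of the muscle recruited at a given current amplitude:
    0 below the twitch threshold, linear up to saturation, 1 beyond."""
    if amplitude_mA < 0:
        raise ValueError("amplitude must be nonnegative")
    if amplitude_mA < muscle.twitch_threshold_mA:
        return 0.0
    a = (amplitude_mA - muscle.twitch_threshold_mA) / (
        muscle.saturation_mA - muscle.twitch_threshold_mA
    )
    return min(a, 1.0)


def fatigue_step(muscle: MusclePlant, charge_rate_mC_s: float, dt: float) -> MusclePlant:
    """One Euler step of the fatigue state.

    dF/dt = k_f * charge_rate * (1 - F) - rho * F, clipped to [0, 1].
    Charge drives fatigue toward 1, rest recovers toward 0; the equilibrium
    under constant charge rate q is k_f q / (k_f q + rho).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if charge_rate_mC_s < 0:
        raise ValueError("charge rate must be nonnegative")
    f = muscle.fatigue
    f += dt * (muscle.k_f_per_mC * charge_rate_mC_s * (1.0 - f) - muscle.rho_per_s * f)
    muscle.fatigue = min(max(f, 0.0), 1.0)
    return muscle


@dataclass
class LungModel:
    """First-order lung volume dynamics with muscle synergy.

    Inspiratory drive P = intrinsic + g_dia*a_dia + g_eic*a_eic +
    g_syn*a_dia*a_eic (volume equivalents, ml); the volume relaxes toward P
    with time constant ``tau_s``, so expiration is passive decay to zero.
    """

    tau_s: float = 0.15
    g_dia_ml: float = 1.0
    g_eic_ml: float = 0.3
    g_syn_ml: float = 0.4
    volume_ml: float = 0.0


def lung_step(
    lung: LungModel,
    a_dia_eff: float,
    a_eic_eff: float,
    intrinsic_drive_ml: float,
    dt: float,
) -> LungModel:
    """One Euler step of lung volume under the combined drive."""
    p = (
        intrinsic_drive_ml
        + lung.g_dia_ml * a_dia_eff
        + lung.g_eic_ml * a_eic_eff
        + lung.g_syn_ml * a_dia_eff * a_eic_eff
    )
    lung.volume_ml += dt * (p - lung.volume_ml) / lung.tau_s
    return lung


@dataclass
class IntrinsicCPG:
    """Free-running breathing oscillator with a Hering-Breuer volume reset.

    Phase theta wraps in [0, 1); the inspiratory half [0, 0.5) emits a
    half-sine drive scaled by ``drive_amplitude_ml`` (calibrated so the
    unassisted plant produces the configured baseline tidal volume).  The
    Hering-Breuer inflation reflex acts with hysteresis: if lung volume
    reaches ``v_hb_ml`` while the oscillator is inspiring, inspiration is cut
    short (theta jumps to the start of expiration, counted in ``resets``) and
    the reflex engages; while engaged, expiratory phase progression is held,
    and the reflex releases only once the lung has deflated below
    ``release_fraction x v_hb_ml`` (stretch-receptor firing outlasts the
    volume peak).  Together these let an assisted breath larger than the
    threshold entrain the intrinsic rhythm: the next intrinsic breath cannot
    begin until one expiratory half-period after deflation.  Set
    ``v_hb_ml = inf`` to disable the reflex.
    """

    t0_s: float = 1.5
    theta: float = 0.0
    drive_amplitude_ml: float = 1.0
    v_hb_ml: float = 1.1
    release_fraction: float = 0.25
    engaged: bool = False
    resets: int = 0


def cpg_step(cpg: IntrinsicCPG, volume_ml: float, dt: float):
    """Advance the oscillator one plant step.

    Returns ``(drive_ml, onset)`` where ``drive_ml`` is the intrinsic
    inspiratory drive for this step (already scaled by the calibrated
    amplitude) and ``onset`` flags a wrap through phase 0, i.e. the start of
    an intrinsic breath.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cpg.theta += dt / cpg.t0_s
    onset = False
    if cpg.theta >= 1.0:
        cpg.theta -= 1.0
        onset = True
    if cpg.engaged and volume_ml < cpg.release_fraction * cpg.v_hb_ml:
        cpg.engaged = False
    if cpg.theta < 0.5:
        if volume_ml >= cpg.v_hb_ml:
            cpg.theta = 0.5
            cpg.resets += 1
            cpg.engaged = True
            drive = 0.0
        else:
            drive = cpg.drive_amplitude_ml * math.sin(2.0 * math.pi * cpg.theta)
    else:
        if cpg.engaged:  # inflation reflex holds expiration until deflation
            cpg.theta = max(0.5, cpg.theta - dt / cpg.t0_s)
            onset = False
        drive = 0.0
    return drive, onset


@dataclass
class SensorModel:
    """Breath-volume sensor: per-cycle baseline re-zeroing plus Gaussian
    noise.  ``integrator_tau_s`` documents the physical flow-integrator time
    constant; the simulated readout is instantaneous."""

    noise_sd_ml: float = 0.02
    integrator_tau_s: float = 0.2
    baseline_ml: float = 0.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))


def measure(sensor: SensorModel, v_true_ml: float, cycle_start: bool = False) -> float:
    """Measured breath volume: true volume minus the baseline captured at the
    last cycle start, plus sensor noise.  Noise-free and freshly re-zeroed,
    the measurement equals the true volume change since cycle start."""
    if cycle_start:
        sensor.baseline_ml = v_true_ml
    return v_true_ml - sensor.baseline_ml + sensor.rng.normal(0.0, sensor.noise_sd_ml)


# ---------------------------------------------------------------------------
# fused control-interval integration (hot path)
# ---------------------------------------------------------------------------

def plant_control_step(
    dia: MusclePlant,
    eic: MusclePlant,
    lung: LungModel,
    cpg: IntrinsicCPG,
    i_dia_mA: float,
    i_eic_mA: float,
    q_dia_rate: float,
    q_eic_rate: float,
    n_sub: int,
    dt: float,
    t_start: float,
):
    """Advance the whole plant by one control interval (``n_sub`` Euler
    substeps of ``dt``) under constant stimulation amplitudes.

    This is the composition of :func:`fatigue_step`, :func:`cpg_step` and
    :func:`lung_step` with recruitment evaluated per substep (activation
    changes with fatigue), unrolled with local variables because it runs
    hundreds of thousands of times per trial.  Returns ``(v_max, onsets)``:
    the peak volume reached during the interval and the absolute times of
    intrinsic breath onsets within it.
    """
    a_dia_raw = recruit(i_dia_mA, dia)
    a_eic_raw = recruit(i_eic_mA, eic)
    f_d, f_e = dia.fatigue, eic.fatigue
    kf_d, rho_d = dia.k_f_per_mC, dia.rho_per_s
    kf_e, rho_e = eic.k_f_per_mC, eic.rho_per_s
    v = lung.volume_ml
    tau = lung.tau_s
    g_d, g_e, g_s = lung.g_dia_ml, lung.g_eic_ml, lung.g_syn_ml
    theta, t0, d0, v_hb = cpg.theta, cpg.t0_s, cpg.drive_amplitude_ml, cpg.v_hb_ml
    v_release = cpg.release_fraction * v_hb
    engaged = cpg.engaged
    resets = cpg.resets
    sin = math.sin
    two_pi = 2.0 * math.pi
    v_max = v
    onsets = []
    t = t_start
    for _ in range(n_sub):
        f_d += dt * (kf_d * q_dia_rate * (1.0 - f_d) - rho_d * f_d)
        if f_d < 0.0:
            f_d = 0.0
        elif f_d > 1.0:
            f_d = 1.0
        f_e += dt * (kf_e * q_eic_rate * (1.0 - f_e) - rho_e * f_e)
        if f_e < 0.0:
            f_e = 0.0
        elif f_e > 1.0:
            f_e = 1.0
        if engaged and v < v_release:
            engaged = False
        theta += dt / t0
        if theta >= 1.0:
            theta -= 1.0
            onsets.append(t)
        if theta < 0.5:
            if v >= v_hb:
                theta = 0.5
                resets += 1
                engaged = True
                drive = 0.0
            else:
                drive = d0 * sin(two_pi * theta)
        else:
            if engaged:  # inflation reflex holds expiration until deflation
                theta -= dt / t0
                if theta < 0.5:
                    theta = 0.5
            drive = 0.0
        a_de = a_dia_raw * (1.0 - f_d)
        a_ee = a_eic_raw * (1.0 - f_e)
        p = drive + g_d * a_de + g_e * a_ee + g_s * a_de * a_ee
        v += dt * (p - v) / tau
        if v > v_max:
            v_max = v
        t += dt
    dia.fatigue, eic.fatigue = f_d, f_e
    lung.volume_ml = v
    cpg.theta, cpg.resets, cpg.engaged = theta, resets, engaged
    return v_max, onsets


# ---------------------------------------------------------------------------
# calibration and baseline characterization
# ---------------------------------------------------------------------------

def calibrate_intrinsic_drive(cfg: RunConfig) -> float:
    """Intrinsic drive amplitude (ml) that makes the unassisted plant's tidal
    volume equal the configured baseline.  The lung is linear in the drive, so
    one probe simulation at unit amplitude fixes the scale exactly."""
    p = cfg.plant
    lung = LungModel(tau_s=p.tau_lung_s, g_dia_ml=p.dia.gain_ml, g_eic_ml=p.eic.gain_ml,
                     g_syn_ml=p.g_syn_ml)
    cpg = IntrinsicCPG(t0_s=p.t0_s, drive_amplitude_ml=1.0, v_hb_ml=math.inf)
    dt = p.plant_dt_s
    n_settle = int(round(3.0 * p.t0_s / dt))
    n_cycle = int(round(p.t0_s / dt))
    for _ in range(n_settle):
        drive, _ = cpg_step(cpg, lung.volume_ml, dt)
        lung_step(lung, 0.0, 0.0, drive, dt)
    peak = 0.0
    for _ in range(n_cycle):
        drive, _ = cpg_step(cpg, lung.volume_ml, dt)
        lung_step(lung, 0.0, 0.0, drive, dt)
        peak = max(peak, lung.volume_ml)
    return p.baseline_tidal_ml / peak


def derive_baseline(peaks, onsets, exclusion_factor: float = 1.5):
    """Baseline tidal volume and breath period from spontaneous cycles.

    Cycles whose peak exceeds ``exclusion_factor`` x the running median of
    peaks so far are treated as non-breathing behavior (sigh-like) and
    excluded from the averages.  Raises :class:`BaselineError` with fewer
    than 5 usable cycles.
    """
    peaks = np.asarray(peaks, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    keep = []
    for i, pk in enumerate(peaks):
        med = float(np.median(peaks[: i + 1]))
        if pk <= exclusion_factor * med:
            keep.append(i)
    if len(keep) < 5:
        raise BaselineError(
            f"baseline contains only {len(keep)} usable breath cycles (need >= 5)"
        )
    keep = np.asarray(keep)
    intervals = np.diff(onsets)
    return float(peaks[keep].mean()), float(intervals[keep].mean())


# ---------------------------------------------------------------------------
# full closed-loop trial
# ---------------------------------------------------------------------------

def simulate_trial(
    config: RunConfig,
    mode: str = "combined",
    sigh: bool = False,
    duration_s: float | None = None,
    seed: int | None = None,
) -> TrialRecord:
    """Run one complete trial: spontaneous baseline, target derivation, then
    the adaptive closed loop for ``duration_s`` of pacing.

    ``mode`` is ``spontaneous`` (stimulation off), ``dia_only`` (intercostal
    channel forced to zero) or ``combined``.  The desired pattern is a
    half-sine at the measured baseline period with peak ``desired_factor``
    (default 1.2) x the measured baseline tidal volume.  The same
    (config, mode, sigh, duration, seed) always produces a bit-identical
    record.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    config.validate()
    p, c, proto = config.plant, config.controller, config.protocol
    if duration_s is None:
        duration_s = proto.pacing_s
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    d0 = calibrate_intrinsic_drive(config)
    dia = MusclePlant(p.dia.twitch_mA, p.dia.sat_mA, p.dia.k_f_per_mC, p.dia.rho_per_s)
    eic = MusclePlant(p.eic.twitch_mA, p.eic.sat_mA, p.eic.k_f_per_mC, p.eic.rho_per_s)
    lung = LungModel(tau_s=p.tau_lung_s, g_dia_ml=p.dia.gain_ml, g_eic_ml=p.eic.gain_ml,
                     g_syn_ml=p.g_syn_ml)
    cpg = IntrinsicCPG(
        t0_s=p.t0_s,
        drive_amplitude_ml=d0,
        v_hb_ml=p.v_hb_factor * p.baseline_tidal_ml,
        release_fraction=p.v_hb_release_fraction,
    )
    sensor = SensorModel(noise_sd_ml=p.sensor_noise_ml, integrator_tau_s=p.sensor_tau_s, rng=rng)

    dt = p.plant_dt_s
    control_dt = c.control_dt_s
    n_sub = round(control_dt / dt)

    # ---- baseline: spontaneous breathing, no stimulation ------------------
    n_base_steps = int(round(proto.baseline_s / control_dt))
    onsets: list = []
    step_peaks = np.empty(n_base_steps)
    t = 0.0
    for j in range(n_base_steps):
        v_max, ons = plant_control_step(
            dia, eic, lung, cpg, 0.0, 0.0, 0.0, 0.0, n_sub, dt, t
        )
        step_peaks[j] = v_max
        onsets.extend(ons)
        t += control_dt
    if len(onsets) < 2:
        raise BaselineError("baseline produced fewer than 2 intrinsic breath onsets")
    peaks = []
    times = np.arange(n_base_steps) * control_dt
    for a, b in zip(onsets[:-1], onsets[1:]):
        mask = (times >= a) & (times < b)
        peaks.append(step_peaks[mask].max() if mask.any() else 0.0)
    baseline_tidal, baseline_period = derive_baseline(peaks, onsets)

    # ---- desired pattern: 120% of baseline tidal volume -------------------
    clock = PGClock(baseline_period, control_dt)
    steps = clock.steps_per_cycle
    period = clock.cycle_period
    a_target = proto.desired_factor * baseline_tidal
    phases = np.arange(steps) / steps
    desired = np.where(phases < 0.5, a_target * np.sin(2.0 * np.pi * phases), 0.0)
    window = inspiratory_window(desired)

    n_cycles = int(duration_s // period)
    if n_cycles < 1:
        raise ValueError("pacing duration shorter than one cycle")

    ps = PSState(
        steps_per_cycle=steps,
        n_basis=c.n_basis,
        learning_rate=c.eta,
        delay_compensation_s=c.tau_d_ms * 1e-3,
    )
    schedule = SighSchedule(sigh_interval=c.sigh_interval)
    ch_dia = StimChannel("dia", c.dia.twitch_mA, c.dia.max_mA, c.dia.pulse_us, c.dia.pulse_hz,
                         activation_floor=c.u_on)
    ch_eic = StimChannel("eic", c.eic.twitch_mA, c.eic.max_mA, c.eic.pulse_us, c.eic.pulse_hz,
                         activation_floor=c.u_on)
    q_coef_dia = ch_dia.pulse_width_us * 1e-6 * ch_dia.pulse_frequency_hz  # mC/s per mA
    q_coef_eic = ch_eic.pulse_width_us * 1e-6 * ch_eic.pulse_frequency_hz

    n_total = n_cycles * steps
    col = {
        name: np.zeros(n_total)
        for name in (
            "time_s", "phase", "V_desired", "V_true", "V_measured", "cpg_phase",
            "u_preclip", "I_dia_mA", "I_eic_mA", "q_dia_mC", "q_eic_mC",
            "F_dia", "F_eic",
        )
    }
    cyc_idx = np.zeros(n_total, dtype=int)
    sigh_flag = np.zeros(n_total, dtype=bool)
    learn_flag = np.zeros(n_total, dtype=bool)
    step_vmax = np.zeros(n_total)
    pace_onsets: list = []
    cycle_baseline = np.zeros(n_cycles)

    stim_on = mode in ("dia_only", "combined")
    t_pace = 0.0
    j = 0
    for cyc in range(n_cycles):
        if sigh and cyc >= 1:
            pre_cycle, paused = apply_sigh(schedule, ps, cyc)
        else:
            pre_cycle, paused = None, False
        is_sigh_cycle = pre_cycle is not None
        ps.learning_enabled = stim_on and not paused
        cycle_baseline[cyc] = lung.volume_ml
        sensor.baseline_ml = lung.volume_ml
        for k in range(steps):
            u_live = ps_output(ps, phases[k])
            pre = float(pre_cycle[k]) if is_sigh_cycle else u_live
            gated = pre if window[k] else 0.0
            if stim_on:
                i_dia = channel_amplitude(gated, ch_dia)
                i_eic = channel_amplitude(gated, ch_eic) if mode == "combined" else 0.0
            else:
                i_dia = i_eic = 0.0
            v_max, ons = plant_control_step(
                dia, eic, lung, cpg,
                i_dia, i_eic,
                i_dia * q_coef_dia, i_eic * q_coef_eic,
                n_sub, dt, t_pace,
            )
            pace_onsets.extend(ons)
            v_meas = measure(sensor, lung.volume_ml)
            if ps.learning_enabled and window[k]:
                e = volume_error(desired[k], v_meas, a_target)
                # anti-windup: no growth while the shaper output is clipped
                if not (e > 0.0 and u_live >= 1.0):
                    ps_update(ps, e, phases[k], period)
            col["time_s"][j] = t_pace
            col["phase"][j] = phases[k]
            col["V_desired"][j] = desired[k]
            col["V_true"][j] = lung.volume_ml
            col["V_measured"][j] = v_meas
            col["cpg_phase"][j] = cpg.theta
            col["u_preclip"][j] = pre
            col["I_dia_mA"][j] = i_dia
            col["I_eic_mA"][j] = i_eic
            col["q_dia_mC"][j] = encode_charge(i_dia, ch_dia, control_dt)
            col["q_eic_mC"][j] = encode_charge(i_eic, ch_eic, control_dt)
            col["F_dia"][j] = dia.fatigue
            col["F_eic"][j] = eic.fatigue
            cyc_idx[j] = cyc
            sigh_flag[j] = is_sigh_cycle
            learn_flag[j] = ps.learning_enabled
            step_vmax[j] = v_max
            t_pace += control_dt
            j += 1
        ps.finish_cycle(store=not is_sigh_cycle)

    # ---- per-cycle summaries ----------------------------------------------
    meas = col["V_measured"].reshape(n_cycles, steps)
    irmse = np.array(
        [_metrics.irmse_cycle(desired, meas[cidx], window) for cidx in range(n_cycles)]
    )
    q_dia_cycle = col["q_dia_mC"].reshape(n_cycles, steps).sum(axis=1)
    q_eic_cycle = col["q_eic_mC"].reshape(n_cycles, steps).sum(axis=1)
    tidal = step_vmax.reshape(n_cycles, steps).max(axis=1) - cycle_baseline
    onset_err = np.full(n_cycles, np.nan)
    if pace_onsets:
        on = np.asarray(pace_onsets)
        for cidx in range(n_cycles):
            t_c = cidx * period
            d = on - t_c
            near = d[np.abs(d) <= 0.75 * period]
            if near.size:
                onset_err[cidx] = near[np.argmin(np.abs(near))] / period

    steps_df = pd.DataFrame(
        {
            "time_s": col["time_s"],
            "cycle_index": cyc_idx,
            "phase": col["phase"],
            "V_desired": col["V_desired"],
            "V_true": col["V_true"],
            "V_measured": col["V_measured"],
            "cpg_phase": col["cpg_phase"],
            "u_preclip": col["u_preclip"],
            "I_dia_mA": col["I_dia_mA"],
            "I_eic_mA": col["I_eic_mA"],
            "q_dia_mC": col["q_dia_mC"],
            "q_eic_mC": col["q_eic_mC"],
            "F_dia": col["F_dia"],
            "F_eic": col["F_eic"],
            "sigh_flag": sigh_flag,
            "learning_flag": learn_flag,
        }
    )
    cycles_df = pd.DataFrame(
        {
            "cycle_index": np.arange(n_cycles),
            "irmse_pct": irmse,
            "charge_dia_mC": q_dia_cycle,
            "charge_eic_mC": q_eic_cycle,
            "tidal_volume_ml": tidal,
            "is_sigh": sigh_flag.reshape(n_cycles, steps)[:, 0],
            "learning_paused": ~learn_flag.reshape(n_cycles, steps)[:, 0],
            "onset_phase_error": onset_err,
        }
    )
    meta = {
        "format_version": 1,
        "mode": mode,
        "sigh": bool(sigh),
        "seed": int(seed),
        "control_dt_s": control_dt,
        "plant_dt_s": dt,
        "cycle_period_s": period,
        "steps_per_cycle": steps,
        "baseline_tidal_ml": baseline_tidal,
        "baseline_period_s": baseline_period,
        "baseline_n_cycles": len(peaks),
        "desired_peak_ml": a_target,
        "desired_factor": proto.desired_factor,
        "n_cycles": n_cycles,
        "hb_resets": cpg.resets,
        "intrinsic_drive_ml": d0,
        "config_hash": config.hash(),
    }
    return TrialRecord(steps=steps_df, cycles=cycles_df, meta=meta)
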