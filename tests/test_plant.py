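"""Tests of the synthetic respiratory plant: recruitment, fatigue dynamics,
lung mechanics with synergy, the intrinsic oscillator with the
Hering-Breuer reflex, volume sensing, and the full closed-loop trial."""

import math

import numpy as np
import pandas as pd
import pytest

from pacesim import RunConfig, simulate_trial
from pacesim.plant import (
    BaselineError,
    IntrinsicCPG,
    LungModel,
    MusclePlant,
    SensorModel,
    calibrate_intrinsic_drive,
    cpg_step,
    derive_baseline,
    fatigue_step,
    lung_step,
    measure,
    plant_control_step,
    recruit,
)


def make_muscle(**kw):
    defaults = dict(twitch_threshold_mA=1.5, saturation_mA=3.0,
                    k_f_per_mC=0.15, rho_per_s=0.0015)
    defaults.update(kw)
    return MusclePlant(**defaults)


class TestRecruit:
    def test_subthreshold_is_silent(self):
        assert recruit(1.5 - 1e-9, make_muscle()) == 0.0

    def test_saturation(self):
        assert recruit(3.0, make_muscle()) == 1.0
        assert recruit(10.0, make_muscle()) == 1.0

    def test_linear_midpoint(self):
        assert recruit(2.25, make_muscle()) == pytest.approx(0.5)

    def test_invalid_muscle_rejected(self):
        with pytest.raises(ValueError):
            MusclePlant(twitch_threshold_mA=2.0, saturation_mA=2.0)


class TestFatigue:
    def test_rest_keeps_fresh_muscle_fresh(self):
        m = make_muscle()
        for _ in range(1000):
            fatigue_step(m, 0.0, 0.001)
        assert m.fatigue == 0.0

    def test_pure_recovery_decays(self):
        m = make_muscle(rho_per_s=0.01)
        m.fatigue = 0.5
        f_prev = 0.5
        for _ in range(1000):
            fatigue_step(m, 0.0, 0.01)
            assert m.fatigue <= f_prev
            f_prev = m.fatigue
        assert m.fatigue < 0.5 * math.exp(-0.01 * 10 * 0.9)

    def test_equilibrium_matches_closed_form(self):
        # dF/dt = k q (1-F) - rho F  ->  F_inf = k q / (k q + rho)
        m = make_muscle(k_f_per_mC=0.15, rho_per_s=0.0015)
        q = 0.015
        rate = m.k_f_per_mC * q + m.rho_per_s
        t_end = 5.0 / rate
        n = int(t_end / 0.001)
        for _ in range(n):
            fatigue_step(m, q, 0.001)
        f_inf = m.k_f_per_mC * q / (m.k_f_per_mC * q + m.rho_per_s)
        assert m.fatigue == pytest.approx(f_inf, rel=0.01)

    def test_monotone_in_charge_rate(self):
        m1, m2 = make_muscle(), make_muscle()
        for _ in range(5000):
            fatigue_step(m1, 0.005, 0.01)
            fatigue_step(m2, 0.010, 0.01)
            assert m1.fatigue <= m2.fatigue

    def test_bounded_in_unit_interval(self):
        m = make_muscle(k_f_per_mC=100.0)
        for _ in range(100):
            fatigue_step(m, 10.0, 0.1)
        assert m.fatigue <= 1.0


class TestLung:
    def test_passive_expiration_exponential(self):
        lung = LungModel(volume_ml=1.0)
        dt, n = 0.0001, 3000
        for _ in range(n):
            lung_step(lung, 0.0, 0.0, 0.0, dt)
        assert lung.volume_ml == pytest.approx(math.exp(-n * dt / lung.tau_s), rel=1e-3)

    def test_steady_states_and_synergy(self):
        def steady(a_d, a_e):
            lung = LungModel(g_dia_ml=1.8, g_eic_ml=0.65, g_syn_ml=0.5)
            for _ in range(40000):
                lung_step(lung, a_d, a_e, 0.0, 0.001)
            return lung.volume_ml

        v_d, v_e, v_both = steady(1, 0), steady(0, 1), steady(1, 1)
        assert v_d == pytest.approx(1.8, rel=1e-6)
        assert v_e == pytest.approx(0.65, rel=1e-6)
        # co-activation exceeds the sum of single-muscle volumes by g_syn
        assert v_both - (v_d + v_e) == pytest.approx(0.5, rel=1e-6)

    def test_step_size_refinement(self):
        def trace(dt):
            lung = LungModel()
            out = []
            for i in range(int(1.5 / dt)):
                drive = math.sin(2 * math.pi * (i * dt) / 1.5) if (i * dt) < 0.75 else 0.0
                lung_step(lung, 0.0, 0.0, drive, dt)
                out.append(lung.volume_ml)
            return np.array(out)

        v1, v2 = trace(0.001), trace(0.0005)
        rel = np.abs(v2[1::2] - v1).max() / v1.max()
        assert rel < 0.005


class TestCPG:
    def test_free_running_period(self):
        cpg = IntrinsicCPG(t0_s=1.5, v_hb_ml=1.1)
        onsets = []
        t = 0.0
        for _ in range(int(10 / 0.001)):
            _, onset = cpg_step(cpg, 0.0, 0.001)
            if onset:
                onsets.append(t)
            t += 0.001
        intervals = np.diff(onsets)
        assert np.allclose(intervals, 1.5, atol=0.002)
        assert cpg.resets == 0

    def test_drive_zero_in_expiration(self):
        cpg = IntrinsicCPG()
        drives = []
        for _ in range(1500):
            d, _ = cpg_step(cpg, 0.0, 0.001)
            drives.append((cpg.theta, d))
        for theta, d in drives:
            if theta >= 0.5:
                assert d == 0.0
            else:
                assert d >= 0.0

    def test_inflation_cuts_inspiration(self):
        cpg = IntrinsicCPG(v_hb_ml=0.5)
        cpg.theta = 0.2
        _, _ = cpg_step(cpg, 0.9, 0.001)
        assert cpg.theta == 0.5 and cpg.resets == 1 and cpg.engaged

    def test_disabled_reflex_never_resets(self):
        cpg = IntrinsicCPG(v_hb_ml=math.inf)
        for _ in range(5000):
            cpg_step(cpg, 100.0, 0.001)
        assert cpg.resets == 0

    def test_release_hysteresis(self):
        cpg = IntrinsicCPG(v_hb_ml=1.0, release_fraction=0.25)
        cpg.theta = 0.2
        cpg_step(cpg, 1.2, 0.001)  # cut + engage
        theta_held = cpg.theta
        for _ in range(100):
            cpg_step(cpg, 0.5, 0.001)  # above release level: held
        assert cpg.theta == pytest.approx(theta_held)
        cpg_step(cpg, 0.1, 0.001)  # deflated: released
        for _ in range(100):
            cpg_step(cpg, 0.1, 0.001)
        assert cpg.theta > theta_held


class TestSensor:
    def test_noise_free_measurement_exact(self):
        s = SensorModel(noise_sd_ml=0.0, rng=np.random.default_rng(0))
        measure(s, 0.7, cycle_start=True)
        assert measure(s, 1.2) == pytest.approx(0.5)

    def test_seed_reproducibility(self):
        a = SensorModel(noise_sd_ml=0.02, rng=np.random.default_rng(42))
        b = SensorModel(noise_sd_ml=0.02, rng=np.random.default_rng(42))
        xs = [measure(a, 1.0) for _ in range(100)]
        ys = [measure(b, 1.0) for _ in range(100)]
        assert xs == ys

    def test_noise_scale(self):
        s = SensorModel(noise_sd_ml=0.02, rng=np.random.default_rng(7))
        x = np.array([measure(s, 0.0) for _ in range(10_000)])
        assert abs(x.std() / 0.02 - 1) < 0.05


class TestBaselineDerivation:
    def test_sigh_like_cycles_excluded(self):
        peaks = [1.0] * 10 + [2.5] + [1.0] * 10
        onsets = np.arange(22) * 1.5
        tidal, period = derive_baseline(peaks, onsets)
        assert tidal == pytest.approx(1.0)
        assert period == pytest.approx(1.5)

    def test_too_few_cycles_raises(self):
        with pytest.raises(BaselineError):
            derive_baseline([1.0] * 3, np.arange(4) * 1.5)


class TestControlStepConsistency:
    def test_fused_step_matches_op_composition(self, cfg):
        """The unrolled control-interval integrator must agree with stepping
        the individual plant operations."""
        p = cfg.plant
        d0 = calibrate_intrinsic_drive(cfg)

        def build():
            dia = MusclePlant(p.dia.twitch_mA, p.dia.sat_mA, p.dia.k_f_per_mC, p.dia.rho_per_s)
            eic = MusclePlant(p.eic.twitch_mA, p.eic.sat_mA, p.eic.k_f_per_mC, p.eic.rho_per_s)
            lung = LungModel(tau_s=p.tau_lung_s, g_dia_ml=p.dia.gain_ml,
                             g_eic_ml=p.eic.gain_ml, g_syn_ml=p.g_syn_ml)
            cpg = IntrinsicCPG(t0_s=p.t0_s, drive_amplitude_ml=d0,
                               v_hb_ml=1.1, release_fraction=p.v_hb_release_fraction)
            return dia, eic, lung, cpg

        i_dia, i_eic, q_d, q_e = 2.4, 1.6, 0.014, 0.0096
        dia1, eic1, lung1, cpg1 = build()
        for step in range(50):
            plant_control_step(dia1, eic1, lung1, cpg1, i_dia, i_eic, q_d, q_e,
                               40, 0.001, step * 0.04)

        dia2, eic2, lung2, cpg2 = build()
        a_d = recruit(i_dia, dia2)
        a_e = recruit(i_eic, eic2)
        for _ in range(50 * 40):
            fatigue_step(dia2, q_d, 0.001)
            fatigue_step(eic2, q_e, 0.001)
            drive, _ = cpg_step(cpg2, lung2.volume_ml, 0.001)
            lung_step(lung2, a_d * (1 - dia2.fatigue), a_e * (1 - eic2.fatigue),
                      drive, 0.001)

        assert lung1.volume_ml == pytest.approx(lung2.volume_ml, rel=1e-12)
        assert dia1.fatigue == pytest.approx(dia2.fatigue, rel=1e-12)
        assert cpg1.theta == pytest.approx(cpg2.theta, rel=1e-9)
        assert cpg1.resets == cpg2.resets


class TestSimulateTrial:
    def test_spontaneous_calibration(self, cfg):
        rec = simulate_trial(cfg, mode="spontaneous", duration_s=30, seed=1)
        assert rec.meta["baseline_tidal_ml"] == pytest.approx(1.0, rel=0.02)
        assert rec.cycles["tidal_volume_ml"].mean() == pytest.approx(1.0, rel=0.02)

    def test_target_is_120_percent_of_baseline(self, rec_combined_500):
        meta = rec_combined_500.meta
        assert meta["desired_peak_ml"] == 1.2 * meta["baseline_tidal_ml"]

    def test_bit_identical_reruns(self, cfg):
        a = simulate_trial(cfg, mode="combined", sigh=True, duration_s=45, seed=9)
        b = simulate_trial(cfg, mode="combined", sigh=True, duration_s=45, seed=9)
        pd.testing.assert_frame_equal(a.steps, b.steps)
        pd.testing.assert_frame_equal(a.cycles, b.cycles)
        assert a.meta == b.meta

    def test_dia_only_mode_silences_eic(self, rec_dia_550):
        assert (rec_dia_550.steps["I_eic_mA"] == 0).all()
        assert (rec_dia_550.steps["q_eic_mC"] == 0).all()

    def test_amplitudes_within_channel_limits(self, rec_combined_500, cfg):
        s = rec_combined_500.steps
        assert (s["I_dia_mA"] >= 0).all()
        assert (s["I_dia_mA"] <= cfg.controller.dia.max_mA + 1e-12).all()
        assert (s["I_eic_mA"] <= cfg.controller.eic.max_mA + 1e-12).all()

    def test_short_baseline_raises(self, cfg):
        cfg.protocol.baseline_s = 5.0
        with pytest.raises(BaselineError):
            simulate_trial(cfg, mode="combined", duration_s=30, seed=1)

    def test_energy_free_rest(self):
        # zero input: volume and fatigue both decay to zero on their own
        # time scales (tau_lung ~0.15 s, 1/rho ~11 min)
        lung = LungModel(volume_ml=1.0)
        for _ in range(20000):
            lung_step(lung, 0.0, 0.0, 0.0, 0.001)
        assert lung.volume_ml < 1e-6
        m = make_muscle()
        m.fatigue = 0.5
        for _ in range(40000):  # 4000 s at dt = 0.1 s
            fatigue_step(m, 0.0, 0.1)
        assert m.fatigue < 0.5 * math.exp(-5)


def phase_drift(onset_errors, n):
    err = np.asarray(onset_errors, dtype=float)[-n:]
    d = np.diff(err)
    d = (d + 0.5) % 1.0 - 0.5
    return abs(np.nansum(d))


class TestEntrainment:
    def test_pacing_phase_locks_intrinsic_rhythm(self, rec_combined_500):
        # once locked, intrinsic breath onsets hold a fixed phase in the paced
        # cycle: onset-to-onset jitter below one control step
        err = rec_combined_500.cycles["onset_phase_error"].to_numpy()[-100:]
        period = rec_combined_500.meta["cycle_period_s"]
        assert np.isfinite(err).all()
        assert phase_drift(err, 100) < 0.5
        jitter = np.abs(np.diff(err)) * period
        assert (jitter < 0.040 + 1e-9).all()

    def test_free_run_without_stimulation(self, cfg):
        rec = simulate_trial(cfg, mode="spontaneous", duration_s=200 * 1.5, seed=1)
        assert rec.meta["hb_resets"] == 0
        # period mismatch 1.5 vs 1.48 accumulates ~1.35% of a cycle per cycle
        assert phase_drift(rec.cycles["onset_phase_error"].to_numpy(), 150) > 1.0
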