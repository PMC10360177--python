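"""Figures for trial and cohort results (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_trial", "plot_fi_scatter", "plot_sigh_factors"]


def plot_trial(record, t_max_s: float | None = None):
    """Desired vs measured volume, stimulation amplitudes and per-cycle iRMSE
    for one trial."""
    steps, cycles = record.steps, record.cycles
    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=False)
    sel = steps if t_max_s is None else steps[steps["time_s"] <= t_max_s]
    axes[0].plot(sel["time_s"], sel["V_desired"], "k--", lw=0.8, label="desired")
    axes[0].plot(sel["time_s"], sel["V_measured"], "b-", lw=0.8, label="measured")
    axes[0].set_ylabel("volume (ml)")
    axes[0].legend(loc="upper right", fontsize=8)
    axes[1].plot(sel["time_s"], sel["I_dia_mA"], label="dia")
    axes[1].plot(sel["time_s"], sel["I_eic_mA"], label="eic")
    axes[1].set_ylabel("amplitude (mA)")
    axes[1].set_xlabel("time (s)")
    axes[1].legend(loc="upper right", fontsize=8)
    axes[2].plot(cycles["cycle_index"], cycles["irmse_pct"])
    axes[2].axhline(20, color="grey", ls=":", lw=0.8)
    axes[2].axhline(10, color="grey", ls="--", lw=0.8)
    axes[2].set_ylabel("iRMSE (%)")
    axes[2].set_xlabel("cycle")
    fig.tight_layout()
    return fig


def plot_fi_scatter(cohort):
    """Diaphragm fatigue index, combined vs dia-only, one point per subject;
    points below the identity line fatigue less under combined pacing."""
    fig, ax = plt.subplots(figsize=(5, 5))
    x = cohort["fi_dia_dia_only"].to_numpy(dtype=float)
    y = cohort["fi_dia_combined"].to_numpy(dtype=float)
    ax.scatter(x, y, zorder=3)
    lim = max(0.05, np.nanmax(np.abs(np.concatenate([x, y]))) * 1.2)
    ax.plot([-lim, lim], [-lim, lim], "b-", lw=1)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("FI (dia only)")
    ax.set_ylabel("FI (dia + eic)")
    ax.set_aspect("equal")
    fig.tight_layout()
    return fig


def plot_sigh_factors(cohort):
    """Per-subject mean sigh tidal-volume factor, dia-only vs combined."""
    fig, ax = plt.subplots(figsize=(6, 4))
    idx = np.arange(len(cohort))
    w = 0.38
    ax.bar(idx - w / 2, cohort["sigh_factor_dia_only"], w, label="dia only")
    ax.bar(idx + w / 2, cohort["sigh_factor_combined"], w, label="dia + eic")
    ax.axhline(1.0, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("subject")
    ax.set_ylabel("sigh tidal volume factor")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
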