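"""Performance measures for paced-breathing trials.

Implements the analysis suite used to judge closed-loop respiratory pacing:

* per-cycle percent inspiratory root-mean-squared tracking error (iRMSE),
* per-cycle stimulation charge and the fatigue index (relative drift of the
  charge needed to hold the target volume),
* entrainment / adaptation onset detection from the iRMSE trace,
* sigh tidal-volume factor,
* breath-onset synchrony loss/reset classification around sighs,
* an exact one-sided Wilcoxon signed-rank test for the small paired samples
  these experiments produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CycleSummary",
    "FatigueIndexResult",
    "irmse_cycle",
    "fatigue_index",
    "entrainment_onset",
    "adaptation_detect",
    "sigh_volume_factor",
    "synchrony_events",
    "wilcoxon_signed_rank_one_sided",
    "summarize_trial",
]


@dataclass
class CycleSummary:
    """One breath cycle's worth of performance numbers."""

    cycle_index: int
    irmse_pct: float
    charge_dia_mC: float
    charge_eic_mC: float
    tidal_volume_ml: float
    is_sigh: bool
    learning_paused: bool
    onset_phase_error: float


@dataclass
class FatigueIndexResult:
    """Fatigue index: relative change in mean charge per cycle between an
    initial and a final 50-cycle window, FI = (Q_final - Q_initial)/Q_initial.

    A positive FI means more charge was needed late in the trial (the muscle
    fatigued); a negative FI means less charge was needed.
    """

    fi: float
    initial_window: tuple
    final_window: tuple
    q_initial_mC: float
    q_final_mC: float


def irmse_cycle(desired, measured, window=None) -> float:
    """Percent inspiratory RMSE of one cycle.

    ``100 * RMS(desired - measured over the inspiratory window) / peak(desired)``.
    ``window`` is a boolean mask over samples; by default the whole trace is
    used.  The normalization is by the desired trace's peak, giving a 0-100%
    scale comparable across target amplitudes.
    """
    desired = np.asarray(desired, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if desired.shape != measured.shape:
        raise ValueError("desired and measured traces must be aligned")
    peak = desired.max() if desired.size else 0.0
    if peak <= 0:
        raise ValueError("desired trace must have a positive peak")
    if window is None:
        window = np.ones(desired.shape, dtype=bool)
    window = np.asarray(window, dtype=bool)
    if not window.any():
        raise ValueError("inspiratory window is empty")
    err = desired[window] - measured[window]
    return 100.0 * float(np.sqrt(np.mean(err**2))) / peak


def fatigue_index(
    charge_per_cycle,
    initial_start: int = 0,
    final_start: int | None = None,
    window: int = 50,
    gap: int = 400,
) -> FatigueIndexResult:
    """Fatigue index from a per-cycle charge series.

    The initial window (``window`` cycles, default 50) starts at
    ``initial_start`` — conventionally the first entrained cycle — and the
    final window starts ``gap`` cycles (default 400) later unless overridden.
    """
    q = np.asarray(charge_per_cycle, dtype=float)
    if final_start is None:
        final_start = initial_start + gap
    if final_start < initial_start + window:
        raise ValueError("fatigue-index windows must be disjoint")
    if final_start + window > q.size:
        raise ValueError(
            f"need at least {final_start + window} cycles for the fatigue index, "
            f"got {q.size}"
        )
    q_init = float(q[initial_start : initial_start + window].mean())
    q_fin = float(q[final_start : final_start + window].mean())
    if q_init <= 0:
        raise ValueError("initial-window charge must be positive")
    return FatigueIndexResult(
        fi=(q_fin - q_init) / q_init,
        initial_window=(initial_start, initial_start + window),
        final_window=(final_start, final_start + window),
        q_initial_mC=q_init,
        q_final_mC=q_fin,
    )


def _first_sustained(series, threshold: float, run_length: int, inclusive: bool):
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series is empty")
    ok = (x <= threshold) if inclusive else (x < threshold)
    if run_length <= 0:
        raise ValueError("run_length must be positive")
    count = 0
    for i, good in enumerate(ok):
        count = count + 1 if good else 0
        if count >= run_length:
            return i - run_length + 1
    return None


def entrainment_onset(irmse_series, threshold_pct: float = 20.0, run_length: int = 20):
    """First cycle starting a run of >= ``run_length`` cycles with iRMSE
    strictly below ``threshold_pct``; None if the trial never entrains."""
    return _first_sustained(irmse_series, threshold_pct, run_length, inclusive=False)


def adaptation_detect(irmse_series, threshold_pct: float = 10.0, run_length: int = 20):
    """First cycle starting a run of >= ``run_length`` cycles with iRMSE at or
    below ``threshold_pct`` (the controller is then considered adapted)."""
    return _first_sustained(irmse_series, threshold_pct, run_length, inclusive=True)


def sigh_volume_factor(sigh_tidal_ml: float, desired_tidal_ml: float) -> float:
    """Sigh tidal volume normalized by the trial's targeted (non-sigh) tidal
    volume, making sigh sizes comparable across trials."""
    if desired_tidal_ml <= 0:
        raise ValueError("desired tidal volume must be positive")
    return sigh_tidal_ml / desired_tidal_ml


def synchrony_events(
    onset_phase_errors,
    sigh_cycles,
    phase_tol: float = 0.25,
    n_required: int = 3,
    post_window: int = 3,
):
    """Classify each sigh by synchrony loss before it and reset after it.

    ``loss_before`` is True when at least ``n_required`` consecutive cycles
    immediately preceding the sigh have |onset phase error| above
    ``phase_tol`` (breath initiation out of phase).  ``reset_after`` is True
    when synchrony was lost before the sigh and within ``post_window``
    cycles after it the error returns to within tolerance (a sigh cannot
    reset alignment that was never lost).
    """
    err = np.abs(np.asarray(onset_phase_errors, dtype=float))
    out = []
    for s in sigh_cycles:
        run = 0
        i = s - 1
        while i >= 0 and err[i] > phase_tol:
            run += 1
            i -= 1
        loss_before = run >= n_required
        post = err[s + 1 : s + 1 + post_window]
        reset_after = bool(loss_before and post.size and (post <= phase_tol).any())
        out.append(
            {"sigh_cycle": int(s), "loss_before": bool(loss_before), "reset_after": reset_after}
        )
    return out


def wilcoxon_signed_rank_one_sided(a, b, alternative: str) -> float:
    """Exact one-sided Wilcoxon signed-rank p-value for paired samples.

    ``alternative='greater'`` tests H1: a > b; ``'less'`` tests H1: a < b.
    The direction must be given explicitly — the hypotheses these experiments
    test are directional.  Zero differences are dropped; ties in |difference|
    get average ranks.  The p-value is exact: the null distribution of the
    positive-rank sum is built over all 2^n sign assignments (computed by
    dynamic programming on doubled ranks, so average ranks stay integral).
    Limited to n <= 25 nonzero pairs, the exact-enumeration regime.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if alternative == "less":
        d = -d
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25 nonzero pairs")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[: total + 1 - r]
    obs = int(round(2 * w_plus))
    return float(counts[obs:].sum() / counts.sum())


def summarize_trial(record, fi_gap: int = 400, fi_window: int = 50) -> dict:
    """Full metrics report for one trial record (JSON-serializable).

    Includes the per-cycle iRMSE trace, entrainment/adaptation onsets, the
    diaphragm and intercostal fatigue indices when the trial is long enough,
    per-sigh volume factors and synchrony events.
    """
    cyc: pd.DataFrame = record.cycles
    irmse = cyc["irmse_pct"].to_numpy()
    regular = ~cyc["is_sigh"].to_numpy(dtype=bool)
    onset_ent = entrainment_onset(irmse)
    onset_adp = adaptation_detect(irmse)
    report = {
        "mode": record.meta["mode"],
        "sigh": record.meta["sigh"],
        "n_cycles": int(len(cyc)),
        "desired_peak_ml": record.meta["desired_peak_ml"],
        "irmse_pct": [float(x) for x in irmse],
        "entrainment_onset": None if onset_ent is None else int(onset_ent),
        "adaptation_onset": None if onset_adp is None else int(onset_adp),
        "mean_irmse_last50_pct": float(irmse[-50:].mean()),
        "mean_charge_dia_mC": float(cyc.loc[regular, "charge_dia_mC"].mean()),
        "mean_charge_eic_mC": float(cyc.loc[regular, "charge_eic_mC"].mean()),
    }
    for ch in ("dia", "eic"):
        key = f"charge_{ch}_mC"
        fi = None
        if onset_ent is not None:
            try:
                fi = fatigue_index(
                    cyc[key].to_numpy(), initial_start=onset_ent, window=fi_window, gap=fi_gap
                )
            except ValueError:
                fi = None
        report[f"fatigue_index_{ch}"] = None if fi is None else fi.fi
    sighs = cyc.index[cyc["is_sigh"].astype(bool)].tolist()
    desired = record.meta["desired_peak_ml"]
    report["sigh_volume_factors"] = [
        sigh_volume_factor(float(cyc.loc[s, "tidal_volume_ml"]), desired) for s in sighs
    ]
    report["synchrony_events"] = synchrony_events(
        cyc["onset_phase_error"].to_numpy(), sighs
    )
    return report
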