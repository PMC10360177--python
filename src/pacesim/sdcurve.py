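"""Strength-duration curve toolkit: rheobase and chronaxie estimation.

Muscle excitability is characterized by the hyperbolic strength-duration
relation between stimulus pulse width and twitch-threshold current.  We use
the Weiss (charge-linear) form

    I(pw) = I_rh * (1 + t_ch / pw)

where ``I_rh`` is the rheobase (threshold at very long pulses) and ``t_ch``
the chronaxie (pulse width at which the threshold is twice the rheobase).
Multiplying by ``pw`` makes the model linear in its parameters — threshold
charge Q = I_rh*pw + I_rh*t_ch — so the fit is an ordinary least-squares
line on (pw, Q).

Two rheobase conventions are reported: the fitted asymptote ``I_rh`` and the
operational value ``rheobase_500`` (the threshold at the longest measured
pulse width, 500 µs), together with the pulse width at which the fitted
curve crosses twice the operational rheobase (``chronaxie_interp``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SDCurve",
    "StrengthDurationModel",
    "sd_grid",
    "weiss_threshold",
    "fit_sd",
    "simulate_sd_measurement",
]

#: Plausible excitability ranges for the simulated measurements (mA, µs).
RHEOBASE_RANGE_MA = (0.35, 1.3)
CHRONAXIE_RANGE_US = (35.0, 100.0)


def sd_grid() -> np.ndarray:
    """The measurement pulse-width grid, descending: 500 to 100 µs in steps
    of 100, then 100 down to 10 µs in steps of 10 (100 appears once) —
    14 values."""
    coarse = np.arange(500, 99, -100)
    fine = np.arange(90, 9, -10)
    return np.concatenate([coarse, fine]).astype(float)


def weiss_threshold(rheobase_mA: float, chronaxie_us: float, pulse_width_us: float) -> float:
    """Weiss-law twitch threshold at a given pulse width."""
    if pulse_width_us <= 0:
        raise ValueError("pulse width must be positive")
    if rheobase_mA <= 0 or chronaxie_us <= 0:
        raise ValueError("rheobase and chronaxie must be positive")
    return rheobase_mA * (1.0 + chronaxie_us / pulse_width_us)


@dataclass
class SDCurve:
    """Fitted strength-duration curve (the results object of
    :class:`StrengthDurationModel`)."""

    pulse_widths_us: np.ndarray
    thresholds_mA: np.ndarray
    rheobase_mA: float
    chronaxie_us: float
    rheobase_500_mA: float
    chronaxie_interp_us: float
    residual_mA: float

    def predict(self, pulse_width_us) -> np.ndarray:
        pw = np.asarray(pulse_width_us, dtype=float)
        return self.rheobase_mA * (1.0 + self.chronaxie_us / pw)

    def summary(self) -> str:
        lines = [
            "Strength-duration curve (Weiss model)",
            "=====================================",
            f"points:                {len(self.pulse_widths_us)}",
            f"rheobase (asymptote):  {self.rheobase_mA:.4f} mA",
            f"chronaxie:             {self.chronaxie_us:.2f} us",
            f"rheobase @500us:       {self.rheobase_500_mA:.4f} mA",
            f"chronaxie (2x @500us): {self.chronaxie_interp_us:.2f} us",
            f"rms residual:          {self.residual_mA:.4g} mA",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rheobase_mA": float(self.rheobase_mA),
            "chronaxie_us": float(self.chronaxie_us),
            "rheobase_500_mA": float(self.rheobase_500_mA),
            "chronaxie_interp_us": float(self.chronaxie_interp_us),
            "residual_mA": float(self.residual_mA),
            "n_points": int(len(self.pulse_widths_us)),
        }


class StrengthDurationModel:
    """Weiss strength-duration model for (pulse width, threshold) data.

    ``fit()`` returns an :class:`SDCurve` results object.
    """

    def __init__(self, pulse_widths_us, thresholds_mA):
        pw = np.asarray(pulse_widths_us, dtype=float)
        thr = np.asarray(thresholds_mA, dtype=float)
        if pw.shape != thr.shape:
            raise ValueError("pulse widths and thresholds must be aligned")
        if np.unique(pw).size < 4:
            raise ValueError("need at least 4 distinct pulse widths")
        if (pw <= 0).any() or (thr <= 0).any():
            raise ValueError("pulse widths and thresholds must be positive")
        self.pulse_widths_us = pw
        self.thresholds_mA = thr

    @classmethod
    def from_dataframe(cls, df, pw_col: str = "pulse_width_us", thr_col: str = "threshold_mA"):
        return cls(df[pw_col].to_numpy(), df[thr_col].to_numpy())

    def fit(self) -> SDCurve:
        pw, thr = self.pulse_widths_us, self.thresholds_mA
        # threshold charge is linear in pulse width: Q = I_rh*pw + I_rh*t_ch
        q = thr * pw
        slope, intercept = np.polyfit(pw, q, 1)
        # t_ch below a nanosecond has collapsed onto the pw axis: the data
        # carry no strength-duration structure (e.g. constant thresholds)
        if slope <= 0 or intercept <= 0 or intercept / slope < 1e-3:
            raise ValueError(
                "degenerate strength-duration data: fitted rheobase or chronaxie "
                "is non-positive or vanishing"
            )
        rheobase = float(slope)
        chronaxie = float(intercept / slope)
        pw_max = pw.max()
        i_at_max = thr[pw == pw_max].mean()  # operational rheobase: measured @500 us
        ratio = 2.0 * i_at_max / rheobase - 1.0
        chron_interp = chronaxie / ratio if ratio > 0 else float("nan")
        resid = float(np.sqrt(np.mean((rheobase * (1.0 + chronaxie / pw) - thr) ** 2)))
        return SDCurve(
            pulse_widths_us=pw,
            thresholds_mA=thr,
            rheobase_mA=rheobase,
            chronaxie_us=chronaxie,
            rheobase_500_mA=float(i_at_max),
            chronaxie_interp_us=float(chron_interp),
            residual_mA=resid,
        )


def fit_sd(pulse_widths_us, thresholds_mA) -> SDCurve:
    """Least-squares Weiss fit; see :class:`StrengthDurationModel`."""
    return StrengthDurationModel(pulse_widths_us, thresholds_mA).fit()


def simulate_sd_measurement(
    rheobase_mA: float | None = None,
    chronaxie_us: float | None = None,
    pulse_widths_us=None,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Simulate a twitch-threshold measurement series over the pulse-width grid.

    Unspecified excitability parameters are drawn uniformly from the plausible
    physiological ranges (rheobase 0.35-1.3 mA, chronaxie 35-100 µs).
    ``noise_sd`` is the relative (multiplicative) measurement noise.  Returns
    ``(pulse_widths, thresholds)``.
    """
    rng = np.random.default_rng(seed)
    if rheobase_mA is None:
        rheobase_mA = float(rng.uniform(*RHEOBASE_RANGE_MA))
    if chronaxie_us is None:
        chronaxie_us = float(rng.uniform(*CHRONAXIE_RANGE_US))
    pw = sd_grid() if pulse_widths_us is None else np.asarray(pulse_widths_us, dtype=float)
    thr = rheobase_mA * (1.0 + chronaxie_us / pw)
    if noise_sd > 0:
        thr = thr * (1.0 + rng.normal(0.0, noise_sd, size=pw.shape))
    return pw, thr
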