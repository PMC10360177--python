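"""Adaptive pattern-generator / pattern-shaper (PG/PS) stimulation controller.

The controller that drives functional electrical stimulation of the
inspiratory muscles has two parts.  The *pattern generator* (PG) is a fixed
oscillator: it sets the breath duration (cycle period) and nothing else.  The
*pattern shaper* (PS) is a single-layer adaptive network that maps cycle phase
to a normalized stimulation amplitude ``u`` in [0, 1]; its weights are trained
online, every control step, from the instantaneous error between the desired
and the measured breath volume.  One shaper drives two stimulation channels
(diaphragm, ``dia``, and external intercostal, ``eic``); each channel converts
``u`` to a current amplitude through its own twitch-threshold-derived limits.

Stimulation is delivered as cathodic-first biphasic pulse trains (default
80 µs/phase at 75 Hz) whose amplitude is updated every 40 ms (25 Hz control
rate).  Charge bookkeeping counts the leading (cathodic) phase of each pulse.

Sighs (augmented breaths) are scheduled every ``sigh_interval`` breaths: on a
sigh cycle the controller replays the stored PS outputs of the previous cycle
at twice their magnitude, and adaptive learning is paused for the sigh cycle
and the cycle that follows it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: controller update interval, seconds (25 Hz)
DEFAULT_CONTROL_DT = 0.040

__all__ = [
    "DEFAULT_CONTROL_DT",
    "PGClock",
    "PSState",
    "StimChannel",
    "SighSchedule",
    "StimCommand",
    "pg_step",
    "ps_basis",
    "ps_output",
    "ps_update",
    "volume_error",
    "apply_sigh",
    "channel_map",
    "encode_charge",
    "inspiratory_window",
]


# ---------------------------------------------------------------------------
# pattern generator
# ---------------------------------------------------------------------------

@dataclass
class PGClock:
    """Fixed-period breath cycle clock.

    The requested ``cycle_period`` is rounded at construction to the nearest
    integer multiple of ``control_dt`` so that every cycle contains the same
    whole number of control steps.
    """

    cycle_period: float
    control_dt: float = DEFAULT_CONTROL_DT
    step_index: int = 0
    cycle_index: int = 0
    steps_per_cycle: int = field(init=False)

    def __post_init__(self) -> None:
        if self.cycle_period <= 0 or self.control_dt <= 0:
            raise ValueError("cycle_period and control_dt must be positive")
        # nearest integer step count; exact half-step ties round down
        self.steps_per_cycle = max(1, math.ceil(self.cycle_period / self.control_dt - 0.5))
        self.cycle_period = self.steps_per_cycle * self.control_dt

    @property
    def step_in_cycle(self) -> int:
        return self.step_index - self.cycle_index * self.steps_per_cycle

    @property
    def phase(self) -> float:
        """Fraction of the current cycle elapsed, in [0, 1)."""
        return self.step_in_cycle / self.steps_per_cycle


def pg_step(clock: PGClock) -> PGClock:
    """Advance the cycle clock by one control step (in place)."""
    clock.step_index += 1
    clock.cycle_index = clock.step_index // clock.steps_per_cycle
    return clock


# ---------------------------------------------------------------------------
# pattern shaper
# ---------------------------------------------------------------------------

def ps_basis(phase: float, centers: np.ndarray, width: float) -> np.ndarray:
    """Gaussian basis activations on circular cycle phase.

    Each basis neuron peaks at 1 when ``phase`` coincides with its center;
    distance is measured on the circle so a neuron at phase 0 responds
    identically to phases just below 1.
    """
    d = np.abs(np.asarray(phase) - centers)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / width) ** 2)


@dataclass
class PSState:
    """Pattern-shaper weights and bookkeeping.

    ``stored_outputs`` holds the normalized output of every control step of
    the most recently completed non-sigh cycle; sigh insertion replays it at
    twice the magnitude.
    """

    steps_per_cycle: int
    n_basis: int = 25
    learning_rate: float = 0.02
    delay_compensation_s: float = 0.080
    basis_width: float | None = None
    learning_enabled: bool = True
    weights: np.ndarray = field(init=False)
    basis_centers: np.ndarray = field(init=False)
    stored_outputs: np.ndarray = field(init=False)
    current_outputs: list = field(init=False)

    def __post_init__(self) -> None:
        if self.n_basis < 2:
            raise ValueError("need at least two basis neurons")
        if self.basis_width is None:
            self.basis_width = 1.0 / self.n_basis
        self.weights = np.zeros(self.n_basis)
        self.basis_centers = np.arange(self.n_basis) / self.n_basis
        self.stored_outputs = np.empty(0)
        self.current_outputs = []

    def finish_cycle(self, *, store: bool = True) -> None:
        """Close the current cycle buffer; keep it as the replay pattern
        unless ``store`` is False (sigh cycles are never stored)."""
        if store and len(self.current_outputs) == self.steps_per_cycle:
            self.stored_outputs = np.asarray(self.current_outputs, dtype=float)
        self.current_outputs = []


def ps_output(state: PSState, phase: float) -> float:
    """Normalized shaper output ``u = clip(Σ w_i φ_i(phase), 0, 1)``.

    The value is appended to the current-cycle buffer so it can be replayed
    (doubled) on the next sigh cycle.
    """
    u = float(np.dot(state.weights, ps_basis(phase, state.basis_centers, state.basis_width)))
    u = min(max(u, 0.0), 1.0)
    state.current_outputs.append(u)
    return u


def volume_error(v_desired: float, v_measured: float, desired_peak: float) -> float:
    """Normalized tracking error ``(V_d - V_m) / max(V_d)``."""
    if desired_peak <= 0:
        raise ValueError("desired peak volume must be positive")
    return (v_desired - v_measured) / desired_peak


def ps_update(state: PSState, error: float, phase: float, cycle_period: float) -> PSState:
    """Delta-rule weight update with delay compensation.

    Credit for the volume error observed at ``phase`` is assigned to the basis
    neurons active ``delay_compensation_s`` earlier in the cycle, compensating
    the actuation + sensing lag.  Weights are clipped at zero: stimulation
    cannot be negative.  No-op while learning is disabled.
    """
    if not state.learning_enabled:
        return state
    shift = state.delay_compensation_s / cycle_period
    shifted = (phase - shift) % 1.0
    phi = ps_basis(shifted, state.basis_centers, state.basis_width)
    state.weights = np.maximum(0.0, state.weights + state.learning_rate * error * phi)
    return state


# ---------------------------------------------------------------------------
# sigh scheduling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SighSchedule:
    """Periodic augmented-breath (sigh) insertion.

    Every ``sigh_interval`` breaths the previous cycle's stored PS outputs are
    replayed at ``amplification`` (fixed 2x) before channel mapping; learning
    is paused on the sigh cycle and the one after (``pause_span`` = 2 cycles).
    """

    sigh_interval: int = 30
    amplification: float = 2.0
    pause_span: int = 2

    def __post_init__(self) -> None:
        if self.sigh_interval < 2:
            raise ValueError("sigh_interval must be >= 2")
        if self.amplification != 2.0:
            raise ValueError("sigh amplification is fixed at 2.0")

    def is_sigh_cycle(self, cycle_index: int) -> bool:
        return cycle_index > 0 and cycle_index % self.sigh_interval == 0

    def learning_paused(self, cycle_index: int) -> bool:
        for back in range(self.pause_span):
            if self.is_sigh_cycle(cycle_index - back):
                return True
        return False


def apply_sigh(schedule: SighSchedule, state: PSState, cycle_index: int):
    """Pre-clip outputs for a whole cycle plus the learning-pause flag.

    On sigh cycles returns ``amplification x stored_outputs`` (one value per
    control step); on regular cycles returns ``None``, meaning the live
    :func:`ps_output` is used step by step.
    """
    if cycle_index < 1:
        raise ValueError("sigh insertion requires at least one completed cycle")
    paused = schedule.learning_paused(cycle_index)
    if schedule.is_sigh_cycle(cycle_index):
        if state.stored_outputs.size == 0:
            raise ValueError("no stored PS outputs available for sigh replay")
        return schedule.amplification * state.stored_outputs, paused
    return None, paused


# ---------------------------------------------------------------------------
# channel mapping and charge accounting
# ---------------------------------------------------------------------------

@dataclass
class StimChannel:
    """One muscle's stimulation channel.

    The maximum amplitude is tied to the twitch threshold (1.5-2x) as a safety
    and recruitment convention; pass ``enforce_limits=False`` to override.
    """

    name: str
    twitch_threshold_mA: float
    max_amplitude_mA: float
    pulse_width_us: float = 80.0
    pulse_frequency_hz: float = 75.0
    activation_floor: float = 0.05
    enforce_limits: bool = True

    def __post_init__(self) -> None:
        if self.twitch_threshold_mA <= 0:
            raise ValueError("twitch threshold must be positive")
        if self.pulse_width_us <= 0 or self.pulse_frequency_hz <= 0:
            raise ValueError("pulse width and frequency must be positive")
        if self.enforce_limits:
            lo = 1.5 * self.twitch_threshold_mA
            hi = 2.0 * self.twitch_threshold_mA
            if not (lo - 1e-12 <= self.max_amplitude_mA <= hi + 1e-12):
                raise ValueError(
                    f"channel {self.name!r}: max amplitude {self.max_amplitude_mA} mA "
                    f"outside [1.5, 2.0] x twitch threshold ({lo}-{hi} mA)"
                )


@dataclass
class StimCommand:
    """Controller output for one control step: per-channel current amplitudes
    (mA), the pre-clip normalized PS output that produced them, and the charge
    delivered during the step (mC, leading phase)."""

    amplitudes_mA: dict
    pre_clip_output: float
    charge_mC: dict


def channel_amplitude(u: float, channel: StimChannel) -> float:
    """Map normalized output to current amplitude for one channel.

    Sub-floor outputs produce no stimulation; above the floor the amplitude
    runs affinely from the twitch threshold at ``u = 0`` to the channel
    maximum at ``u = 1`` and saturates there (sigh doubling never exceeds
    the stimulator's hard limit).
    """
    if u < channel.activation_floor:
        return 0.0
    i = channel.twitch_threshold_mA + min(u, 1.0) * (
        channel.max_amplitude_mA - channel.twitch_threshold_mA
    )
    return min(i, channel.max_amplitude_mA)


def encode_charge(amplitude_mA: float, channel: StimChannel, dt: float) -> float:
    """Leading-phase charge (mC) of the biphasic train delivered during ``dt``.

    charge = amplitude x pulse width x pulse rate x dt.  The biphasic pulses
    are charge balanced, so only the cathodic (leading) phase is counted.
    """
    if amplitude_mA < 0:
        raise ValueError("amplitude must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return amplitude_mA * (channel.pulse_width_us * 1e-6) * channel.pulse_frequency_hz * dt


def channel_map(u: float, channels) -> StimCommand:
    """Turn a (possibly sigh-doubled) pre-clip output into per-channel
    amplitudes; charge is filled per control step by the caller."""
    if u < 0:
        raise ValueError("pre-clip output must be nonnegative")
    amps = {ch.name: channel_amplitude(u, ch) for ch in channels}
    return StimCommand(amplitudes_mA=amps, pre_clip_output=u, charge_mC={})


# ---------------------------------------------------------------------------
# stimulation / learning window
# ---------------------------------------------------------------------------

def inspiratory_window(desired: np.ndarray, peak_fraction: float = 0.9) -> np.ndarray:
    """Boolean mask of control steps treated as inspiration.

    A step is inspiratory when the desired volume is rising into the next step
    or is within ``1 - peak_fraction`` of its peak.  Stimulation and learning
    are confined to this window: pacing assists inspiration only, expiration
    is passive.
    """
    desired = np.asarray(desired, dtype=float)
    if desired.size == 0:
        raise ValueError("desired trace is empty")
    peak = desired.max()
    if peak <= 0:
        raise ValueError("desired trace has no positive peak")
    rising = np.zeros(desired.size, dtype=bool)
    rising[:-1] = desired[1:] > desired[:-1]
    return rising | (desired >= peak_fraction * peak)
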