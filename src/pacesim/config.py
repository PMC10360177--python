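"""Run configuration: structured, validated, YAML round-trippable.

A :class:`RunConfig` bundles the three blocks a simulated pacing experiment
needs — plant parameters, controller gains, and the trial protocol — plus a
seed and output directory.  Configs serialize to plain YAML and round-trip
unchanged, so a run is fully described by (config file, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

FORMAT_VERSION = 1

__all__ = [
    "ChannelConfig",
    "MuscleConfig",
    "PlantConfig",
    "ControllerConfig",
    "ProtocolConfig",
    "RunConfig",
    "ConfigError",
    "FORMAT_VERSION",
]


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class ChannelConfig:
    """Stimulation-channel limits and pulse parameters (controller side)."""

    twitch_mA: float
    max_mA: float
    pulse_us: float = 80.0
    pulse_hz: float = 75.0


@dataclass
class MuscleConfig:
    """One muscle's plant-side properties: recruitment range, volume gain and
    charge-driven fatigue constants."""

    twitch_mA: float
    sat_mA: float
    gain_ml: float
    k_f_per_mC: float
    rho_per_s: float


@dataclass
class PlantConfig:
    """Synthetic respiratory plant parameters.

    Defaults emulate an anesthetized rat breathing at 1.5 s per breath with a
    1.0 ml baseline tidal volume.  The intrinsic oscillator's Hering-Breuer
    threshold sits at ``v_hb_factor`` x baseline tidal volume: inflation past
    it during intrinsic inspiration terminates the intrinsic breath, which is
    what lets pacing entrain the intrinsic rhythm.
    """

    t0_s: float = 1.5
    tau_lung_s: float = 0.15
    g_syn_ml: float = 0.5
    baseline_tidal_ml: float = 1.0
    v_hb_factor: float = 1.1
    v_hb_release_fraction: float = 0.25
    sensor_noise_ml: float = 0.02
    sensor_tau_s: float = 0.2
    plant_dt_s: float = 0.001
    dia: MuscleConfig = field(
        default_factory=lambda: MuscleConfig(
            twitch_mA=1.5, sat_mA=3.0, gain_ml=1.8, k_f_per_mC=0.15, rho_per_s=0.0015
        )
    )
    eic: MuscleConfig = field(
        default_factory=lambda: MuscleConfig(
            twitch_mA=1.0, sat_mA=2.0, gain_ml=0.65, k_f_per_mC=0.15, rho_per_s=0.0015
        )
    )


@dataclass
class ControllerConfig:
    """PG/PS controller gains and per-channel stimulation limits."""

    n_basis: int = 25
    eta: float = 0.03
    tau_d_ms: float = 80.0
    control_dt_s: float = 0.040
    u_on: float = 0.05
    sigh_interval: int = 30
    dia: ChannelConfig = field(default_factory=lambda: ChannelConfig(twitch_mA=1.5, max_mA=3.0))
    eic: ChannelConfig = field(default_factory=lambda: ChannelConfig(twitch_mA=1.0, max_mA=2.0))


@dataclass
class ProtocolConfig:
    """Trial protocol: a spontaneous-breathing baseline, then adaptive pacing
    at 120% of the measured baseline tidal volume, one trial per requested
    mode x sigh setting.  Rest between trials is implicit — each trial starts
    from a fresh, unfatigued plant."""

    baseline_s: float = 60.0
    pacing_s: float = 600.0
    modes: list = field(default_factory=lambda: ["dia_only", "combined"])
    sigh: list = field(default_factory=lambda: [False, True])
    desired_factor: float = 1.2
    require_entrainment: bool = True


@dataclass
class RunConfig:
    format_version: int = FORMAT_VERSION
    seed: int = 0
    outdir: str = "pacesim_out"
    plant: PlantConfig = field(default_factory=PlantConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "RunConfig":
        p, c, pr = self.plant, self.controller, self.protocol
        if self.format_version != FORMAT_VERSION:
            raise ConfigError(f"unsupported format_version {self.format_version}")
        for name, val in [
            ("plant.t0_s", p.t0_s),
            ("plant.tau_lung_s", p.tau_lung_s),
            ("plant.baseline_tidal_ml", p.baseline_tidal_ml),
            ("plant.plant_dt_s", p.plant_dt_s),
            ("controller.control_dt_s", c.control_dt_s),
            ("protocol.baseline_s", pr.baseline_s),
            ("protocol.pacing_s", pr.pacing_s),
            ("protocol.desired_factor", pr.desired_factor),
        ]:
            if val <= 0:
                raise ConfigError(f"{name} must be positive, got {val}")
        n_sub = c.control_dt_s / p.plant_dt_s
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ConfigError("plant_dt_s must divide control_dt_s exactly")
        for name, m in [("dia", p.dia), ("eic", p.eic)]:
            if m.sat_mA <= m.twitch_mA:
                raise ConfigError(f"plant.{name}: saturation must exceed twitch threshold")
            if m.twitch_mA <= 0 or m.gain_ml <= 0:
                raise ConfigError(f"plant.{name}: twitch and gain must be positive")
            if m.k_f_per_mC < 0 or m.rho_per_s < 0:
                raise ConfigError(f"plant.{name}: fatigue constants must be nonnegative")
        for name, ch in [("dia", c.dia), ("eic", c.eic)]:
            if ch.twitch_mA <= 0 or ch.pulse_us <= 0 or ch.pulse_hz <= 0:
                raise ConfigError(f"controller.{name}: pulse parameters must be positive")
        if c.sigh_interval < 2:
            raise ConfigError("controller.sigh_interval must be >= 2")
        if not (0 < c.eta < 1):
            raise ConfigError("controller.eta must lie in (0, 1)")
        for m in pr.modes:
            if m not in ("spontaneous", "dia_only", "combined"):
                raise ConfigError(f"unknown mode {m!r}")
        return self

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            plant = d.pop("plant", {})
            ctrl = d.pop("controller", {})
            proto = d.pop("protocol", {})
            cfg = cls(
                plant=PlantConfig(
                    **{
                        **{k: v for k, v in plant.items() if k not in ("dia", "eic")},
                        "dia": MuscleConfig(**plant["dia"]) if "dia" in plant else PlantConfig().dia,
                        "eic": MuscleConfig(**plant["eic"]) if "eic" in plant else PlantConfig().eic,
                    }
                ),
                controller=ControllerConfig(
                    **{
                        **{k: v for k, v in ctrl.items() if k not in ("dia", "eic")},
                        "dia": ChannelConfig(**ctrl["dia"]) if "dia" in ctrl else ControllerConfig().dia,
                        "eic": ChannelConfig(**ctrl["eic"]) if "eic" in ctrl else ControllerConfig().eic,
                    }
                ),
                protocol=ProtocolConfig(**proto),
                **d,
            )
        except TypeError as exc:
            raise ConfigError(f"malformed config: {exc}") from exc
        return cfg.validate()

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def hash(self) -> str:
        """Stable digest of the canonical config, for trial metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
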