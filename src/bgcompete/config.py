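"""Structured run configuration: schema, validation, defaults, round-trip.

A run is fully described by one YAML document with the sections below (all
optional; an empty file yields the documented defaults).  Unknown keys are
rejected, and every validation error names the offending key and the
violated constraint.

    network:   tau, w_self, w_inh, g_d, g_i, noise_sd, dt,
               activation: {kind, slope, offset, fmax}
    input:     I_d, I_i, I_m, I_lambda, gain_nonselective
    decision:  threshold, deadline, evidence_gain, norm_eps, t0, baseline
    cued:      coherence, sensory_base, sensory_gain, direct_bias,
               cue_strength, cue_validity, i_lambda, plus optional
               channel_params / decision_params sub-sections shaped like
               network / decision
    learning:  alpha_q, delta, drift_map_slope, drift_base, gain_bounds,
               rpe_scaled_delta, race_noise_sd, race_dt
    sweep:     levels, n_per_level, gate_separation, probe_q_diff,
               tonic_drift_gain, n_entropy_trials
    ddm:       n_boot, ci
    seed, output_dir, log_level
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .cued import CuedTaskParams
from .decision import DecisionParams
from .learning import LearningParams
from .network import Activation, ChannelInput, ChannelParams

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]

LOG_LEVELS = ("debug", "info", "warning")


class ConfigError(ValueError):
    """Configuration parse or validation failure, naming the offending key."""


def _build(cls, d: dict, path: str, nested: Optional[dict] = None):
    """Construct a dataclass from a dict, rejecting unknown keys and
    re-raising field validation errors with the dotted key path.

    ``nested`` maps field names to either a dataclass or a builder function
    ``f(value, path)`` for sub-sections.
    """
    nested = nested or {}
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(d).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in d.items():
        if key not in names:
            raise ConfigError(f"{path}.{key}: unknown key")
        if key in nested:
            sub = nested[key]
            if dataclasses.is_dataclass(sub):
                val = _build(sub, val, f"{path}.{key}")
            else:
                val = sub(val, f"{path}.{key}")
        if key == "gain_bounds" or key == "levels":
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _build_channel(d, path):
    return _build(ChannelParams, d, path, nested={"activation": Activation})


@dataclass(frozen=True)
class SweepSection:
    levels: tuple = (0.2, 0.7, 1.2)
    n_per_level: int = 1000
    gate_separation: float = 0.1
    probe_q_diff: float = 0.4
    tonic_drift_gain: float = 2.0
    n_entropy_trials: int = 1000

    def __post_init__(self):
        lv = tuple(float(x) for x in self.levels)
        if not all(b > a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly increasing")
        object.__setattr__(self, "levels", lv)


@dataclass(frozen=True)
class DDMSection:
    n_boot: int = 1000
    ci: float = 0.95

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0.0 < self.ci < 1.0):
            raise ValueError("ci must be in (0, 1)")


def _default_input() -> ChannelInput:
    # a moderately direct-favouring drive so default runs actually decide
    return ChannelInput(I_d=0.6, I_i=0.4)


@dataclass(frozen=True)
class RunConfig:
    network: ChannelParams = field(default_factory=ChannelParams)
    input: ChannelInput = field(default_factory=_default_input)
    decision: DecisionParams = field(default_factory=DecisionParams)
    cued: CuedTaskParams = field(default_factory=CuedTaskParams)
    learning: LearningParams = field(default_factory=LearningParams)
    sweep: SweepSection = field(default_factory=SweepSection)
    ddm: DDMSection = field(default_factory=DDMSection)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "info"
    # section names the user explicitly set (lets commands distinguish
    # "use my network" from "use your preset"); not part of equality
    provided: frozenset = field(default=frozenset(), compare=False,
                                repr=False)

    def __post_init__(self):
        if self.log_level not in LOG_LEVELS:
            raise ValueError(f"log_level must be one of {LOG_LEVELS}")


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML config file.

    ``path=None`` or an empty file gives the documented defaults.
    ``overrides`` (e.g. CLI flags) are applied on top of the file content
    before validation.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    if overrides:
        data = {**data, **{k: v for k, v in overrides.items() if v is not None}}

    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            raise ConfigError(f"{key}: unknown key")

    cfg_kwargs = dict(
        network=_build_channel(data.get("network"), "network"),
        input=(_build(ChannelInput, data["input"], "input")
               if "input" in data else _default_input()),
        decision=_build(DecisionParams, data.get("decision"), "decision"),
        cued=_build(CuedTaskParams, data.get("cued"), "cued",
                    nested={"channel_params": _build_channel,
                            "decision_params": DecisionParams}),
        learning=_build(LearningParams, data.get("learning"), "learning"),
        sweep=_build(SweepSection, data.get("sweep"), "sweep"),
        ddm=_build(DDMSection, data.get("ddm"), "ddm"),
        provided=frozenset(data),
    )
    for scalar in ("seed", "output_dir", "log_level"):
        if scalar in data:
            cfg_kwargs[scalar] = data[scalar]
    try:
        return RunConfig(**cfg_kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def _as_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj) if f.name != "provided"}
    if isinstance(obj, tuple):
        return [_as_dict(x) for x in obj]
    return obj


def dump_config(cfg: RunConfig) -> str:
    """Serialize a config to YAML such that load(dump(cfg)) == cfg."""
    return yaml.safe_dump(_as_dict(cfg), sort_keys=True)
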