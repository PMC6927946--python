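"""Run configuration: cohort, curriculum, sequencer, agents and rig.

Configs are YAML mappings validated eagerly; unknown keys are rejected with
their key path.  An omitted curriculum section loads the packaged default
seven-phase table.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path

import yaml

from .controller import TrialTimings
from .curriculum import DEFAULT_CURRICULUM, PhaseParams
from .sequencing import SequenceParams
from .virtual_rig import AgentParams

__all__ = ["AnimalEntry", "RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration; message carries the offending key path."""


@dataclasses.dataclass(frozen=True)
class AnimalEntry:
    animal_id: str
    rfid: str = ""
    group: str = "default"


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one simulated (or real) run."""

    cohort: list[AnimalEntry] = dataclasses.field(
        default_factory=lambda: [AnimalEntry("m1")]
    )
    curriculum: tuple[PhaseParams, ...] = DEFAULT_CURRICULUM
    sequencer: SequenceParams = dataclasses.field(default_factory=SequenceParams)
    agents: AgentParams = dataclasses.field(default_factory=AgentParams)
    agent_overrides: dict[str, AgentParams] = dataclasses.field(default_factory=dict)
    timings: TrialTimings = dataclasses.field(default_factory=TrialTimings)
    odor_pair: tuple[str, str] = ("cineol", "eugenol")
    discrimination_reward_ul: float = 15.0
    retry_mean_s: float = 60.0
    start_hour: float = 0.0
    start_time: _dt.datetime = _dt.datetime(2024, 1, 1, 0, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [a.animal_id for a in self.cohort]
        if not ids:
            raise ConfigError("cohort: must contain at least one animal")
        if len(set(ids)) != len(ids):
            raise ConfigError("cohort: duplicate animal_id")
        if self.odor_pair[0] == self.odor_pair[1]:
            raise ConfigError("odor_pair: odors must be distinct")
        if self.discrimination_reward_ul <= 0:
            raise ConfigError("discrimination_reward_ul: must be positive")
        if self.retry_mean_s <= 0:
            raise ConfigError("retry_mean_s: must be positive")
        unknown = set(self.agent_overrides) - set(ids)
        if unknown:
            raise ConfigError(f"agent_overrides: unknown animal ids {sorted(unknown)}")

    def agent_params(self, animal_id: str) -> AgentParams:
        return self.agent_overrides.get(animal_id, self.agents)

    def to_dict(self) -> dict:
        """Plain mapping for hashing and log headers."""
        return {
            "cohort": [dataclasses.asdict(a) for a in self.cohort],
            "curriculum": [dataclasses.asdict(p) for p in self.curriculum],
            "sequencer": dataclasses.asdict(self.sequencer),
            "agents": dataclasses.asdict(self.agents),
            "agent_overrides": {
                k: dataclasses.asdict(v) for k, v in self.agent_overrides.items()
            },
            "timings": dataclasses.asdict(self.timings),
            "odor_pair": list(self.odor_pair),
            "discrimination_reward_ul": self.discrimination_reward_ul,
            "retry_mean_s": self.retry_mean_s,
            "start_hour": self.start_hour,
            "start_time": self.start_time.isoformat(),
            "seed": self.seed,
        }


def _build(cls, mapping: dict, path: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: expected a mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _phase_from_mapping(mapping: dict, path: str) -> PhaseParams:
    for key in ("reward_delay_ms", "reward_ul", "iti_s"):
        if key in mapping and isinstance(mapping[key], list):
            mapping[key] = tuple(mapping[key])
    return _build(PhaseParams, mapping, path)


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a run configuration from YAML (or a mapping).

    Sections ``cohort``, ``curriculum``, ``sequencer``, ``agents``,
    ``timings`` and scalar run options may each be omitted; omitted
    sections fall back to packaged defaults (the default curriculum is the
    standard seven-phase table).
    """
    if data is None:
        if path is None:
            raise ConfigError("either a path or a mapping is required")
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a mapping")
    known = {
        "cohort", "curriculum", "sequencer", "agents", "agent_overrides",
        "timings", "odor_pair", "discrimination_reward_ul", "retry_mean_s",
        "start_hour", "start_time", "seed",
    }
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"top level: unknown key(s) {sorted(unknown)}")

    kwargs: dict = {}
    if "cohort" in data:
        entries = data["cohort"]
        if not isinstance(entries, list):
            raise ConfigError("cohort: expected a list")
        kwargs["cohort"] = [
            _build(AnimalEntry, e, f"cohort[{i}]") for i, e in enumerate(entries)
        ]
    if "curriculum" in data:
        rows = data["curriculum"]
        if rows:
            if not isinstance(rows, list):
                raise ConfigError("curriculum: expected a list of phase rows")
            kwargs["curriculum"] = tuple(
                _phase_from_mapping(dict(r), f"curriculum[{i}]")
                for i, r in enumerate(rows)
            )
    if "sequencer" in data:
        kwargs["sequencer"] = _build(SequenceParams, data["sequencer"], "sequencer")
    if "agents" in data:
        agents = dict(data["agents"])
        if "activity_rate" in agents:
            agents["activity_rate"] = tuple(agents["activity_rate"])
        kwargs["agents"] = _build(AgentParams, agents, "agents")
    if "agent_overrides" in data:
        overrides = {}
        for aid, mapping in data["agent_overrides"].items():
            mapping = dict(mapping)
            if "activity_rate" in mapping:
                mapping["activity_rate"] = tuple(mapping["activity_rate"])
            overrides[aid] = _build(AgentParams, mapping, f"agent_overrides.{aid}")
        kwargs["agent_overrides"] = overrides
    if "timings" in data:
        kwargs["timings"] = _build(TrialTimings, data["timings"], "timings")
    if "odor_pair" in data:
        pair = data["odor_pair"]
        if not isinstance(pair, (list, tuple)) or len(pair) != 2:
            raise ConfigError("odor_pair: expected two odor ids")
        kwargs["odor_pair"] = (str(pair[0]), str(pair[1]))
    for key in ("discrimination_reward_ul", "retry_mean_s", "start_hour", "seed"):
        if key in data:
            kwargs[key] = data[key]
    if "start_time" in data:
        raw = data["start_time"]
        kwargs["start_time"] = (
            raw if isinstance(raw, _dt.datetime) else _dt.datetime.fromisoformat(str(raw))
        )
    try:
        return RunConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
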