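"""Run configuration: one YAML file covering stimuli, evolution and evaluation.

Every defaulted value is a study constant: tau = 0.25, 1000-moment sessions,
six events with maximum duration M = 50 and minimum gap 100, oscillator
noise 0.05, populations of 1000 with 20% selection, 2% per-gene mutation of
+-10%, 500 generations for the interval-timing model and 300 further
generations for the extension.  Scaled-down profiles override these
explicitly and are echoed next to every run's outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .coevolution import EvolutionConfig
from .stimuli import StimulusConfig

__all__ = ["RunConfig", "load_config", "dump_config", "scaled_down_profile"]


def scaled_down_profile(generations: int = 300) -> EvolutionConfig:
    """The desk-scale surrogate of the full tuning protocol.

    Compared with the full-scale defaults (1000 chromosomes per module,
    500 generations) this runs 48 chromosomes for the 16-neuron hub
    modules and 1024 for the cheap 2-neuron event modules, 3 evaluation
    sessions per generation refreshed in blocks of 10, for 300
    generations — roughly eight minutes on one CPU.  Selection, crossover
    and mutation are unchanged.
    """
    return EvolutionConfig(
        population_size=48,
        event_population_size=1024,
        generations=generations,
        sessions_per_evaluation=3,
        session_refresh_every=10,
    )


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration; the single seed feeds every substream."""

    seed: int = 0
    model: str = "interval_timing"   # or "when_and_how_long"
    stimuli: StimulusConfig = field(default_factory=StimulusConfig)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    extension_generations: int = 300
    eval_runs: int = 50
    eval_durations: tuple = (20, 25, 30, 35, 40, 45)
    noise_amplitudes: tuple = (0.03, 0.05, 0.07, 0.09, 0.11, 0.13)
    noise_sessions: int = 20
    readout_window: int = 10

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Apply non-None overrides, dotted into the nested sections."""
        run_kw, evo_kw, stim_kw = {}, {}, {}
        evo_fields = {f.name for f in fields(EvolutionConfig)}
        stim_fields = {f.name for f in fields(StimulusConfig)}
        for key, value in kwargs.items():
            if value is None:
                continue
            if key in evo_fields:
                evo_kw[key] = value
            elif key in stim_fields:
                stim_kw[key] = value
            else:
                run_kw[key] = value
        cfg = self
        if evo_kw:
            cfg = replace(cfg, evolution=replace(cfg.evolution, **evo_kw))
        if stim_kw:
            cfg = replace(cfg, stimuli=replace(cfg.stimuli, **stim_kw))
        if run_kw:
            cfg = replace(cfg, **run_kw)
        return cfg


def _tupleize(d):
    if isinstance(d, list):
        return tuple(_tupleize(v) for v in d)
    return d


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    stim = StimulusConfig(**{k: _tupleize(v) for k, v in data.pop("stimuli", {}).items()})
    evo = EvolutionConfig(**data.pop("evolution", {}))
    data = {k: _tupleize(v) for k, v in data.items()}
    return RunConfig(stimuli=stim, evolution=evo, **data)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig, path) -> None:
    """Echo the fully resolved configuration (round-trips via load_config)."""
    d = _listify(asdict(cfg))
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
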