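"""Model architectures: module graphs, genome codec, assembly and readouts.

Two architectures are provided:

* :func:`interval_timing_model` — the "how-long" model.  Four oscillator
  channels feed a recurrently coupled pair of 16-neuron time-sense modules
  (``tSen1`` <-> ``tSen2``); ``tSen2`` projects to six 2-neuron duration
  modules (``tDuration1`` .. ``tDuration6``), each of which also receives
  the tone channel and all six event-id lines and must ramp-code the
  duration of "its" event.
* :func:`when_and_how_long_model` — the combined model.  Two 16-neuron hub
  modules (``tDuration``, ``tDistance``) read ``tSen2`` and reshape the
  sense of time for the duration branch and for the logarithmic
  temporal-distance branch; six 2-neuron distance modules
  (``tDistance1`` .. ``tDistance6``) join the six duration modules.  The
  event-level modules keep their direct ``tSen2`` afferents alongside the
  new hub afferents, so a trained interval-timing model can be lifted into
  the combined architecture without changing its behaviour (new links
  start at zero).

Inter-module arrows are all-to-all: every neuron of a source module
projects to every neuron of the target module.  Within one simulation
moment every module reads the afferent activations of the *previous*
moment (synchronous update), so the module evaluation order is
irrelevant.  The readout of each 2-neuron event module is its first
neuron; the second is hidden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .ctrnn import (
    DEFAULT_MOMENT_DT,
    DEFAULT_SUBSTEPS,
    DEFAULT_TAU,
    ModuleWiring,
    NeuronParams,
    euler_decay_factor,
)
from .stimuli import EventSchedule, Session, channel_layout

__all__ = [
    "ModuleDef",
    "ModelSpec",
    "AssembledModel",
    "SessionTrace",
    "interval_timing_model",
    "when_and_how_long_model",
    "decode_genome",
    "encode_genome",
    "lift_genomes",
    "read_duration",
    "read_distance",
    "save_genomes",
    "load_genomes",
]


@dataclass(frozen=True)
class ModuleDef:
    """One CTRNN module: size, external channels, afferent modules, fitness scope.

    ``afferents`` lists module names whose neurons project into this module;
    the module itself comes first (recurrent self-wiring).  ``fitness_events``
    lists the (kind, event-index) error terms whose fitnesses multiply into
    this module's evolutionary fitness.
    """

    name: str
    n_neurons: int
    ext_channels: tuple
    afferents: tuple
    fitness_events: tuple

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("modules need at least one neuron")
        if not self.afferents or self.afferents[0] != self.name:
            raise ValueError("afferents must list the module itself first")


@dataclass(frozen=True)
class ModelSpec:
    """A named collection of modules wired into one model."""

    name: str
    modules: tuple
    n_events: int = 6
    n_channels: int = 11

    def __post_init__(self):
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("duplicate module names")
        for m in self.modules:
            for a in m.afferents:
                if a not in names:
                    raise ValueError(f"module {m.name} lists unknown afferent {a}")

    # -- derived layout -------------------------------------------------
    def module(self, name: str) -> ModuleDef:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def module_names(self):
        return [m.name for m in self.modules]

    @property
    def n_neurons(self) -> int:
        return sum(m.n_neurons for m in self.modules)

    def rows(self, name: str) -> np.ndarray:
        """Global neuron indices of one module."""
        start = 0
        for m in self.modules:
            if m.name == name:
                return np.arange(start, start + m.n_neurons)
            start += m.n_neurons
        raise KeyError(name)

    def afferent_columns(self, name: str) -> np.ndarray:
        """Global indices of the afferent neurons of one module, own first."""
        m = self.module(name)
        return np.concatenate([self.rows(a) for a in m.afferents])

    def n_afferents(self, name: str) -> int:
        m = self.module(name)
        return sum(self.module(a).n_neurons for a in m.afferents)

    def genome_length(self, name: str) -> int:
        m = self.module(name)
        return m.n_neurons * (len(m.ext_channels) + self.n_afferents(name) + 1)

    @property
    def total_parameters(self) -> int:
        return sum(self.genome_length(m.name) for m in self.modules)

    def readout_row(self, kind: str, event: int) -> int:
        """Global row of the output neuron coding event ``event`` (0-based)."""
        prefix = {"dur": "tDuration", "dist": "tDistance"}[kind]
        return int(self.rows(f"{prefix}{event + 1}")[0])

    def downstream_rows(self, name: str) -> np.ndarray:
        """Rows of ``name`` plus every module reachable downstream from it.

        These are the only neurons whose trajectories can depend on the
        parameters of ``name``; everything else can be frozen during
        candidate evaluation.
        """
        affected = {name}
        changed = True
        while changed:
            changed = False
            for m in self.modules:
                if m.name not in affected and any(a in affected for a in m.afferents):
                    affected.add(m.name)
                    changed = True
        return np.sort(np.concatenate([self.rows(n) for n in affected]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "n_events": self.n_events,
                "n_channels": self.n_channels,
                "modules": [
                    {
                        "name": m.name,
                        "n_neurons": m.n_neurons,
                        "ext_channels": list(m.ext_channels),
                        "afferents": list(m.afferents),
                        "fitness_events": [list(fe) for fe in m.fitness_events],
                    }
                    for m in self.modules
                ],
            },
            indent=1,
        )


def _event_module_defs(n_events, layout, kind, hub=None):
    prefix = {"dur": "tDuration", "dist": "tDistance"}[kind]
    ext = tuple([layout["tone"]] + layout["event_id"])
    defs = []
    for i in range(n_events):
        name = f"{prefix}{i + 1}"
        aff = (name, "tSen2") if hub is None else (name, "tSen2", hub)
        defs.append(
            ModuleDef(
                name=name, n_neurons=2, ext_channels=ext,
                afferents=aff, fitness_events=((kind, i),),
            )
        )
    return defs


def interval_timing_model(n_events: int = 6) -> ModelSpec:
    """The 8-module "how-long" architecture (six duration modules)."""
    layout = channel_layout(n_events)
    all_dur = tuple(("dur", i) for i in range(n_events))
    mods = [
        ModuleDef("tSen1", 16, tuple(layout["osc"]), ("tSen1", "tSen2"), all_dur),
        ModuleDef("tSen2", 16, (), ("tSen2", "tSen1"), all_dur),
    ]
    mods += _event_module_defs(n_events, layout, "dur")
    return ModelSpec(
        name="interval_timing", modules=tuple(mods),
        n_events=n_events, n_channels=layout["n_channels"],
    )


def when_and_how_long_model(n_events: int = 6) -> ModelSpec:
    """The 16-module combined "when + how-long" architecture."""
    layout = channel_layout(n_events)
    all_dur = tuple(("dur", i) for i in range(n_events))
    all_dist = tuple(("dist", i) for i in range(n_events))
    mods = [
        ModuleDef("tSen1", 16, tuple(layout["osc"]), ("tSen1", "tSen2"), all_dur + all_dist),
        ModuleDef("tSen2", 16, (), ("tSen2", "tSen1"), all_dur + all_dist),
        ModuleDef("tDuration", 16, (), ("tDuration", "tSen2"), all_dur),
        ModuleDef("tDistance", 16, (), ("tDistance", "tSen2"), all_dist),
    ]
    mods += _event_module_defs(n_events, layout, "dur", hub="tDuration")
    mods += _event_module_defs(n_events, layout, "dist", hub="tDistance")
    return ModelSpec(
        name="when_and_how_long", modules=tuple(mods),
        n_events=n_events, n_channels=layout["n_channels"],
    )


# ---------------------------------------------------------------------------
# genome codec
# ---------------------------------------------------------------------------

def decode_genome(spec: ModelSpec, name: str, genome: np.ndarray):
    """Split a flat parameter vector into (ws, wp, theta) for one module."""
    m = spec.module(name)
    genome = np.asarray(genome, dtype=float)
    L = spec.genome_length(name)
    if genome.shape != (L,):
        raise ValueError(
            f"genome for module {name} has length {genome.shape}, expected ({L},)"
        )
    n, R, A = m.n_neurons, len(m.ext_channels), spec.n_afferents(name)
    ws = genome[: n * R].reshape(n, R)
    wp = genome[n * R: n * R + n * A].reshape(n, A)
    theta = genome[n * R + n * A:]
    return ws, wp, theta


def encode_genome(spec: ModelSpec, name: str, ws, wp, theta) -> np.ndarray:
    """Flatten (ws, wp, theta) back into the module's parameter vector."""
    m = spec.module(name)
    ws = np.asarray(ws, float).reshape(m.n_neurons, len(m.ext_channels))
    wp = np.asarray(wp, float).reshape(m.n_neurons, spec.n_afferents(name))
    theta = np.asarray(theta, float).reshape(m.n_neurons)
    return np.concatenate([ws.ravel(), wp.ravel(), theta])


def lift_genomes(old_spec: ModelSpec, new_spec: ModelSpec, genomes: dict) -> dict:
    """Re-encode genomes of shared modules into a richer architecture.

    External-channel weights, biases and the presynaptic blocks of afferent
    modules that exist in both architectures are copied; blocks for newly
    introduced afferents start at zero, so the lifted model reproduces the
    old model's behaviour exactly.  Modules absent from ``old_spec`` are not
    returned (they need fresh genomes).
    """
    lifted = {}
    for name, vec in genomes.items():
        if name not in new_spec.module_names:
            continue
        old_m, new_m = old_spec.module(name), new_spec.module(name)
        if old_m.ext_channels != new_m.ext_channels or old_m.n_neurons != new_m.n_neurons:
            raise ValueError(f"module {name} is not structurally compatible")
        ws, wp_old, theta = decode_genome(old_spec, name, vec)
        wp_new = np.zeros((new_m.n_neurons, new_spec.n_afferents(name)))
        col = 0
        blocks = {}
        for a in new_m.afferents:
            w = new_spec.module(a).n_neurons
            blocks[a] = slice(col, col + w)
            col += w
        col = 0
        for a in old_m.afferents:
            w = old_spec.module(a).n_neurons
            if a in blocks:
                wp_new[:, blocks[a]] = wp_old[:, col: col + w]
            col += w
        lifted[name] = encode_genome(new_spec, name, ws, wp_new, theta)
    return lifted


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

@dataclass
class AssembledModel:
    """Dense whole-model matrices built from per-module genomes."""

    spec: ModelSpec
    genomes: dict
    tau: float = DEFAULT_TAU
    substeps: int = DEFAULT_SUBSTEPS
    moment_dt: float = DEFAULT_MOMENT_DT
    W: np.ndarray = field(init=False, repr=False)
    Ws: np.ndarray = field(init=False, repr=False)
    theta: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        spec = self.spec
        missing = [n for n in spec.module_names if n not in self.genomes]
        if missing:
            raise ValueError(f"missing genomes for modules: {missing}")
        N, K = spec.n_neurons, spec.n_channels
        W = np.zeros((N, N))
        Ws = np.zeros((N, K))
        theta = np.zeros(N)
        for m in spec.modules:
            ws, wp, th = decode_genome(spec, m.name, self.genomes[m.name])
            rows = spec.rows(m.name)
            cols = spec.afferent_columns(m.name)
            W[np.ix_(rows, cols)] = wp
            if m.ext_channels:
                Ws[np.ix_(rows, np.array(m.ext_channels))] = ws
            theta[rows] = th
        self.W, self.Ws, self.theta = W, Ws, theta

    @property
    def alpha(self) -> float:
        return euler_decay_factor(self.tau, self.substeps, self.moment_dt)

    def module_wiring(self, name: str):
        """Per-module (ModuleWiring, NeuronParams) view for reference stepping."""
        ws, wp, th = decode_genome(self.spec, name, self.genomes[name])
        return ModuleWiring(ws=ws, wp=wp), NeuronParams(theta=th, tau=self.tau)

    def run_session(self, session: Session | np.ndarray) -> "SessionTrace":
        """Integrate one session; returns the full activation trace."""
        if isinstance(session, Session):
            inputs = session.inputs
            schedule = session.schedule
        else:
            inputs = np.asarray(session, dtype=float)
            schedule = None
        if inputs.shape[1] != self.spec.n_channels:
            raise ValueError(
                f"session has {inputs.shape[1]} channels, model expects {self.spec.n_channels}"
            )
        acts = _kernel.simulate_single(self.W, self.Ws, self.theta, inputs, self.alpha)
        return SessionTrace(spec=self.spec, acts=acts, schedule=schedule)


@dataclass(frozen=True)
class SessionTrace:
    """Activation record of one session run.

    ``acts`` has shape (T+1, N); row 0 is the initial state and row t+1 the
    activations after integrating input moment t.  ``output(kind, line)``
    is therefore indexed by input moment t = 0 .. T-1.
    """

    spec: ModelSpec
    acts: np.ndarray
    schedule: EventSchedule | None = None

    @property
    def horizon(self) -> int:
        return self.acts.shape[0] - 1

    def output(self, kind: str, line: int) -> np.ndarray:
        """Readout trace of the event module on id line ``line`` (0-based)."""
        return self.acts[1:, self.spec.readout_row(kind, line)]

    def module_activations(self, name: str) -> np.ndarray:
        """(T, n_neurons) activation trace of one module."""
        return self.acts[1:, self.spec.rows(name)]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for m in self.spec.modules:
            for j, r in enumerate(self.spec.rows(m.name)):
                cols[f"{m.name}.{j}"] = self.acts[1:, r]
        return pd.DataFrame(cols, index=pd.RangeIndex(self.horizon, name="t"))


# ---------------------------------------------------------------------------
# readouts (inverses of the target codes)
# ---------------------------------------------------------------------------

def read_duration(
    trace: SessionTrace,
    event: int,
    schedule: EventSchedule | None = None,
    window: int = 10,
) -> float:
    """Decode the duration (in moments) memorised for event ``event``.

    Inverts the ramp code: the plateau value times the maximum duration M,
    averaged over ``window`` moments following the event's end.
    """
    schedule = schedule if schedule is not None else trace.schedule
    if schedule is None:
        raise ValueError("a schedule is required to locate the event")
    e = int(schedule.ends[event])
    if e >= trace.horizon:
        raise ValueError(f"event {event} has not ended within the trace")
    out = trace.output("dur", int(schedule.event_ids[event]))
    stop = min(e + window, trace.horizon)
    return float(schedule.max_duration * np.mean(out[e:stop]))


def read_distance(
    trace: SessionTrace,
    event: int,
    t: int,
    schedule: EventSchedule | None = None,
) -> float:
    """Decode the temporal distance (moments before ``t``) of event ``event``.

    Inverts the log code: an output of TD implies the onset was at
    ``t * 10**(-TD)``, i.e. the event lies ``t * (1 - 10**(-TD))`` moments
    in the past.
    """
    schedule = schedule if schedule is not None else trace.schedule
    if schedule is None:
        raise ValueError("a schedule is required to locate the event")
    st = int(schedule.starts[event])
    if t <= st:
        raise ValueError(f"moment {t} is not after the onset of event {event} ({st})")
    if t >= trace.horizon:
        raise ValueError(f"moment {t} lies beyond the trace (horizon {trace.horizon})")
    out = trace.output("dist", int(schedule.event_ids[event]))[t]
    return float(t * (1.0 - 10.0 ** (-out)))


# ---------------------------------------------------------------------------
# genome files
# ---------------------------------------------------------------------------

def save_genomes(path, spec: ModelSpec, genomes: dict, metadata: dict | None = None):
    """Write genomes plus the spec and metadata as a single JSON file."""
    payload = {
        "spec": json.loads(spec.to_json()),
        "metadata": metadata or {},
        "genomes": {k: np.asarray(v, float).tolist() for k, v in genomes.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_genomes(path):
    """Load (spec, genomes, metadata) written by :func:`save_genomes`."""
    payload = json.loads(Path(path).read_text())
    sd = payload["spec"]
    modules = tuple(
        ModuleDef(
            name=m["name"], n_neurons=m["n_neurons"],
            ext_channels=tuple(m["ext_channels"]), afferents=tuple(m["afferents"]),
            fitness_events=tuple((fe[0], fe[1]) for fe in m["fitness_events"]),
        )
        for m in sd["modules"]
    )
    spec = ModelSpec(
        name=sd["name"], modules=modules,
        n_events=sd["n_events"], n_channels=sd["n_channels"],
    )
    genomes = {k: np.array(v, dtype=float) for k, v in payload["genomes"].items()}
    return spec, genomes, payload.get("metadata", {})
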