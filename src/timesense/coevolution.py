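"""Hierarchical cooperative coevolution of the module genomes.

One population of chromosomes is kept per CTRNN module.  A chromosome is
scored by substituting it into a full model assembled from the current
*representatives* (previous best) of all other populations, running that
model on a shared set of randomly generated sessions, and applying the
module's place in the fitness tree: event-level modules are scored by
their own tracking error (ff = 1000/E), hub modules by the product of
their branch's event fitnesses, and the time-sense root modules by the
product over every event module they serve.

Within a generation every candidate of every population sees the same
sessions, so fitness differences reflect genomes rather than luck; fresh
sessions are drawn each generation so genomes cannot overfit a single
schedule.  Reproduction per population: the best ``selection_fraction``
chromosomes survive unchanged (elitism) and parent uniformly drawn pairs
recombined by single-point crossover; each offspring gene mutates with
probability ``mutation_prob`` by additive uniform noise of +-10% of its
magnitude (with a floor so near-zero genes can move).

Because a candidate can only influence its own module and the modules
downstream of it, candidate evaluation freezes all upstream neuron rows
to a representative base trace — evaluating a 2-neuron leaf module does
not re-integrate the 16-neuron time-sense chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .architecture import (
    AssembledModel,
    ModelSpec,
    interval_timing_model,
    lift_genomes,
    when_and_how_long_model,
)
from .ctrnn import DEFAULT_MOMENT_DT, DEFAULT_SUBSTEPS, DEFAULT_TAU
from .stimuli import OscillatorBank, StimulusConfig, generate_schedule, render_session
from .targets import EPS_ERROR, distance_target_trace, duration_target_trace

__all__ = [
    "EvolutionConfig",
    "Population",
    "EvolutionResult",
    "init_population",
    "mutate",
    "single_point_crossover",
    "next_generation",
    "evaluate_populations",
    "evolve",
    "extend_and_retrain",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Coevolution parameters (defaults are the full-scale protocol)."""

    population_size: int = 1000
    event_population_size: int | None = None  # optional larger pool for the
    # cheap 2-neuron event modules (their evaluation reuses the frozen
    # time-sense trace); None means population_size everywhere
    generations: int = 500
    selection_fraction: float = 0.20
    mutation_prob: float = 0.02
    mutation_scale: float = 0.10       # additive noise in +-10% of the gene
    mutation_floor: float = 0.10       # magnitude floor so zero genes can escape
    weight_init: float = 5.0           # weights start uniform in [-5, 5]
    bias_init: float = 2.0             # bias range (used when center_crossing=False)
    center_crossing: bool = True       # biases start at half the presynaptic row
    # sum (plus a small jitter), placing every neuron at the centre of its
    # sigmoid where slow, near-marginal dynamics are reachable
    reload_mutation_prob: float = 0.10  # per-gene rate when seeding from reloads
    sessions_per_evaluation: int = 3
    session_refresh_every: int = 1     # draw fresh evaluation sessions every k generations
    validation_sessions: int = 5       # fixed held-out sessions used to snapshot the best team
    tau: float = DEFAULT_TAU
    substeps: int = DEFAULT_SUBSTEPS
    moment_dt: float = DEFAULT_MOMENT_DT
    fresh_sessions: bool = True        # False: every generation reuses the same sessions

    def __post_init__(self):
        for name in ("selection_fraction", "mutation_prob", "reload_mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.generations < 1 or self.population_size < 2:
            raise ValueError("need at least 2 chromosomes and 1 generation")


@dataclass
class Population:
    """The evolving chromosome pool of one module."""

    module: str
    chromosomes: np.ndarray          # (P, L)
    fitness: np.ndarray              # (P,)
    representative: np.ndarray       # (L,) genome used by other populations

    @property
    def size(self) -> int:
        return self.chromosomes.shape[0]

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.fitness))


def _init_genome(spec: ModelSpec, name: str, cfg: EvolutionConfig, rng) -> np.ndarray:
    m = spec.module(name)
    L = spec.genome_length(name)
    n, R, A = m.n_neurons, len(m.ext_channels), spec.n_afferents(name)
    g = rng.uniform(-cfg.weight_init, cfg.weight_init, size=L)
    if cfg.center_crossing:
        wp = g[n * R: n * R + n * A].reshape(n, A)
        g[-n:] = 0.5 * wp.sum(axis=1) + rng.uniform(-0.5, 0.5, size=n)
    else:
        g[-n:] = rng.uniform(-cfg.bias_init, cfg.bias_init, size=n)
    return g


def _population_size(spec: ModelSpec, name: str, cfg: EvolutionConfig) -> int:
    is_event = len(spec.module(name).fitness_events) == 1
    if is_event and cfg.event_population_size is not None:
        return cfg.event_population_size
    return cfg.population_size


def init_population(spec: ModelSpec, name: str, cfg: EvolutionConfig, rng) -> Population:
    size = _population_size(spec, name, cfg)
    chroms = np.stack([_init_genome(spec, name, cfg, rng) for _ in range(size)])
    return Population(
        module=name,
        chromosomes=chroms,
        fitness=np.full(size, np.nan),
        representative=chroms[0].copy(),
    )


def mutate(genes: np.ndarray, cfg: EvolutionConfig, rng, prob: float | None = None) -> np.ndarray:
    """Per-gene additive mutation: +-mutation_scale of the gene's magnitude."""
    p = cfg.mutation_prob if prob is None else prob
    genes = np.asarray(genes, dtype=float)
    mask = rng.random(genes.shape) < p
    scale = cfg.mutation_scale * np.maximum(np.abs(genes), cfg.mutation_floor)
    noise = rng.uniform(-1.0, 1.0, size=genes.shape) * scale
    return np.where(mask, genes + noise, genes)


def single_point_crossover(p1: np.ndarray, p2: np.ndarray, rng) -> np.ndarray:
    """Child takes a prefix of one parent and the suffix of the other."""
    L = p1.shape[0]
    point = int(rng.integers(1, L)) if L > 1 else 0
    return np.concatenate([p1[:point], p2[point:]])


def next_generation(pop: Population, cfg: EvolutionConfig, rng) -> Population:
    """Elitist selection + crossover + mutation; population size preserved."""
    P = pop.size
    n_elite = max(1, int(round(cfg.selection_fraction * P)))
    order = np.argsort(-pop.fitness, kind="stable")
    elite = pop.chromosomes[order[:n_elite]]
    children = []
    for _ in range(P - n_elite):
        i, j = rng.integers(0, n_elite, size=2)
        child = single_point_crossover(elite[i], elite[j], rng)
        children.append(mutate(child, cfg, rng))
    chroms = np.concatenate([elite, np.stack(children)]) if children else elite.copy()
    return Population(
        module=pop.module,
        chromosomes=chroms,
        fitness=np.full(P, np.nan),
        representative=pop.representative.copy(),
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _make_sessions(spec: ModelSpec, cfg: EvolutionConfig, stim_cfg: StimulusConfig, seed_seq):
    """Shared evaluation sessions for one generation (inputs + target traces)."""
    rng = np.random.default_rng(seed_seq)
    has_dist = any(m.name.startswith("tDistance") for m in spec.modules)
    sessions = []
    for _ in range(cfg.sessions_per_evaluation):
        schedule = generate_schedule(rng, stim_cfg)
        bank = OscillatorBank.random(rng, noise_amp=stim_cfg.noise_amp)
        sess = render_session(schedule, bank, rng, n_id_channels=spec.n_events)
        targets = {"dur": duration_target_trace(schedule)}
        if has_dist:
            targets["dist"] = distance_target_trace(schedule)
        sessions.append((sess, targets))
    return sessions


def _batch_matrices(spec: ModelSpec, rep_model: AssembledModel, pop: Population):
    """Stack the representative matrices and substitute each candidate."""
    P = pop.size
    name = pop.module
    rows = spec.rows(name)
    cols = spec.afferent_columns(name)
    m = spec.module(name)
    n, R, A = m.n_neurons, len(m.ext_channels), spec.n_afferents(name)
    chroms = pop.chromosomes
    ws = chroms[:, : n * R].reshape(P, n, R)
    wp = chroms[:, n * R: n * R + n * A].reshape(P, n, A)
    th = chroms[:, n * R + n * A:]
    W = np.repeat(rep_model.W[None], P, axis=0)
    Ws = np.repeat(rep_model.Ws[None], P, axis=0)
    theta = np.repeat(rep_model.theta[None], P, axis=0)
    W[np.ix_(np.arange(P), rows, cols)] = wp
    if R:
        Ws[np.ix_(np.arange(P), rows, np.array(m.ext_channels))] = ws
    theta[:, rows] = th
    return W, Ws, theta


def evaluate_populations(
    spec: ModelSpec,
    populations: dict,
    cfg: EvolutionConfig,
    sessions,
    representatives: dict | None = None,
) -> dict:
    """Score every chromosome of every population on the shared sessions.

    Returns per-module error summaries for the representative team.  The
    populations' ``fitness`` arrays are filled in place.  Representatives
    are *not* updated here.
    """
    reps = representatives or {name: populations[name].representative for name in populations}
    rep_model = AssembledModel(
        spec, reps, tau=cfg.tau, substeps=cfg.substeps, moment_dt=cfg.moment_dt
    )
    alpha = rep_model.alpha
    base = [
        _kernel.simulate_single(rep_model.W, rep_model.Ws, rep_model.theta, sess.inputs, alpha)
        for sess, _ in sessions
    ]

    # representative-team error (for logging): decoded-duration mean abs error
    team = {"dur_abs_error": [], "dist_abs_error": []}
    for (sess, targets), acts in zip(sessions, base):
        sched = sess.schedule
        for i in range(sched.n_events):
            row = spec.readout_row("dur", int(sched.event_ids[i]))
            e = int(sched.ends[i])
            stop = min(e + 10, sched.horizon)
            est = sched.max_duration * float(np.mean(acts[1 + e: 1 + stop, row]))
            team["dur_abs_error"].append(abs(est - float(sched.durations[i])))
            if "dist" in targets:
                drow = spec.readout_row("dist", int(sched.event_ids[i]))
                err = np.abs(acts[1:, drow] - targets["dist"][i])
                team["dist_abs_error"].append(float(np.mean(err[sched.starts[i]:])))

    for name, pop in populations.items():
        W, Ws, theta = _batch_matrices(spec, rep_model, pop)
        active = spec.downstream_rows(name)
        scope = spec.module(name).fitness_events
        record = np.array([spec.readout_row(kind, i) for kind, i in scope])
        errors = np.zeros((pop.size, len(scope)))
        for (sess, targets), base_acts in zip(sessions, base):
            acts = _kernel.simulate_batch(
                W, Ws, theta, sess.inputs, alpha,
                active=active, base_acts=base_acts, record=record,
            )
            sched = sess.schedule
            # training schedules list events in id order (event i on line i)
            for s_idx, (kind, i) in enumerate(scope):
                outs = acts[:, 1:, s_idx]
                target = targets[kind][i] if i < sched.n_events else 0.0
                errors[:, s_idx] += np.sum((outs - target) ** 2, axis=1)
        pop.fitness = np.prod(1000.0 / (errors + EPS_ERROR), axis=1)

    return {k: (float(np.mean(v)) if v else np.nan) for k, v in team.items()}


# ---------------------------------------------------------------------------
# the outer loop
# ---------------------------------------------------------------------------

@dataclass
class EvolutionResult:
    spec: ModelSpec
    genomes: dict                  # best validated team over the whole run
    history: pd.DataFrame          # per generation / module fitness log
    config: EvolutionConfig
    stimulus_config: StimulusConfig
    seed: int
    populations: dict = field(repr=False, default=None)  # type: ignore[assignment]
    final_genomes: dict = field(repr=False, default=None)  # type: ignore[assignment]

    def model(self, **kwargs) -> AssembledModel:
        return AssembledModel(
            self.spec, self.genomes,
            tau=kwargs.get("tau", self.config.tau),
            substeps=kwargs.get("substeps", self.config.substeps),
            moment_dt=kwargs.get("moment_dt", self.config.moment_dt),
        )


def _session_seed(seed: int, gen: int, cfg: EvolutionConfig):
    block = (gen // cfg.session_refresh_every) if cfg.fresh_sessions else 0
    return np.random.SeedSequence(entropy=[seed, 101, block])


def _team_score(spec: ModelSpec, genomes: dict, cfg, val_sessions):
    """Validation score of a representative team on fixed held-out sessions.

    Duration branch: mean |decoded - true| in moments, normalised by M.
    Distance branch (combined model): mean |output - TD target| after each
    onset, in log10 units.  Lower is better.
    """
    model = AssembledModel(
        spec, genomes, tau=cfg.tau, substeps=cfg.substeps, moment_dt=cfg.moment_dt
    )
    dur_errs, dist_errs = [], []
    for sess, targets in val_sessions:
        acts = _kernel.simulate_single(
            model.W, model.Ws, model.theta, sess.inputs, model.alpha
        )
        sched = sess.schedule
        for i in range(sched.n_events):
            row = spec.readout_row("dur", int(sched.event_ids[i]))
            e = int(sched.ends[i])
            stop = min(e + 10, sched.horizon)
            est = sched.max_duration * float(np.mean(acts[1 + e: 1 + stop, row]))
            dur_errs.append(abs(est - float(sched.durations[i])))
            if "dist" in targets:
                drow = spec.readout_row("dist", int(sched.event_ids[i]))
                err = np.abs(acts[1:, drow] - targets["dist"][i])
                dist_errs.append(float(np.mean(err[sched.starts[i]:])))
    dur = float(np.mean(dur_errs))
    dist = float(np.mean(dist_errs)) if dist_errs else 0.0
    M = val_sessions[0][0].schedule.max_duration
    return dur / M + dist, dur, dist


def evolve(
    spec: ModelSpec,
    cfg: EvolutionConfig,
    stim_cfg: StimulusConfig = StimulusConfig(),
    seed: int = 0,
    initial_populations: dict | None = None,
    on_generation=None,
) -> EvolutionResult:
    """Run the full coevolutionary loop; reproducible from ``seed``."""
    if initial_populations is None:
        populations = {
            m.name: init_population(
                spec, m.name, cfg, np.random.default_rng(np.random.SeedSequence([seed, 303, k]))
            )
            for k, m in enumerate(spec.modules)
        }
    else:
        populations = initial_populations

    val_sessions = _make_sessions(
        spec,
        replace(cfg, sessions_per_evaluation=cfg.validation_sessions),
        stim_cfg,
        np.random.SeedSequence(entropy=[seed, 505]),
    )
    best_score, best_genomes = np.inf, None

    records = []
    for gen in range(cfg.generations):
        sessions = _make_sessions(spec, cfg, stim_cfg, _session_seed(seed, gen, cfg))
        team = evaluate_populations(spec, populations, cfg, sessions)
        # simultaneous representative update, then score the new team
        for name, pop in populations.items():
            pop.representative = pop.chromosomes[pop.best_index].copy()
        reps = {name: pop.representative for name, pop in populations.items()}
        score, val_dur, val_dist = _team_score(spec, reps, cfg, val_sessions)
        if score < best_score:
            best_score = score
            best_genomes = {name: g.copy() for name, g in reps.items()}
        for name, pop in populations.items():
            records.append(
                {
                    "generation": gen,
                    "module": name,
                    "best_fitness": float(pop.fitness[pop.best_index]),
                    "mean_fitness": float(np.mean(pop.fitness)),
                    "team_dur_abs_error": team["dur_abs_error"],
                    "team_dist_abs_error": team["dist_abs_error"],
                    "val_dur_abs_error": val_dur,
                    "val_dist_abs_error": val_dist,
                    "val_best_score": best_score,
                }
            )
        if on_generation is not None:
            on_generation(gen, populations, records[-len(populations):])
        if gen < cfg.generations - 1:
            for k, name in enumerate(list(populations)):
                rng = np.random.default_rng(np.random.SeedSequence([seed, 202, gen, k]))
                populations[name] = next_generation(populations[name], cfg, rng)

    final = {name: pop.representative.copy() for name, pop in populations.items()}
    return EvolutionResult(
        spec=spec, genomes=best_genomes if best_genomes is not None else final,
        history=pd.DataFrame(records),
        config=cfg, stimulus_config=stim_cfg, seed=seed, populations=populations,
        final_genomes=final,
    )


def extend_and_retrain(
    old_spec: ModelSpec,
    genomes: dict,
    cfg: EvolutionConfig,
    stim_cfg: StimulusConfig = StimulusConfig(),
    seed: int = 0,
) -> EvolutionResult:
    """Grow a trained interval-timing model into the when+how-long model.

    Populations of pre-existing modules are seeded with the reloaded (lifted)
    genome — kept verbatim as chromosome 0 and initial representative — plus
    mutated copies; populations of the new modules start from random
    genomes.  Evolution then proceeds under the extended fitness tree.
    """
    new_spec = when_and_how_long_model(n_events=old_spec.n_events)
    lifted = lift_genomes(old_spec, new_spec, genomes)
    populations = {}
    for k, m in enumerate(new_spec.modules):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 404, k]))
        if m.name in lifted:
            base = lifted[m.name]
            size = _population_size(new_spec, m.name, cfg)
            chroms = np.stack(
                [base]
                + [
                    mutate(base, cfg, rng, prob=cfg.reload_mutation_prob)
                    for _ in range(size - 1)
                ]
            )
            populations[m.name] = Population(
                module=m.name, chromosomes=chroms,
                fitness=np.full(size, np.nan),
                representative=base.copy(),
            )
        else:
            populations[m.name] = init_population(spec=new_spec, name=m.name, cfg=cfg, rng=rng)
    return evolve(
        new_spec, cfg, stim_cfg, seed=seed, initial_populations=populations
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, spec: ModelSpec, populations: dict, generation: int):
    """Serialise every population (JSON) so a run can be resumed."""
    payload = {
        "spec_name": spec.name,
        "n_events": spec.n_events,
        "generation": generation,
        "populations": {
            name: {
                "chromosomes": pop.chromosomes.tolist(),
                "fitness": np.where(np.isnan(pop.fitness), None, pop.fitness).tolist(),
                "representative": pop.representative.tolist(),
            }
            for name, pop in populations.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path):
    """Load (spec, populations, generation) written by :func:`save_checkpoint`."""
    payload = json.loads(Path(path).read_text())
    builder = {
        "interval_timing": interval_timing_model,
        "when_and_how_long": when_and_how_long_model,
    }[payload["spec_name"]]
    spec = builder(n_events=payload["n_events"])
    populations = {}
    for name, d in payload["populations"].items():
        fit = np.array([np.nan if v is None else v for v in d["fitness"]], dtype=float)
        populations[name] = Population(
            module=name,
            chromosomes=np.array(d["chromosomes"], dtype=float),
            fitness=fit,
            representative=np.array(d["representative"], dtype=float),
        )
    return spec, populations, int(payload["generation"])
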