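"""Target traces and the hierarchical fitness tree.

Two target codes are defined per event *i* with onset ``st_i`` and offset
``e_i``:

* **Duration ramp** ``D_i(t)``: 0 before the event, rises linearly with
  slope ``1/M`` while the tone is on, and holds the plateau
  ``(e_i - st_i)/M`` forever after.  The plateau is the event duration
  normalised by the maximum measurable duration ``M`` (= 50 moments).
* **Temporal distance** ``TD_i(t)``: 0 up to the onset, then
  ``log10(t / st_i)`` — the base-10 logarithmic distance between "now" and
  the event's onset.  With onsets at moment >= 100 in a 1000-moment session
  this stays within the (0, 1) range of a sigmoid output neuron.

Module performance is the sum of squared deviations between a module's
output trace and its target over the session.  Fitness is 1000 divided by
that error; hub modules serving several event modules take the *product*
of the event-module fitnesses, and the root time-sense modules of the
combined when/how-long model take the product of the duration-tree and
distance-tree fitnesses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .stimuli import EventSchedule

__all__ = [
    "EPS_ERROR",
    "duration_target",
    "distance_target",
    "duration_target_trace",
    "distance_target_trace",
    "sum_squared_error",
    "FitnessRecord",
    "fitness_tree",
]

#: Guard added to the divisor of the fitness ratio so a perfect (zero-error)
#: module gets a large finite fitness instead of a division by zero.
EPS_ERROR = 1e-9


def duration_target(t, st: int, e: int, M: int):
    """Ramp-coded duration target D(t) for an event spanning [st, e).

    Returns 0 for t < st, (t - st)/M during the event and the plateau
    (e - st)/M once the event has ended.  ``t`` may be scalar or array.
    """
    if not st < e:
        raise ValueError("event must have positive duration (st < e)")
    if e - st >= M:
        raise ValueError(f"event duration {e - st} must be below the maximum M = {M}")
    t = np.asarray(t, dtype=float)
    out = np.where(t < st, 0.0, np.where(t < e, (t - st) / M, (e - st) / M))
    return float(out) if out.ndim == 0 else out


def distance_target(t, st: int):
    """Logarithmic temporal-distance target TD(t) = log10(t / st) for t > st."""
    if st <= 0:
        raise ValueError("event onset must be a positive moment (log undefined at 0)")
    t = np.asarray(t, dtype=float)
    out = np.where(t <= st, 0.0, np.log10(np.maximum(t, st) / st))
    return float(out) if out.ndim == 0 else out


def duration_target_trace(schedule: EventSchedule, horizon: int | None = None) -> np.ndarray:
    """Stack of D_i(t) traces, shape (n_events, T)."""
    T = horizon if horizon is not None else schedule.horizon
    t = np.arange(T)
    return np.stack(
        [
            duration_target(t, schedule.starts[i], schedule.ends[i], schedule.max_duration)
            for i in range(schedule.n_events)
        ]
    ) if schedule.n_events else np.zeros((0, T))


def distance_target_trace(schedule: EventSchedule, horizon: int | None = None) -> np.ndarray:
    """Stack of TD_i(t) traces, shape (n_events, T)."""
    T = horizon if horizon is not None else schedule.horizon
    t = np.arange(T)
    return np.stack(
        [distance_target(t, schedule.starts[i]) for i in range(schedule.n_events)]
    ) if schedule.n_events else np.zeros((0, T))


def sum_squared_error(out: np.ndarray, target: np.ndarray) -> float:
    """Sum over moments of the squared output/target deviation."""
    out = np.asarray(out, dtype=float)
    target = np.asarray(target, dtype=float)
    if out.shape != target.shape:
        raise ValueError(f"trace length mismatch: {out.shape} vs {target.shape}")
    return float(np.sum((out - target) ** 2))


@dataclass(frozen=True)
class FitnessRecord:
    """The full fitness tree derived from per-module errors.

    ``e_dur``/``ff_dur_i`` always exist; the distance branch is present only
    for the combined when/how-long model (``e_dist`` given).  ``ff`` is the
    product of the duration-module fitnesses (the time-sense fitness of the
    interval-timing model); ``ff_global`` multiplies the duration and
    distance branch products and drives the time-sense modules of the
    combined model.
    """

    e_dur: np.ndarray
    ff_dur_i: np.ndarray
    ff_dur: float
    e_dist: np.ndarray | None = None
    ff_dist_i: np.ndarray | None = None
    ff_dist: float | None = None

    @property
    def ff(self) -> float:
        return self.ff_dur

    @property
    def ff_global(self) -> float | None:
        if self.ff_dist is None:
            return None
        return self.ff_dur * self.ff_dist

    def to_json(self) -> str:
        d = {
            "e_dur": self.e_dur.tolist(),
            "ff_dur_i": self.ff_dur_i.tolist(),
            "ff_dur": self.ff_dur,
            "ff": self.ff,
        }
        if self.e_dist is not None:
            d.update(
                e_dist=self.e_dist.tolist(),
                ff_dist_i=self.ff_dist_i.tolist(),
                ff_dist=self.ff_dist,
                ff_global=self.ff_global,
            )
        return json.dumps(d)


def module_fitness(error) -> np.ndarray | float:
    """Per-module fitness 1000 / error (with a small epsilon guard)."""
    error = np.asarray(error, dtype=float)
    if np.any(error < 0):
        raise ValueError("errors must be non-negative")
    out = 1000.0 / (error + EPS_ERROR)
    return float(out) if out.ndim == 0 else out


def fitness_tree(e_dur, e_dist=None) -> FitnessRecord:
    """Compose per-event errors into the hierarchical fitness record."""
    e_dur = np.asarray(e_dur, dtype=float)
    ff_dur_i = module_fitness(e_dur)
    ff_dur = float(np.prod(ff_dur_i))
    if e_dist is None:
        return FitnessRecord(e_dur=e_dur, ff_dur_i=ff_dur_i, ff_dur=ff_dur)
    e_dist = np.asarray(e_dist, dtype=float)
    ff_dist_i = module_fitness(e_dist)
    ff_dist = float(np.prod(ff_dist_i))
    return FitnessRecord(
        e_dur=e_dur, ff_dur_i=ff_dur_i, ff_dur=ff_dur,
        e_dist=e_dist, ff_dist_i=ff_dist_i, ff_dist=ff_dist,
    )
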