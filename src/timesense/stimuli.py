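"""Synthetic stimuli: noisy oscillator channels and random tone-event sessions.

The model never sees external data.  Its inputs are

* four sinusoidal oscillator channels at fixed angular frequencies
  (4, 1, 0.25, 0.1 radians per moment) with a random phase offset drawn
  once per session from U[0, pi] and independent additive uniform noise
  U[-a, a] per channel and moment (a = 0.05 unless a noise study says
  otherwise), and
* a binary *tone* channel that is 1 while any event is active, together
  with six one-hot *event-id* channels identifying which event it is.

A session lasts ``horizon`` = 1000 moments and contains ``n_events`` = 6
tone events (the working-memory capacity of the model).  Event durations
are random integers below the maximum measurable duration ``M`` = 50, with
a minimum gap of 100 moments between consecutive events and the first
onset at moment >= 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "N_OSCILLATORS",
    "OSCILLATOR_FREQS",
    "StimulusConfig",
    "OscillatorBank",
    "EventSchedule",
    "InputFrame",
    "Session",
    "oscillator_values",
    "generate_schedule",
    "render_session",
    "channel_layout",
]

N_OSCILLATORS = 4

#: Angular frequencies (radians per simulation moment) of the four oscillators.
OSCILLATOR_FREQS = np.array([4.0, 1.0, 0.25, 0.1])


def channel_layout(n_events: int = 6) -> dict:
    """Index layout of the model input vector: oscillators, tone, id lines."""
    return {
        "osc": list(range(N_OSCILLATORS)),
        "tone": N_OSCILLATORS,
        "event_id": list(range(N_OSCILLATORS + 1, N_OSCILLATORS + 1 + n_events)),
        "n_channels": N_OSCILLATORS + 1 + n_events,
    }


@dataclass(frozen=True)
class StimulusConfig:
    """Session-generation parameters (defaults are the study conditions)."""

    horizon: int = 1000
    n_events: int = 6
    max_duration: int = 50       # M: exclusive upper bound on event duration
    min_gap: int = 100           # minimum moments between an end and the next start
    duration_range: tuple = (10, 50)   # uniform integer durations [low, high)
    first_start_min: int = 100   # earliest onset; keeps log10(t/st) <= 1
    end_margin: int = 10         # last event ends at least this early (readout room)
    noise_amp: float = 0.05      # oscillator noise amplitude a


@dataclass(frozen=True)
class OscillatorBank:
    """Per-session oscillator state: phase offsets and noise amplitude."""

    phases: np.ndarray
    noise_amp: float = 0.05
    freqs: np.ndarray = field(default_factory=lambda: OSCILLATOR_FREQS.copy())

    def __post_init__(self):
        phases = np.asarray(self.phases, dtype=float)
        if phases.shape != (N_OSCILLATORS,):
            raise ValueError(f"expected {N_OSCILLATORS} phases, got {phases.shape}")
        if self.noise_amp < 0:
            raise ValueError("noise amplitude must be >= 0")
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))

    @classmethod
    def random(cls, rng: np.random.Generator, noise_amp: float = 0.05) -> "OscillatorBank":
        """Draw fresh phase offsets uniformly from [0, pi]."""
        return cls(phases=rng.uniform(0.0, np.pi, size=N_OSCILLATORS), noise_amp=noise_amp)


def oscillator_values(t, bank: OscillatorBank, rng: np.random.Generator | None = None):
    """Oscillator channel values at moment(s) ``t``: sin(w*t + k) + U[-a, a].

    ``t`` may be a scalar or an array of moments; the result has one row per
    moment and one column per oscillator.  Noise is sampled independently
    per channel and moment; pass ``rng=None`` for the noise-free signal.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    vals = np.sin(np.outer(tt, bank.freqs) + bank.phases[None, :])
    if rng is not None and bank.noise_amp > 0:
        vals = vals + rng.uniform(-bank.noise_amp, bank.noise_amp, size=vals.shape)
    return vals[0] if scalar else vals


@dataclass(frozen=True)
class EventSchedule:
    """Start/end moments of the tone events of one session.

    ``event_ids[i]`` is the one-hot id line (0-based) carried by event *i*;
    by default event *i* uses line *i*, but probe sessions with a single
    event may put it on any line.
    """

    starts: np.ndarray
    ends: np.ndarray
    horizon: int = 1000
    max_duration: int = 50
    min_gap: int = 100
    event_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=int)
        ends = np.asarray(self.ends, dtype=int)
        ids = self.event_ids
        ids = np.arange(starts.size) if ids is None else np.asarray(ids, dtype=int)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "event_ids", ids)
        self.validate()

    def validate(self):
        st, e = self.starts, self.ends
        if st.shape != e.shape or st.ndim != 1:
            raise ValueError("starts/ends must be matching 1-d arrays")
        if st.size == 0:
            return
        dur = e - st
        if np.any(dur <= 0) or np.any(dur >= self.max_duration):
            raise ValueError("event durations must satisfy 0 < e - st < max_duration")
        if np.any(e > self.horizon):
            raise ValueError("events must end within the session horizon")
        if np.any(st[1:] - e[:-1] < self.min_gap):
            raise ValueError("consecutive events must be at least min_gap moments apart")
        if st[0] <= 0:
            raise ValueError("event onsets must be positive moments")
        if self.event_ids.shape != st.shape or np.any(self.event_ids < 0):
            raise ValueError("event_ids must assign one non-negative id line per event")

    @property
    def n_events(self) -> int:
        return self.starts.size

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    def to_json(self) -> str:
        return json.dumps(
            {
                "starts": self.starts.tolist(),
                "ends": self.ends.tolist(),
                "horizon": int(self.horizon),
                "max_duration": int(self.max_duration),
                "min_gap": int(self.min_gap),
                "event_ids": self.event_ids.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EventSchedule":
        d = json.loads(text)
        return cls(
            starts=np.array(d["starts"], dtype=int),
            ends=np.array(d["ends"], dtype=int),
            horizon=d["horizon"],
            max_duration=d["max_duration"],
            min_gap=d["min_gap"],
            event_ids=np.array(d["event_ids"], dtype=int),
        )


def generate_schedule(rng: np.random.Generator, cfg: StimulusConfig = StimulusConfig()) -> EventSchedule:
    """Draw a random feasible event schedule.

    Durations are uniform integers in ``cfg.duration_range``; the slack left
    by the horizon after reserving onsets, gaps and durations is split
    uniformly at random among the inter-event offsets, which jitters every
    start time.  Identical generator state yields an identical schedule.
    """
    n = cfg.n_events
    if n == 0:
        return EventSchedule(
            starts=np.empty(0, int), ends=np.empty(0, int),
            horizon=cfg.horizon, max_duration=cfg.max_duration, min_gap=cfg.min_gap,
        )
    lo, hi = cfg.duration_range
    if not (0 < lo < hi <= cfg.max_duration):
        raise ValueError("duration_range must satisfy 0 < low < high <= max_duration")
    durations = rng.integers(lo, hi, size=n)
    reserved = cfg.first_start_min + int(durations.sum()) + (n - 1) * cfg.min_gap
    slack = cfg.horizon - cfg.end_margin - reserved
    if slack < 0:
        raise ValueError(
            "infeasible session: first_start_min + sum(durations) + "
            f"(n_events-1)*min_gap = {reserved} exceeds horizon - end_margin = "
            f"{cfg.horizon - cfg.end_margin}"
        )
    # split the slack into n non-negative extra offsets (total <= slack)
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    extras = np.diff(np.concatenate(([0], cuts)))
    starts = np.empty(n, int)
    ends = np.empty(n, int)
    cursor = cfg.first_start_min
    for i in range(n):
        starts[i] = cursor + int(extras[i])
        ends[i] = starts[i] + int(durations[i])
        cursor = ends[i] + cfg.min_gap
    return EventSchedule(
        starts=starts, ends=ends,
        horizon=cfg.horizon, max_duration=cfg.max_duration, min_gap=cfg.min_gap,
    )


@dataclass(frozen=True)
class InputFrame:
    """Model input at one moment: oscillators, tone bit, one-hot event id."""

    osc: np.ndarray
    tone: int
    event_id: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.osc, [float(self.tone)], self.event_id])


@dataclass(frozen=True)
class Session:
    """A fully rendered input session (arrays indexed by moment)."""

    schedule: EventSchedule
    bank: OscillatorBank
    osc: np.ndarray        # (T, 4)
    tone: np.ndarray       # (T,)
    event_id: np.ndarray   # (T, n_events)

    @property
    def horizon(self) -> int:
        return self.osc.shape[0]

    @property
    def inputs(self) -> np.ndarray:
        """Concatenated (T, 4 + 1 + n_events) input matrix."""
        return np.concatenate(
            [self.osc, self.tone[:, None].astype(float), self.event_id.astype(float)],
            axis=1,
        )

    def frame(self, t: int) -> InputFrame:
        return InputFrame(osc=self.osc[t], tone=int(self.tone[t]), event_id=self.event_id[t].astype(float))

    def __iter__(self):
        return (self.frame(t) for t in range(self.horizon))

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"osc{j+1}": self.osc[:, j] for j in range(self.osc.shape[1])}
        cols["tone"] = self.tone
        for i in range(self.event_id.shape[1]):
            cols[f"id{i+1}"] = self.event_id[:, i]
        return pd.DataFrame(cols, index=pd.RangeIndex(self.horizon, name="t"))


def render_session(
    schedule: EventSchedule,
    bank: OscillatorBank,
    rng: np.random.Generator | None,
    n_id_channels: int = 6,
) -> Session:
    """Render a schedule into per-moment input arrays with fresh noise.

    The id matrix always has ``n_id_channels`` columns (the model's fixed
    input width) regardless of how many events the schedule contains.
    """
    T = schedule.horizon
    t = np.arange(T)
    osc = oscillator_values(t, bank, rng)
    tone = np.zeros(T, dtype=int)
    event_id = np.zeros((T, n_id_channels), dtype=int)
    for i in range(schedule.n_events):
        st, e = schedule.starts[i], schedule.ends[i]
        tone[st:e] = 1
        event_id[st:e, schedule.event_ids[i]] = 1
    return Session(schedule=schedule, bank=bank, osc=osc, tone=tone, event_id=event_id)
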