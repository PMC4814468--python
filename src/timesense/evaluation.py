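"""Behavioural studies on an assembled model.

Three protocols, all operating on decoded duration estimates:

* :func:`scalar_study` — probe single-tone sessions of fixed true duration
  (20 .. 45 moments), 50 independently initialised runs each, and report
  mean / standard deviation / coefficient of variation of the estimates.
  A timing system with the scalar property shows near-accurate means and
  a variability that grows with duration.
* :func:`noise_study` — full six-event sessions at increasing oscillator
  noise amplitudes; reports the average absolute duration error per event
  and the mean number of *mismeasured* events per session (estimate off by
  more than ``mismeasure_threshold`` = 5 moments, 10% of the maximum
  duration).
* :func:`transient_noise_test` — paired sessions with and without a short
  high-amplitude noise burst during each event; leaky integration should
  smooth out brief disturbances, so the degradation should stay far below
  the effect of sustained noise of the same amplitude.

Both the evolved model (via :class:`ModelTimer`) and an exact oracle that
emits the target traces themselves (:class:`OracleTimer`) satisfy the
timer interface, so every protocol can be sanity-checked against a
perfect reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .architecture import AssembledModel, read_duration
from .stimuli import (
    EventSchedule,
    OscillatorBank,
    Session,
    StimulusConfig,
    generate_schedule,
    render_session,
)
from .targets import duration_target_trace

__all__ = [
    "ModelTimer",
    "OracleTimer",
    "ScalarReport",
    "NoiseReport",
    "TransientReport",
    "scalar_study",
    "noise_study",
    "transient_noise_test",
]

DEFAULT_PROBE_DURATIONS = (20, 25, 30, 35, 40, 45)
DEFAULT_NOISE_AMPLITUDES = (0.03, 0.05, 0.07, 0.09, 0.11, 0.13)

#: An event counts as mismeasured if its decoded duration is off by more
#: than this many moments (10% of the maximum duration M = 50).
MISMEASURE_THRESHOLD = 5.0


class ModelTimer:
    """Adapter running an :class:`AssembledModel` and decoding durations."""

    def __init__(self, model: AssembledModel, window: int = 10):
        self.model = model
        self.window = window

    def duration_estimates(self, session: Session) -> np.ndarray:
        trace = self.model.run_session(session)
        sched = session.schedule
        return np.array(
            [read_duration(trace, i, sched, window=self.window) for i in range(sched.n_events)]
        )


class OracleTimer:
    """Perfect reference: reads durations off the exact target traces."""

    def __init__(self, window: int = 10):
        self.window = window

    def duration_estimates(self, session: Session) -> np.ndarray:
        sched = session.schedule
        targets = duration_target_trace(sched)
        ests = []
        for i in range(sched.n_events):
            e = int(sched.ends[i])
            stop = min(e + self.window, sched.horizon)
            ests.append(sched.max_duration * float(np.mean(targets[i, e:stop])))
        return np.array(ests)


# ---------------------------------------------------------------------------
# scalar-property study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalarReport:
    """Per-probe-duration estimate statistics over independent runs."""

    durations: tuple
    estimates: dict  # duration -> (runs,) decoded estimates

    @property
    def mean(self) -> np.ndarray:
        return np.array([np.mean(self.estimates[d]) for d in self.durations])

    @property
    def std(self) -> np.ndarray:
        return np.array([np.std(self.estimates[d], ddof=1) for d in self.durations])

    @property
    def cv(self) -> np.ndarray:
        return self.std / self.mean

    def scaled_distributions(self) -> dict:
        """Estimates divided by the true duration (identical under scalar timing)."""
        return {d: np.asarray(self.estimates[d]) / d for d in self.durations}

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "actual": list(self.durations),
                "mean": self.mean,
                "std": self.std,
                "cv": self.cv,
            }
        ).set_index("actual")

    def plot(self, path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for d, scaled in self.scaled_distributions().items():
            ax.hist(scaled, bins=15, alpha=0.5, label=f"{d} moments", density=True)
        ax.set_xlabel("estimate / true duration")
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _probe_session(
    duration: int,
    cfg: StimulusConfig,
    rng: np.random.Generator,
    horizon: int = 600,
    start_range=(100, 400),
    n_id_channels: int = 6,
) -> Session:
    """One single-tone probe session with fresh phases, noise, start and id line."""
    st = int(rng.integers(start_range[0], start_range[1] + 1))
    line = int(rng.integers(0, n_id_channels))
    sched = EventSchedule(
        starts=np.array([st]), ends=np.array([st + duration]),
        horizon=horizon, max_duration=cfg.max_duration, min_gap=cfg.min_gap,
        event_ids=np.array([line]),
    )
    bank = OscillatorBank.random(rng, noise_amp=cfg.noise_amp)
    return render_session(sched, bank, rng, n_id_channels=n_id_channels)


def scalar_study(
    timer,
    rng: np.random.Generator,
    durations=DEFAULT_PROBE_DURATIONS,
    runs: int = 50,
    stim_cfg: StimulusConfig = StimulusConfig(),
    horizon: int = 600,
) -> ScalarReport:
    """Estimate-statistics study across probe durations.

    Each run is a fresh single-tone session (random phases, noise, onset in
    [100, 400] and a random id line) containing one event of the probed
    duration; the decoded estimate is collected and summarised per duration.
    """
    estimates = {}
    for d in durations:
        vals = np.empty(runs)
        for r in range(runs):
            sess = _probe_session(d, stim_cfg, rng, horizon=horizon)
            vals[r] = timer.duration_estimates(sess)[0]
        estimates[d] = vals
    return ScalarReport(durations=tuple(durations), estimates=estimates)


# ---------------------------------------------------------------------------
# noise robustness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseReport:
    """Duration accuracy as a function of oscillator noise amplitude."""

    amplitudes: tuple
    abs_errors: dict        # amplitude -> flat array of |estimate - true| per event
    mismeasured: dict       # amplitude -> (sessions,) mismeasured-event counts

    @property
    def avg_abs_error(self) -> np.ndarray:
        return np.array([np.mean(self.abs_errors[a]) for a in self.amplitudes])

    @property
    def mean_mismeasured(self) -> np.ndarray:
        return np.array([np.mean(self.mismeasured[a]) for a in self.amplitudes])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "noise_amplitude": list(self.amplitudes),
                "avg_abs_error": self.avg_abs_error,
                "mean_mismeasured_events": self.mean_mismeasured,
            }
        ).set_index("noise_amplitude")


def noise_study(
    timer,
    rng: np.random.Generator,
    amplitudes=DEFAULT_NOISE_AMPLITUDES,
    sessions_per_level: int = 20,
    stim_cfg: StimulusConfig = StimulusConfig(),
    mismeasure_threshold: float = MISMEASURE_THRESHOLD,
) -> NoiseReport:
    """Run full six-event sessions at each noise amplitude."""
    abs_errors, mismeasured = {}, {}
    for a in amplitudes:
        cfg = dc_replace(stim_cfg, noise_amp=a)
        errs, counts = [], []
        for _ in range(sessions_per_level):
            sched = generate_schedule(rng, cfg)
            bank = OscillatorBank.random(rng, noise_amp=a)
            sess = render_session(sched, bank, rng, n_id_channels=cfg.n_events)
            est = timer.duration_estimates(sess)
            err = np.abs(est - sched.durations)
            errs.append(err)
            counts.append(int(np.sum(err > mismeasure_threshold)))
        abs_errors[a] = np.concatenate(errs)
        mismeasured[a] = np.array(counts)
    return NoiseReport(
        amplitudes=tuple(amplitudes), abs_errors=abs_errors, mismeasured=mismeasured
    )


# ---------------------------------------------------------------------------
# transient noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransientReport:
    """Paired with/without-burst duration errors."""

    burst_amplitude: float
    burst_len: int
    clean_abs_error: np.ndarray
    burst_abs_error: np.ndarray

    @property
    def mean_degradation(self) -> float:
        return float(np.mean(self.burst_abs_error - self.clean_abs_error))


def transient_noise_test(
    timer,
    rng: np.random.Generator,
    burst_amplitude: float = 0.13,
    burst_len: int = 5,
    sessions: int = 20,
    stim_cfg: StimulusConfig = StimulusConfig(),
) -> TransientReport:
    """Compare duration errors with and without short noise bursts.

    For every event of every session an extra uniform noise burst of
    amplitude ``burst_amplitude`` is added to all oscillator channels for
    ``burst_len`` moments starting at a random moment within the event;
    the same session without the bursts serves as the paired control.
    """
    clean_err, burst_err = [], []
    for _ in range(sessions):
        sched = generate_schedule(rng, stim_cfg)
        bank = OscillatorBank.random(rng, noise_amp=stim_cfg.noise_amp)
        sess = render_session(sched, bank, rng, n_id_channels=stim_cfg.n_events)
        osc = sess.osc.copy()
        for i in range(sched.n_events):
            st, e = int(sched.starts[i]), int(sched.ends[i])
            b0 = int(rng.integers(st, e)) if burst_len > 0 else st
            b1 = min(b0 + burst_len, sess.horizon)
            osc[b0:b1] += rng.uniform(-burst_amplitude, burst_amplitude, size=osc[b0:b1].shape)
        noisy = Session(
            schedule=sess.schedule, bank=sess.bank, osc=osc,
            tone=sess.tone, event_id=sess.event_id,
        )
        true = sched.durations.astype(float)
        clean_err.append(np.abs(timer.duration_estimates(sess) - true))
        burst_err.append(np.abs(timer.duration_estimates(noisy) - true))
    return TransientReport(
        burst_amplitude=burst_amplitude,
        burst_len=burst_len,
        clean_abs_error=np.concatenate(clean_err),
        burst_abs_error=np.concatenate(burst_err),
    )
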