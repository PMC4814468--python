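"""Leaky-integrator neuron dynamics for one CTRNN module.

A module is a small set of continuous-time recurrent neurons.  The cell
potential ``gamma_i`` of neuron *i* follows

    tau * dgamma_i/dt = -gamma_i + sum_k ws[i, k] * I_k + sum_m wp[i, m] * A_m

where ``I`` are external input channels and ``A`` are afferent activations
(the module's own neurons plus any neurons projecting into it from other
modules).  The activation is a logistic function of the potential,

    A_i = 1 / (1 + exp(-(gamma_i - theta_i)))

so activations live strictly in (0, 1).  All neurons share the same time
constant ``tau`` (default 0.25) so that no neuron is structurally privileged.

One *simulation moment* — one oscillator sample and one network update —
advances the dynamical time of the neuron equation by ``moment_dt`` = 0.01
units: reading ``tau`` = 0.25 as seconds and a moment as a 10 ms tick (the
physical correspondence usually quoted for this class of model), a neuron
integrates drive over a ~25-moment memory window, which is what lets
ramp-like timing activity emerge.  Each moment is integrated with
``substeps`` forward-Euler
sub-steps of size ``h = moment_dt/substeps`` while the external inputs and
afferent activations are held constant at their values from the previous
moment.  With constant drive the sub-stepped update has the exact closed
form

    gamma(t+1) = d + (gamma(t) - d) * (1 - h/tau) ** substeps

with drive ``d = ws @ I + wp @ A``, which :func:`euler_decay_factor` exposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_TAU",
    "DEFAULT_MOMENT_DT",
    "DEFAULT_SUBSTEPS",
    "NeuronParams",
    "ModuleWiring",
    "ModuleState",
    "sigmoid",
    "euler_decay_factor",
    "step_module",
]

#: Shared neuron time constant, in dynamical-time units.
DEFAULT_TAU = 0.25

#: Dynamical time advanced per simulation moment (a 10 ms tick on a
#: tau = 0.25 s neuron; the neuron memory spans ~25 moments).
DEFAULT_MOMENT_DT = 0.01

#: Euler sub-steps per simulation moment (h = moment_dt/substeps).
DEFAULT_SUBSTEPS = 10


def sigmoid(gamma, theta=0.0):
    """Logistic activation ``1 / (1 + exp(-(gamma - theta)))``.

    Numerically stable for arbitrarily large ``|gamma - theta|`` (saturates
    to 0 or 1 without overflow).  Accepts scalars or arrays.
    """
    x = np.asarray(gamma, dtype=float) - np.asarray(theta, dtype=float)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def euler_decay_factor(
    tau: float, substeps: int, moment_dt: float = DEFAULT_MOMENT_DT
) -> float:
    """Per-moment decay factor ``(1 - h/tau) ** substeps`` of sub-stepped Euler."""
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    if tau <= 0 or moment_dt <= 0:
        raise ValueError("tau and moment_dt must be positive")
    h = moment_dt / substeps
    return (1.0 - h / tau) ** substeps


@dataclass(frozen=True)
class NeuronParams:
    """Activation biases and the shared time constant of one module."""

    theta: np.ndarray
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 1:
            raise ValueError("theta must be a 1-d array (one bias per neuron)")
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta must be finite")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        object.__setattr__(self, "theta", theta)

    @property
    def n_neurons(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class ModuleWiring:
    """Sensory (``ws``) and presynaptic (``wp``) weight matrices of one module.

    ``ws`` has shape (n_neurons, n_inputs); ``wp`` has shape
    (n_neurons, n_afferents) where the afferent axis covers the module's own
    neurons followed by any external afferent neurons.
    """

    ws: np.ndarray
    wp: np.ndarray

    def __post_init__(self):
        ws = np.atleast_2d(np.asarray(self.ws, dtype=float))
        wp = np.atleast_2d(np.asarray(self.wp, dtype=float))
        if ws.shape[0] != wp.shape[0]:
            raise ValueError(
                f"ws and wp disagree on neuron count: {ws.shape[0]} vs {wp.shape[0]}"
            )
        if not (np.all(np.isfinite(ws)) and np.all(np.isfinite(wp))):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "ws", ws)
        object.__setattr__(self, "wp", wp)

    @property
    def n_neurons(self) -> int:
        return self.ws.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.ws.shape[1]

    @property
    def n_afferents(self) -> int:
        return self.wp.shape[1]


@dataclass(frozen=True)
class ModuleState:
    """Cell potentials and matching activations of one module at one moment."""

    gamma: np.ndarray
    activation: np.ndarray = field(default=None)  # type: ignore[assignment]
    theta: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        gamma = np.asarray(self.gamma, dtype=float)
        if not np.all(np.isfinite(gamma)):
            raise ValueError("cell potentials must be finite")
        theta = self.theta
        theta = np.zeros_like(gamma) if theta is None else np.asarray(theta, float)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "activation", sigmoid(gamma, theta))

    @classmethod
    def zeros(cls, params: NeuronParams) -> "ModuleState":
        """Resting state: all potentials at 0, activations at sigmoid(-theta)."""
        return cls(gamma=np.zeros(params.n_neurons), theta=params.theta)


def step_module(
    state: ModuleState,
    wiring: ModuleWiring,
    params: NeuronParams,
    inputs: np.ndarray,
    afferents: np.ndarray,
    substeps: int = DEFAULT_SUBSTEPS,
    moment_dt: float = DEFAULT_MOMENT_DT,
) -> ModuleState:
    """Advance one module by one simulation moment (``moment_dt`` time units).

    ``inputs`` (external channels) and ``afferents`` (activations of all
    afferent neurons, own module first) are held constant over the moment;
    the potentials relax toward the constant drive via ``substeps`` Euler
    sub-steps; activations are recomputed from the final potentials.
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    inputs = np.asarray(inputs, dtype=float)
    afferents = np.asarray(afferents, dtype=float)
    if inputs.shape != (wiring.n_inputs,):
        raise ValueError(
            f"inputs shape {inputs.shape} does not match wiring ({wiring.n_inputs} channels)"
        )
    if afferents.shape != (wiring.n_afferents,):
        raise ValueError(
            f"afferents shape {afferents.shape} does not match wiring "
            f"({wiring.n_afferents} afferents)"
        )
    if not np.all(np.isfinite(state.gamma)):
        raise ValueError("non-finite module state")

    drive = wiring.ws @ inputs + wiring.wp @ afferents
    h = moment_dt / substeps
    gamma = state.gamma.copy()
    for _ in range(substeps):
        gamma = gamma + (h / params.tau) * (drive - gamma)
    return ModuleState(gamma=gamma, theta=params.theta)
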