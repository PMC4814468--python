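"""Batched whole-model simulation kernel.

The assembled model — whatever its module structure — is one block-sparse
CTRNN over ``N`` neurons with dense matrices built by the architecture
layer: a recurrent matrix ``W`` (N x N, structural zeros where no arrow
exists), an input matrix ``Ws`` (N x K) and biases ``theta`` (N,).  The
synchronous update contract (all modules read afferent activations from
the previous moment, drives held constant within a moment) collapses the
sub-stepped Euler integration into the closed-form per-moment update

    gamma[t+1] = alpha * gamma[t] + (1 - alpha) * (W @ A[t] + Ws @ I[t])
    A[t+1]     = sigmoid(gamma[t+1] - theta)

with ``alpha = (1 - 1/(substeps*tau)) ** substeps``, which is algebraically
identical to running ``substeps`` explicit Euler steps with the drive held
fixed.

The kernel integrates a *batch* of models that differ only in their
weights (one coevolution population) and supports freezing a subset of
neuron rows to a precomputed base trace: a candidate genome for an event
module cannot influence upstream modules, so their activations are reused
from a single representative run instead of being re-integrated per
candidate.  Drive contributions from frozen rows and from the external
inputs are precomputed with batched matrix products; the sequential loop
only couples the active rows.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_batch", "simulate_single"]


@njit(cache=True, fastmath=True)
def _integrate(Wact, ext_drive, theta, alpha, rec_pos, rec):
    """Sequential part: integrate active rows only.

    Wact: (B, R, R) active-active coupling; ext_drive: (B, R, T) drive from
    frozen rows + external inputs; theta: (B, R); rec_pos: positions within
    the active set to record; rec: (B, T+1, len(rec_pos)) output.
    """
    B, R, T = ext_drive.shape
    Rr = rec_pos.shape[0]
    beta = 1.0 - alpha
    for b in range(B):
        gamma = np.zeros(R)
        gnew = np.zeros(R)
        A = np.empty(R)
        for r in range(R):
            x = -theta[b, r]
            if x >= 0.0:
                A[r] = 1.0 / (1.0 + np.exp(-x))
            else:
                ex = np.exp(x)
                A[r] = ex / (1.0 + ex)
        for q in range(Rr):
            rec[b, 0, q] = A[rec_pos[q]]
        for t in range(T):
            for r in range(R):
                d = ext_drive[b, r, t]
                for j in range(R):
                    d += Wact[b, r, j] * A[j]
                gnew[r] = alpha * gamma[r] + beta * d
            for r in range(R):
                gamma[r] = gnew[r]
                x = gamma[r] - theta[b, r]
                if x >= 0.0:
                    A[r] = 1.0 / (1.0 + np.exp(-x))
                else:
                    ex = np.exp(x)
                    A[r] = ex / (1.0 + ex)
            for q in range(Rr):
                rec[b, t + 1, q] = A[rec_pos[q]]
    return rec


def simulate_batch(
    W: np.ndarray,
    Ws: np.ndarray,
    theta: np.ndarray,
    inputs: np.ndarray,
    alpha: float,
    active: np.ndarray | None = None,
    base_acts: np.ndarray | None = None,
    record: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate a batch of models over one session.

    Parameters
    ----------
    W, Ws, theta
        Stacked per-candidate matrices, shapes (B, N, N), (B, N, K), (B, N).
    inputs
        Session input matrix (T, K).
    alpha
        Per-moment decay factor (see :func:`timesense.ctrnn.euler_decay_factor`).
    active
        Global row indices integrated per candidate; defaults to all rows.
        Rows outside ``active`` are frozen to ``base_acts``.
    base_acts
        (T+1, N) activation trace supplying the frozen rows; required when
        ``active`` is a proper subset.
    record
        Global row indices to return traces for; defaults to all rows.
        Recorded frozen rows are copied from ``base_acts``.

    Returns
    -------
    acts : (B, T+1, len(record)) activation traces (index 0 = initial state).
    """
    W = np.ascontiguousarray(W, dtype=np.float64)
    Ws = np.ascontiguousarray(Ws, dtype=np.float64)
    theta = np.ascontiguousarray(theta, dtype=np.float64)
    inputs = np.ascontiguousarray(inputs, dtype=np.float64)
    B, N, _ = W.shape
    T = inputs.shape[0]
    active = np.arange(N) if active is None else np.asarray(active, dtype=np.int64)
    record = np.arange(N) if record is None else np.asarray(record, dtype=np.int64)
    frozen = np.setdiff1d(np.arange(N), active)
    if frozen.size and base_acts is None:
        raise ValueError("base_acts required when freezing rows")

    # drive seen by active rows from external inputs and frozen afferents
    ext = np.matmul(Ws[:, active, :], inputs.T)  # (B, R, T)
    if frozen.size:
        Wfroz = np.ascontiguousarray(W[:, active[:, None], frozen[None, :]])
        base_prev = np.ascontiguousarray(base_acts[:T, frozen].T)  # (F, T): A at t-1
        ext = ext + np.matmul(Wfroz, base_prev)
    ext = np.ascontiguousarray(ext)

    Wact = np.ascontiguousarray(W[:, active[:, None], active[None, :]])
    theta_act = np.ascontiguousarray(theta[:, active])

    pos_of = {int(g): i for i, g in enumerate(active)}
    rec_active = np.array([r for r in record if int(r) in pos_of], dtype=np.int64)
    rec_pos = np.array([pos_of[int(r)] for r in rec_active], dtype=np.int64)
    rec = np.empty((B, T + 1, rec_pos.size))
    _integrate(Wact, ext, theta_act, float(alpha), rec_pos, rec)

    if rec_active.size == record.size and np.array_equal(rec_active, record):
        out = rec
    else:
        out = np.empty((B, T + 1, record.size))
        col_of = {int(g): i for i, g in enumerate(rec_active)}
        for i, r in enumerate(record):
            r = int(r)
            if r in col_of:
                out[:, :, i] = rec[:, :, col_of[r]]
            else:
                out[:, :, i] = base_acts[:, r][None, :]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite activation produced during simulation")
    return out


def simulate_single(W, Ws, theta, inputs, alpha) -> np.ndarray:
    """Single-model convenience wrapper; returns the full (T+1, N) trace."""
    return simulate_batch(W[None], Ws[None], theta[None], inputs, alpha)[0]
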