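"""Markov transition matrices and neuron activation thresholds.

The network's per-neuron thresholds are read off a Markov chain built from
the training score matrix ``S`` (rows = sessions, columns = indicators).
The one-step transition matrix ``P(1)`` is a row-normalised similarity
matrix; the m-step matrix ``P(m)`` follows by Chapman-Kolmogorov (the m-th
matrix power); and the threshold of neuron ``i`` is the maximum entry of row
``i`` of ``P(m)`` — the most probable one-step-ahead destination, read as
the activation probability of that neuron.

Two constructions of ``P(1)`` are offered.  ``mode="shape"`` dispatches on
the shape of ``S``: the row-normalised ``S`` itself when square, the
normalised Gram matrix ``SᵀS`` (indicator space, m = K) when there are more
columns than rows, and ``SSᵀ`` (sample space, m = V) when there are more
rows than columns.  ``mode="indicator_space"`` — the default — always works
in indicator space, keeping m equal to the indicator count regardless of the
number of training rows; with V training sessions and K indicators this
keeps the chain K×K instead of V×V, which is what a 7-neuron network
actually consumes and what keeps the construction linear in V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransitionMatrix",
    "normalize_rows",
    "first_step_matrix",
    "step_matrix",
    "thresholds",
]

#: Absolute per-row tolerance for row-stochasticity checks.
ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """A row-stochastic matrix together with its step count and provenance.

    ``branch`` records which construction produced the one-step matrix:
    ``"direct"`` (row-normalised square score matrix), ``"indicator_gram"``
    (normalised SᵀS) or ``"sample_gram"`` (normalised SSᵀ).
    """

    values: np.ndarray
    step: int = 1
    branch: str = "direct"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("transition matrix must be square")
        sums = values.sum(axis=1)
        if np.any(values < -ROW_SUM_TOL) or np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
            raise ValueError("matrix is not row-stochastic")
        object.__setattr__(self, "values", values)

    @property
    def m(self) -> int:
        """Number of states (= neurons)."""
        return self.values.shape[0]


def _as_score_matrix(matrix) -> np.ndarray:
    S = np.asarray(matrix, dtype=float)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("score matrix must be a non-empty 2-D array")
    if not np.all(np.isfinite(S)):
        raise ValueError("score matrix entries must be finite")
    if np.any(S < 0):
        raise ValueError("score matrix entries must be non-negative")
    return S


def normalize_rows(matrix) -> np.ndarray:
    """Divide each row of a non-negative matrix by its sum.

    A row that sums to zero carries no transition information and is replaced
    by the uniform distribution, keeping the result stochastic.
    """
    M = np.asarray(matrix, dtype=float)
    if np.any(M < 0):
        raise ValueError("row normalisation requires non-negative entries")
    sums = M.sum(axis=1, keepdims=True)
    n_cols = M.shape[1]
    out = np.where(sums > 0, M / np.where(sums > 0, sums, 1.0), 1.0 / n_cols)
    return out


def first_step_matrix(S, mode: str = "indicator_space") -> TransitionMatrix:
    """Build the one-step transition matrix P(1) from a score matrix.

    Parameters
    ----------
    S
        V×K score matrix with non-negative entries (rows = sessions,
        columns = indicators).
    mode
        ``"shape"`` dispatches on the shape of ``S`` (see module docstring);
        ``"indicator_space"`` always reduces to the K×K Gram matrix SᵀS.
    """
    S = _as_score_matrix(S)
    V, K = S.shape
    if mode == "indicator_space":
        gram, branch = S.T @ S, "indicator_gram"
    elif mode == "shape":
        if K == V:
            return TransitionMatrix(normalize_rows(S), step=1, branch="direct")
        if K > V:
            gram, branch = S.T @ S, "indicator_gram"
        else:
            gram, branch = S @ S.T, "sample_gram"
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'shape' or 'indicator_space'")
    return TransitionMatrix(normalize_rows(gram), step=1, branch=branch)


def step_matrix(P1: TransitionMatrix | np.ndarray, m: int) -> TransitionMatrix:
    """The m-step transition matrix P(m) = P(1)^m (Chapman-Kolmogorov)."""
    if m < 1:
        raise ValueError("step count m must be >= 1")
    if isinstance(P1, TransitionMatrix):
        values, branch = P1.values, P1.branch
    else:
        tm = TransitionMatrix(np.asarray(P1, dtype=float))
        values, branch = tm.values, tm.branch
    power = np.linalg.matrix_power(values, m)
    # powering can drift rows off 1 by accumulated round-off; renormalise
    power = power / power.sum(axis=1, keepdims=True)
    return TransitionMatrix(power, step=m, branch=branch)


def thresholds(Pm: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Per-neuron activation thresholds: the row maxima of P(m).

    A row maximum of a row-stochastic matrix lies in [1/m, 1], so every
    threshold is a valid activation probability.
    """
    if not isinstance(Pm, TransitionMatrix):
        Pm = TransitionMatrix(np.asarray(Pm, dtype=float))
    return Pm.values.max(axis=1)
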