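"""Discrete Hopfield network: bipolar states, Hebbian weights, dynamics.

Neurons take bipolar values x_j ∈ {−1, +1}; weights are symmetric with zero
diagonal; updates are asynchronous with the sign activation

    x_j ← sgn( Σ_i w_ij x_i − λ T_j ),       sgn(0) = +1,

where T_j is the neuron's activation threshold (here a probability from the
Markov construction) and λ ≥ 0 scales thresholds against the O(1) Hebbian
net inputs.  Asynchronous updates of a symmetric zero-diagonal network never
increase the Lyapunov energy

    E(x) = −½ Σ_ij w_ij x_i x_j + λ Σ_j T_j x_j,

so deterministic runs always reach a fixed point (an attractor).  In
stochastic mode each neuron's computed update is applied with probability
T_j per visit — "the neuron is activated with probability T_j" — using a
seeded generator so runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FitConfig",
    "UpdateStep",
    "UpdateTrace",
    "ConvergenceResult",
    "sgn",
    "hebbian_weights",
    "energy",
    "update_sweep",
    "run_to_convergence",
]


def sgn(value: float) -> int:
    """Sign activation: +1 for net input ≥ 0, −1 otherwise."""
    if not math.isfinite(value):
        raise ValueError(f"sgn requires a finite value, got {value!r}")
    return 1 if value >= 0 else -1


@dataclass(frozen=True)
class FitConfig:
    """Run-time options for the network dynamics.

    ``j_max`` caps the number of full asynchronous sweeps; ``threshold_scale``
    is λ above (0 recovers the classic zero-threshold network);
    ``update_mode`` selects deterministic updates or threshold-probability
    acceptance; ``neuron_order`` fixes the visit order or reshuffles it each
    sweep with the seeded generator.
    """

    j_max: int = 1000
    update_mode: str = "deterministic"
    threshold_scale: float = 1.0
    seed: int | None = None
    neuron_order: str = "fixed"

    def __post_init__(self) -> None:
        if self.j_max < 1:
            raise ValueError("j_max must be >= 1")
        if self.threshold_scale < 0:
            raise ValueError("threshold_scale must be >= 0")
        if self.update_mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")
        if self.neuron_order not in ("fixed", "shuffled"):
            raise ValueError(f"unknown neuron_order {self.neuron_order!r}")


@dataclass(frozen=True)
class UpdateStep:
    neuron: int
    net: float
    old: int
    new: int


@dataclass
class UpdateTrace:
    """Per-neuron records of one or more asynchronous sweeps."""

    steps: list[UpdateStep] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)
    sweeps: int = 0

    @property
    def flips(self) -> int:
        return sum(1 for s in self.steps if s.new != s.old)


@dataclass(frozen=True)
class ConvergenceResult:
    state: np.ndarray
    sweeps: int
    converged: bool
    trace: UpdateTrace


def _as_state(x) -> np.ndarray:
    x = np.asarray(x, dtype=int)
    if x.ndim != 1 or not np.all(np.abs(x) == 1):
        raise ValueError("network state must be a 1-D bipolar (+1/-1) vector")
    return x


def _check_weights(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=0):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.diagonal(W) != 0):
        raise ValueError("weight matrix must have zero diagonal")
    return W


def hebbian_weights(patterns) -> np.ndarray:
    """Store bipolar patterns by the Hebbian outer-product rule.

    w_ij = (1/n) Σ_p ξ_p,i ξ_p,j for i ≠ j, zero diagonal.  Stored patterns
    become attractors of the dynamics in the low-load regime.
    """
    P = np.asarray(patterns, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("need at least one pattern")
    if not np.all(np.abs(P) == 1):
        raise ValueError("patterns must be bipolar (+1/-1)")
    n = P.shape[1]
    W = (P.T @ P) / n
    np.fill_diagonal(W, 0.0)
    return W


def energy(W, x, T=None, threshold_scale: float = 1.0) -> float:
    """Lyapunov energy E = −½ xᵀWx + λ Tᵀx of a state."""
    W = np.asarray(W, dtype=float)
    x = _as_state(x)
    if W.shape != (x.size, x.size):
        raise ValueError("weight matrix and state dimensions disagree")
    e = -0.5 * float(x @ W @ x)
    if T is not None and threshold_scale != 0.0:
        T = np.asarray(T, dtype=float)
        if T.shape != x.shape:
            raise ValueError("threshold vector and state dimensions disagree")
        e += threshold_scale * float(T @ x)
    return e


def _sweep(W, x, T, lam, mode, order, rng, trace: UpdateTrace | None) -> int:
    """One in-place asynchronous pass; returns the number of flips."""
    flips = 0
    for j in order:
        net = float(W[j] @ x) - lam * (float(T[j]) if T is not None else 0.0)
        candidate = sgn(net)
        new = candidate
        if mode == "stochastic":
            accept_p = float(T[j]) if T is not None else 1.0
            if rng.random() >= accept_p:
                new = int(x[j])
        if trace is not None:
            trace.steps.append(UpdateStep(int(j), net, int(x[j]), int(new)))
        if new != x[j]:
            x[j] = new
            flips += 1
        if trace is not None:
            trace.energies.append(energy(W, x, T, lam))
    return flips


def update_sweep(W, X, T=None, config: FitConfig | None = None, rng=None):
    """One full asynchronous pass over all neurons.

    Returns the new state and an :class:`UpdateTrace` with per-neuron net
    inputs and the energy after every visit.
    """
    config = config or FitConfig()
    W = _check_weights(W)
    x = _as_state(X).copy()
    if W.shape[0] != x.size:
        raise ValueError("weight matrix and state dimensions disagree")
    if T is not None and np.asarray(T).shape != x.shape:
        raise ValueError("threshold vector and state dimensions disagree")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    order = np.arange(x.size)
    if config.neuron_order == "shuffled":
        order = rng.permutation(order)
    trace = UpdateTrace()
    _sweep(W, x, T, config.threshold_scale, config.update_mode, order, rng, trace)
    trace.sweeps = 1
    return x, trace


def run_to_convergence(W, X0, T=None, config: FitConfig | None = None,
                       record_trace: bool = False) -> ConvergenceResult:
    """Iterate asynchronous sweeps until a sweep flips nothing, or j_max.

    A sweep with zero flips means every neuron agrees with its sign rule
    (deterministic mode), i.e. the state is a fixed point.  In stochastic
    mode a flipless sweep may also reflect rejected updates; j_max still
    bounds the run.
    """
    config = config or FitConfig()
    W = _check_weights(W)
    x = _as_state(X0).copy()
    if W.shape[0] != x.size:
        raise ValueError("weight matrix and state dimensions disagree")
    rng = np.random.default_rng(config.seed)
    trace = UpdateTrace() if record_trace else None
    order_base = np.arange(x.size)
    converged = False
    sweeps = 0
    for sweeps in range(1, config.j_max + 1):
        order = rng.permutation(order_base) if config.neuron_order == "shuffled" else order_base
        flips = _sweep(W, x, T, config.threshold_scale, config.update_mode, order, rng, trace)
        if flips == 0:
            converged = True
            break
    if trace is not None:
        trace.sweeps = sweeps
    return ConvergenceResult(x, sweeps, converged, trace or UpdateTrace(sweeps=sweeps))
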