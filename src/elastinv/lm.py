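"""Self-adapting Levenberg-Marquardt solver.

Minimizes S(x) = ||Y(x)||^2 for a residual Y with Jacobian J.  The damped
step solves (J^T J + lambda I) d = -J^T Y.  What distinguishes this variant
from classical LM is how the damping lambda is chosen: it is the product of
a self-adaptive factor eta and a theta-weighted mix of two residual/gradient
ratios,

    lambda = eta * [ theta * min(||Y||^2, ||J^T Y||^2) / ||Y||
                   + (1-theta) * min(||Y||^2, ||J^T Y||^2) / ||J^T Y|| ],

and eta evolves between iterations through the gain ratio tau (actual vs
predicted decrease of the squared residual):

    eta_{k+1} = min(c, eta_k * q(tau_k)),      q(tau) = max(0.5, 1 - (2 tau - 1)^2).

Steps are accepted when tau > p0 (strictly); eta is updated every iteration,
accepted or not.  The solver is generic over (residual, jacobian) callables
and fully deterministic.

Because q <= 1, the adaptive factor alone can never *increase* the damping;
after a rejected step the formula above would keep shrinking lambda and the
iteration could re-propose the same (or a wilder) step forever.  ``run``
therefore applies a rejection safeguard: a multiplier nu on lambda that
quadruples while steps are rejected and resets to 1 on every acceptance, so
the published update is exactly what happens on the accepted path and the
safeguard only engages to escape stagnation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg

__all__ = ["LMConfig", "LMState", "IterationRecord", "step_direction", "damping",
           "gain_ratio", "q_function", "update_eta", "run"]


@dataclass(frozen=True)
class LMConfig:
    """Solver constants.  Defaults follow common trust-region practice; every
    value is a plain knob with no hidden coupling.

    epsilon   -- stop when ||J^T Y|| < epsilon (gradient norm)
    theta     -- damping mix in [0, 1]
    c         -- cap on the adaptive factor eta (> 0)
    p0        -- acceptance threshold on the gain ratio, in (0, 1)
    eta1      -- initial adaptive factor, > c
    max_iter  -- iteration budget; hitting it returns best-so-far with a flag
    """

    epsilon: float = 1e-8
    theta: float = 0.5
    c: float = 1e4
    p0: float = 1e-3
    eta1: float = 2e4
    max_iter: int = 500

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"theta must lie in [0, 1]; got {self.theta}")
        if self.c <= 0:
            raise ValueError(f"c must be positive; got {self.c}")
        if not (0.0 < self.p0 < 1.0):
            raise ValueError(f"p0 must lie in (0, 1); got {self.p0}")
        if self.eta1 <= self.c:
            raise ValueError(f"eta1 must exceed c; got eta1={self.eta1}, c={self.c}")
        if self.epsilon <= 0 or self.max_iter < 1:
            raise ValueError("epsilon must be positive and max_iter >= 1")


@dataclass
class IterationRecord:
    k: int
    accepted: bool
    cost: float          # ||Y||^2 at the start of the iteration
    cost_new: float      # ||Y(x + d)||^2
    lam: float
    tau: float
    eta: float
    grad_norm: float

    def as_dict(self) -> dict:
        return {
            "k": self.k, "accepted": self.accepted, "cost": self.cost,
            "cost_new": self.cost_new, "lambda": self.lam, "tau": self.tau,
            "eta": self.eta, "grad_norm": self.grad_norm,
        }


@dataclass
class LMState:
    """Final iterate plus the full per-iteration trace."""

    x: np.ndarray
    cost: float
    grad_norm: float
    n_iter: int
    converged: bool
    trace: list[IterationRecord] = field(default_factory=list)

    def write_trace(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for rec in self.trace:
                fh.write(json.dumps(rec.as_dict()) + "\n")


def step_direction(J: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Damped Gauss-Newton direction d = -(J^T J + lam I)^{-1} J^T Y."""
    JtJ = J.T @ J
    A = JtJ + lam * np.eye(JtJ.shape[0])
    g = J.T @ Y
    try:
        cf = scipy.linalg.cho_factor(A, lower=True)
        return -scipy.linalg.cho_solve(cf, g)
    except np.linalg.LinAlgError as exc:
        if lam > 0:
            raise
        raise np.linalg.LinAlgError("J^T J singular with lam = 0; use positive damping") from exc


def damping(Y: np.ndarray, J: np.ndarray, eta: float, theta: float) -> float:
    """Adaptive damping lambda (see module docstring for the formula)."""
    ny = np.linalg.norm(Y)
    ng = np.linalg.norm(J.T @ Y)
    if ny == 0.0 or ng == 0.0:
        raise ZeroDivisionError("damping undefined at a stationary/zero-residual point")
    m = min(ny * ny, ng * ng)
    return eta * (theta * m / ny + (1.0 - theta) * m / ng)


def gain_ratio(Y: np.ndarray, Y_new: np.ndarray, J: np.ndarray, d: np.ndarray) -> float:
    """tau = (||Y||^2 - ||Y_new||^2) / (||Y||^2 - ||Y + J d||^2).

    Returns -inf when the predicted decrement is not positive (degenerate
    step); the caller treats that as a rejected step.
    """
    c0 = float(Y @ Y)
    actual = c0 - float(Y_new @ Y_new)
    lin = Y + J @ d
    predicted = c0 - float(lin @ lin)
    if predicted <= 0.0:
        return -np.inf
    return actual / predicted


def q_function(tau: float) -> float:
    """q(tau) = max(0.5, 1 - (2 tau - 1)^2); peaks at 1 for tau = 0.5."""
    if not np.isfinite(tau) or abs(tau) > 1e100:
        return 0.5
    with np.errstate(over="ignore"):
        return float(max(0.5, 1.0 - (2.0 * tau - 1.0) ** 2))


def update_eta(eta: float, tau: float, c: float) -> float:
    """eta_next = min(c, eta * q(tau)); capped by c, never shrinks below half."""
    return min(c, eta * q_function(tau))


def run(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    jacobian_fn: Callable[[np.ndarray], np.ndarray],
    x1: np.ndarray,
    config: LMConfig | None = None,
    callback: Callable[[IterationRecord], None] | None = None,
) -> LMState:
    """Run the self-adapting LM iteration from ``x1``.

    Stops when the gradient norm ||J^T Y|| drops below ``config.epsilon`` or
    the iteration budget is exhausted (then ``converged`` is False).
    """
    cfg = config or LMConfig()
    x = np.asarray(x1, dtype=float).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("initial point contains non-finite entries")
    Y = np.asarray(residual_fn(x), dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("residual at the initial point is not finite")
    eta = cfg.eta1
    nu = 1.0                      # rejection safeguard multiplier on lambda
    trace: list[IterationRecord] = []
    J = jacobian_fn(x)
    g = J.T @ Y
    grad_norm = float(np.linalg.norm(g))
    cost = float(Y @ Y)
    k = 0
    converged = grad_norm < cfg.epsilon
    while not converged and k < cfg.max_iter:
        k += 1
        lam = nu * damping(Y, J, eta, cfg.theta)
        d = step_direction(J, Y, lam)
        x_new = x + d
        Y_new = np.asarray(residual_fn(x_new), dtype=float)
        if not np.all(np.isfinite(Y_new)):
            tau = -np.inf
        else:
            tau = gain_ratio(Y, Y_new, J, d)
        accepted = tau > cfg.p0
        cost_new = float(Y_new @ Y_new) if np.all(np.isfinite(Y_new)) else np.inf
        rec = IterationRecord(k=k, accepted=accepted, cost=cost, cost_new=cost_new,
                              lam=lam, tau=tau, eta=eta, grad_norm=grad_norm)
        trace.append(rec)
        if callback is not None:
            callback(rec)
        eta = update_eta(eta, tau, cfg.c)
        nu = 1.0 if accepted else min(nu * 4.0, 1e30)
        if accepted:
            x = x_new
            Y = Y_new
            cost = cost_new
            J = jacobian_fn(x)
            g = J.T @ Y
            grad_norm = float(np.linalg.norm(g))
            converged = grad_norm < cfg.epsilon
    return LMState(x=x, cost=cost, grad_norm=grad_norm, n_iter=k, converged=converged, trace=trace)
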