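"""Iterative minimizers of the registration cost.

The workhorse is the regular-step gradient descent (RSGD): at each
iteration the cost gradient is estimated by central finite differences
and each parameter takes a step of fixed length along its own descent
direction,

    theta_i <- theta_i - alpha_i * sign(g_i),

with a parameter's step length relaxed (alpha_i <- relax * alpha_i)
whenever that parameter's gradient direction reverses, i.e. the iterate
has stepped across the valley along that axis.  In one dimension this is
exactly the classic rule — fixed step along the gradient, step halved on
direction reversal; keeping a step length *per parameter* extends it to
the 6-DOF pose, where the cost is orders of magnitude more sensitive to
in-plane motion than to motion along the X-ray axis: a shared step length
would be ground down by the strong axes' oscillation long before the weak
axis had travelled anywhere.  An optional regrowth factor (`grow`, off by
default) multiplies a parameter's step while its gradient direction stays
consistent, letting an axis whose step collapsed early — e.g. from
coupling bias while other parameters were still far off — recover; 1.2 is
the customary choice (resilient-propagation heuristic), small enough that
relaxation wins near the optimum.

The walk stops when every step length falls below step_min, the gradient
vanishes, the cost plateaus, or max_iter is hit.  Because steps have
fixed length the method cannot creep to a halt far from the optimum the
way a vanishing-gradient descent can, yet the relaxation lets it settle
to within ~step_min of the minimizer.

Plain gradient descent (fixed step, no relaxation) and Powell's
derivative-free direction-set method are provided as baselines; Powell is
delegated to scipy.optimize.

Parameters mix degrees and millimetres; per-parameter `scales` put them
on a common footing (default 1 deg ~ 1 mm).  Finite-difference probes and
step lengths are taken in this scaled space.  The returned optimum is the
best (lowest-cost) point visited, not necessarily the last iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


@dataclass
class OptimizerConfig:
    step0: float = 1.0
    step_min: float = 0.01
    relax: float = 0.5
    grow: float = 1.0  # step regrowth on consistent direction; 1.0 = off
    restarts: int = 0  # step-length resets from the best point, within max_iter
    max_iter: int = 200
    grad_delta: float = 0.5  # finite-difference offset, scaled units
    scales: np.ndarray | None = None  # per-parameter scale; default all 1
    flat_tol: float = 1e-6
    flat_patience: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.step_min < self.step0):
            raise ValueError(f"need 0 < step_min < step0, got {self.step_min}, {self.step0}")
        if not (0 < self.relax < 1):
            raise ValueError(f"relax must be in (0, 1), got {self.relax}")
        if self.grow < 1:
            raise ValueError(f"grow must be >= 1, got {self.grow}")
        if self.restarts < 0:
            raise ValueError(f"restarts must be >= 0, got {self.restarts}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.scales is not None:
            self.scales = np.asarray(self.scales, dtype=float)
            if np.any(self.scales <= 0):
                raise ValueError("scales must be positive")

    def scales_for(self, n: int) -> np.ndarray:
        return np.ones(n) if self.scales is None else self.scales


@dataclass
class OptimizerState:
    """Terminal state (and trace) of one optimizer run."""

    theta: np.ndarray  # best-so-far parameters
    cost: float
    alpha: float
    k: int
    converged: bool
    reason: str
    trace: list = field(default_factory=list)  # dicts: k, theta, alpha, cost


class OptimizationError(RuntimeError):
    pass


def _checked(cost, theta) -> float:
    c = float(cost(np.asarray(theta, dtype=float)))
    if not np.isfinite(c):
        raise OptimizationError(f"non-finite cost {c} at theta={np.asarray(theta)}")
    return c


def fd_gradient(cost, theta, cfg: OptimizerConfig, delta=None) -> np.ndarray:
    """Central-difference gradient, evaluated in scaled parameter space.

    `delta` optionally overrides the per-parameter probe offset (scaled
    units); the descent loops pass the current step length here so the
    slope is always measured over the distance about to be travelled.
    """
    theta = np.asarray(theta, dtype=float)
    scales = cfg.scales_for(theta.size)
    if delta is None:
        delta = np.full(theta.size, cfg.grad_delta)
    else:
        delta = np.broadcast_to(np.asarray(delta, dtype=float), (theta.size,))
    g = np.empty_like(theta)
    for i in range(theta.size):
        d_i = delta[i] * scales[i]
        tp, tm = theta.copy(), theta.copy()
        tp[i] += d_i
        tm[i] -= d_i
        g[i] = (_checked(cost, tp) - _checked(cost, tm)) / (2 * d_i) / scales[i]
    return g


def _descent(cost, theta0, cfg: OptimizerConfig, relax_steps: bool) -> OptimizerState:
    theta = np.asarray(theta0, dtype=float).copy()
    scales = cfg.scales_for(theta.size)
    alpha = np.full(theta.size, float(cfg.step0))
    c = _checked(cost, theta)
    best_theta, best_cost = theta.copy(), c
    trace = [{"k": 0, "theta": theta.copy(), "alpha": float(alpha.max()), "cost": c}]
    d_prev = None
    flat_run = 0
    k = 0
    restarts_left = cfg.restarts
    best_at_restart = c
    converged, reason = False, "max_iter"
    while k < cfg.max_iter:
        # Probe each axis over (at most) the distance it is about to move.
        g = fd_gradient(cost, theta, cfg,
                        delta=np.clip(alpha, cfg.step_min, cfg.grad_delta))
        gnorm = float(np.linalg.norm(g))
        if gnorm < 1e-12:
            converged, reason = True, "zero_gradient"
            break
        d = np.sign(g)
        if relax_steps and d_prev is not None:
            flipped = d * d_prev < 0
            steady = d * d_prev > 0
            alpha[flipped] *= cfg.relax
            if cfg.grow > 1:
                alpha[steady] = np.minimum(alpha[steady] * cfg.grow, cfg.step0)
            if float(alpha.max()) < cfg.step_min:
                if restarts_left > 0 and best_cost < best_at_restart - 1e-10:
                    # Re-open the step budget from the best point seen so
                    # far; worthwhile while each convergence still improves.
                    restarts_left -= 1
                    best_at_restart = best_cost
                    theta = best_theta.copy()
                    alpha[:] = cfg.step0
                    d_prev = None
                    flat_run = 0
                    c = best_cost
                    continue
                converged, reason = True, "step_min"
                break
        if d_prev is None:
            d_prev = d
        else:
            d_prev = np.where(d != 0, d, d_prev)  # remember last nonzero direction
        theta = theta - alpha * d * scales
        c_new = _checked(cost, theta)
        k += 1
        trace.append({"k": k, "theta": theta.copy(), "alpha": float(alpha.max()), "cost": c_new})
        if c_new < best_cost:
            best_theta, best_cost = theta.copy(), c_new
        if abs(c_new - c) < cfg.flat_tol:
            flat_run += 1
            if flat_run >= cfg.flat_patience:
                converged, reason = True, "flat"
                break
        else:
            flat_run = 0
        c = c_new
    return OptimizerState(
        theta=best_theta, cost=best_cost, alpha=float(alpha.max()), k=k,
        converged=converged, reason=reason, trace=trace,
    )


def rsgd_minimize(cost, theta0, cfg: OptimizerConfig | None = None) -> OptimizerState:
    """Regular-step gradient descent with step relaxation on reversal."""
    return _descent(cost, theta0, cfg or OptimizerConfig(), relax_steps=True)


def gd_minimize(cost, theta0, cfg: OptimizerConfig | None = None) -> OptimizerState:
    """Plain fixed-step gradient descent (no step relaxation)."""
    return _descent(cost, theta0, cfg or OptimizerConfig(), relax_steps=False)


def powell_minimize(cost, theta0, cfg: OptimizerConfig | None = None) -> OptimizerState:
    """Powell's direction-set method (Brent line minimizations)."""
    cfg = cfg or OptimizerConfig()
    theta0 = np.asarray(theta0, dtype=float)
    scales = cfg.scales_for(theta0.size)
    trace = []

    def scaled_cost(u):
        c = _checked(cost, u * scales)
        return c

    def cb(uk):
        trace.append({
            "k": len(trace) + 1, "theta": uk * scales,
            "alpha": float("nan"), "cost": scaled_cost(uk),
        })

    u0 = theta0 / scales
    trace.append({"k": 0, "theta": theta0.copy(), "alpha": float("nan"),
                  "cost": scaled_cost(u0)})
    res = optimize.minimize(
        scaled_cost, u0, method="Powell", callback=cb,
        options={"xtol": 1e-4, "ftol": cfg.flat_tol, "maxiter": cfg.max_iter},
    )
    theta = np.asarray(res.x) * scales
    return OptimizerState(
        theta=theta, cost=float(res.fun), alpha=float("nan"),
        k=int(res.get("nit", len(trace) - 1)), converged=bool(res.success),
        reason=res.message, trace=trace,
    )
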