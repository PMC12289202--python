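"""Integration of the coupled trait dynamics and transition classification.

The mean traits evolve by the canonical equations

    d alpha / dt = vH * G_H(alpha, beta)
    d beta  / dt = vP * G_P(alpha, beta)

with one boundary rule: discrimination ability cannot become negative, so
``d alpha/dt`` is set to 0 whenever ``alpha = 0`` and the host gradient is
negative (the trajectory slides along the boundary until selection on alpha
turns positive).

Trajectories are integrated with an adaptive explicit Runge-Kutta scheme
(RK45, rtol 1e-8 / atol 1e-10) and stopped early by terminal events: entry
into a small ball around a supplied stable attractor, or collapse of the
phase-velocity norm below ``grad_tol`` (the state has reached *some* fixed
point).  A transition of interaction type is a sign change of beta(t);
crossings are debounced so numerical jitter around commensalism (|beta|
below ``eps_beta``) is never counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import FixedPoint
from .model import (
    ModelParams,
    TraitState,
    host_selection_gradient,
    partner_selection_gradient,
)

__all__ = [
    "Trajectory",
    "UnclassifiableTrajectoryError",
    "trait_derivatives",
    "integrate_trajectory",
    "classify_transition",
]

#: Phase-velocity norm below which the state counts as converged.
GRAD_TOL = 1e-10

#: Distance to a supplied stable attractor that counts as arrival.
ATTRACTOR_TOL = 1e-3

#: Default integration horizon (model time units).
DEFAULT_T_END = 1e6

#: Debounce threshold on |beta| for transition counting.
EPS_BETA = 1e-3

#: Minimum number of stored points per trajectory (dense resampling).
N_DENSE = 500


class UnclassifiableTrajectoryError(ValueError):
    """Transition classification requested for an unconverged trajectory."""


@dataclass
class Trajectory:
    """A time-indexed trait path with convergence metadata.

    ``converged_to`` is the attractor reached (when attractors were supplied
    or convergence was detected), else None.  ``beta_sign_changes`` lists
    debounced zero crossings of beta(t) as (time, direction) with direction
    "+to-" or "-to+".
    """

    times: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray
    params: ModelParams
    converged: bool
    converged_to: FixedPoint | None = None
    beta_sign_changes: list[tuple[float, str]] = field(default_factory=list)
    pathway_label: str = "unclassified"

    @property
    def initial(self) -> TraitState:
        return TraitState(float(self.alphas[0]), float(self.betas[0]))

    @property
    def final(self) -> TraitState:
        return TraitState(float(self.alphas[-1]), float(self.betas[-1]))

    def to_dataframe(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "alpha": self.alphas, "beta": self.betas}
        )


def trait_derivatives(
    state: TraitState, params: ModelParams
) -> tuple[float, float]:
    """(d alpha/dt, d beta/dt) at a trait state, with the alpha >= 0 rule.

    Negative alpha (possible transiently inside an adaptive integrator) is
    evaluated at the clamped value alpha = 0.
    """
    alpha = max(state[0], 0.0)
    beta = state[1]
    s = TraitState(alpha, beta)
    gh = host_selection_gradient(s, params)
    gp = partner_selection_gradient(s, params)
    dalpha = params.vH * gh if (alpha > 0.0 or gh > 0.0) else 0.0
    return (dalpha, params.vP * gp)


def _speed(state: Sequence[float], params: ModelParams) -> float:
    da, db = trait_derivatives(TraitState(state[0], state[1]), params)
    return math.hypot(da, db)


def integrate_trajectory(
    initial: TraitState,
    params: ModelParams,
    t_end: float = DEFAULT_T_END,
    attractors: Sequence[FixedPoint] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    grad_tol: float = GRAD_TOL,
    attractor_tol: float = ATTRACTOR_TOL,
    n_dense: int = N_DENSE,
) -> Trajectory:
    """Integrate the trait dynamics from ``initial`` until convergence.

    Stops at the first of: entry into an ``attractor_tol`` ball around one
    of the supplied stable ``attractors``; phase-velocity norm below
    ``grad_tol``; or ``t_end``.  The stored path is resampled from the dense
    integrator output at >= ``n_dense`` points, with alpha clamped to >= 0.

    Raises
    ------
    RuntimeError
        On integrator failure (step-size collapse); the message includes the
        last valid state.
    """
    alpha0, beta0 = initial
    if alpha0 < 0:
        raise ValueError("initial alpha must be non-negative")
    if beta0 >= params.beta_max:
        raise ValueError("initial beta must lie below beta_max")
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    def rhs(t: float, y: np.ndarray) -> list[float]:
        return list(trait_derivatives(TraitState(y[0], y[1]), params))

    events = []
    stable = [fp for fp in (attractors or []) if fp.stability == "stable"]
    for fp in stable:
        def hit(t, y, fp=fp):
            return math.hypot(y[0] - fp.alpha, y[1] - fp.beta) - attractor_tol

        hit.terminal = True
        hit.direction = -1
        events.append(hit)

    def stalled(t, y):
        return _speed(y, params) - grad_tol

    stalled.terminal = True
    stalled.direction = -1
    events.append(stalled)

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [alpha0, beta0],
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=events,
    )
    if sol.status == -1:
        raise RuntimeError(
            f"integration failed: {sol.message}; last valid state "
            f"t={sol.t[-1]:.6g}, (alpha, beta)=({sol.y[0, -1]:.6g}, "
            f"{sol.y[1, -1]:.6g})"
        )

    t_final = float(sol.t[-1])
    times = np.linspace(0.0, t_final, max(n_dense, len(sol.t)))
    path = sol.sol(times)
    # exact endpoint (event location) rather than interpolant tail
    path[:, -1] = sol.y[:, -1]
    alphas = np.maximum(path[0], 0.0)
    betas = path[1]

    converged = sol.status == 1  # a terminal event fired
    converged_to: FixedPoint | None = None
    if converged and stable:
        final = (float(alphas[-1]), float(betas[-1]))
        nearest = min(stable, key=lambda fp: fp.distance_to(final))
        if nearest.distance_to(final) <= 10 * attractor_tol:
            converged_to = nearest

    traj = Trajectory(
        times=times,
        alphas=alphas,
        betas=betas,
        params=params,
        converged=converged,
        converged_to=converged_to,
    )
    traj.beta_sign_changes = _sign_changes(traj)
    if converged:
        traj.pathway_label = classify_transition(traj)
    return traj


def _sign_changes(
    traj: Trajectory, eps_beta: float = EPS_BETA
) -> list[tuple[float, str]]:
    """Debounced zero crossings of beta(t): a crossing counts only between
    consecutive excursions of |beta| > eps_beta with opposite signs."""
    changes: list[tuple[float, str]] = []
    last_sign = 0
    for t, b in zip(traj.times, traj.betas):
        if abs(b) <= eps_beta:
            continue
        sign = 1 if b > 0 else -1
        if last_sign != 0 and sign != last_sign:
            changes.append((float(t), "+to-" if sign < 0 else "-to+"))
        last_sign = sign
    return changes


def classify_transition(traj: Trajectory, eps_beta: float = EPS_BETA) -> str:
    """Label the transition pathway of a converged trajectory.

    Returns one of:

    * ``"none"`` — beta never crosses zero;
    * ``"M_to_A"`` — single mutualism-to-antagonism crossing;
    * ``"A_to_M"`` — single antagonism-to-mutualism crossing;
    * ``"back_and_forth"`` — antagonism to transient mutualism and back;
    * ``"other"`` — anything else, including near-commensalistic starts
      (|beta0| <= eps_beta, where the initial interaction type is undefined).

    Raises
    ------
    UnclassifiableTrajectoryError
        If the trajectory did not converge.
    """
    if not traj.converged:
        raise UnclassifiableTrajectoryError(
            "trajectory did not converge; transition pathway undefined"
        )
    if abs(traj.betas[0]) <= eps_beta:
        return "other"
    dirs = [d for _, d in _sign_changes(traj, eps_beta)]
    if not dirs:
        return "none"
    if dirs == ["+to-"]:
        return "M_to_A"
    if dirs == ["-to+"]:
        return "A_to_M"
    if dirs == ["-to+", "+to-"]:
        return "back_and_forth"
    return "other"
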