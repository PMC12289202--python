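"""Null-isoclines, fixed points and linear stability analysis.

The coupled trait dynamics

    d alpha / dt = vH * G_H(alpha, beta)
    d beta  / dt = vP * G_P(alpha, beta)

have fixed points where both selection gradients vanish simultaneously,
i.e. at intersections of the two null-isoclines:

* host isocline:     beta^2 * f * (1-f) = cD
* partner isocline:  alpha * (1-f) * wP_hat(beta) = cP

The partner isocline is single-valued as beta(alpha) (the left-hand side is
strictly decreasing in beta for alpha > 0) but *not* as alpha(beta): for
beta > 0 the equation has zero or two alpha roots.  Both parameterizations
are provided.

Fixed points are located by two independent routes: multi-start Newton
iteration from a grid of seeds (``method="newton"``), and a scan of the host
gradient along the single-valued partner isocline (``method="isocline"``,
exhaustive for interior fixed points and much faster — every fixed point must
lie on the partner isocline).  Stability follows from the eigenvalues of the
analytic Jacobian.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .model import (
    ModelParams,
    TraitState,
    host_selection_gradient,
    partner_hat_fitness,
    partner_selection_gradient,
    sigmoid,
)

__all__ = [
    "FixedPoint",
    "BoundaryJacobianError",
    "host_isocline",
    "partner_isocline_beta",
    "partner_isocline_alpha",
    "sample_isoclines",
    "jacobian",
    "classify_stability",
    "find_fixed_points",
    "DEFAULT_REGION",
]

logger = logging.getLogger(__name__)

#: Default trait-space search window (alpha_min, alpha_max, beta_min, beta_max).
#: Contains all baseline structure with margin; the beta ceiling is further
#: capped at beta_max - 0.01 at run time.
DEFAULT_REGION = (0.0, 8.0, -3.0, 3.0)

#: Eigenvalue real-part threshold separating stable/unstable from marginal.
MARGINALITY_TAU = 1e-12

#: |beta*| below which a fixed point counts as commensalistic.
COMMENSAL_TOL = 1e-6

#: Euclidean distance below which two fixed-point candidates are duplicates.
DEDUP_TOL = 1e-4

#: Both gradients must vanish to this absolute tolerance at a fixed point.
ROOT_TOL = 1e-10


class BoundaryJacobianError(ValueError):
    """Jacobian requested on the alpha = 0 boundary, where the clamped
    dynamics are not differentiable."""


@dataclass(frozen=True)
class FixedPoint:
    """A simultaneous zero of both selection gradients.

    Attributes
    ----------
    alpha, beta : trait-space coordinates.
    eigenvalues : the two Jacobian eigenvalues (complex).
    stability : "stable", "unstable" or "marginal".
    interaction_type : "mutualistic" (beta > 0), "antagonistic" (beta < 0)
        or "commensalistic" (|beta| <= COMMENSAL_TOL).
    """

    alpha: float
    beta: float
    eigenvalues: tuple[complex, complex] = field(default=(0j, 0j))
    stability: str = "unclassified"
    interaction_type: str = "unclassified"

    @property
    def state(self) -> TraitState:
        return TraitState(self.alpha, self.beta)

    def distance_to(self, state: Sequence[float]) -> float:
        return math.hypot(self.alpha - state[0], self.beta - state[1])

    def to_dict(self) -> dict:
        lam1, lam2 = self.eigenvalues
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "eigenvalue_1": {"re": lam1.real, "im": lam1.imag},
            "eigenvalue_2": {"re": lam2.real, "im": lam2.imag},
            "stability": self.stability,
            "interaction_type": self.interaction_type,
        }


# ---------------------------------------------------------------------------
# Null-isoclines
# ---------------------------------------------------------------------------

def host_isocline(beta: float, params: ModelParams) -> tuple[float, ...]:
    """Alpha values on the host null-isocline at a given beta.

    Solves ``beta^2 * f * (1-f) = cD`` with ``f = sigmoid(alpha*beta)`` in
    closed form.  Since ``f(1-f) <= 1/4``, no solution exists when
    ``beta^2 < 4*cD``; otherwise there is exactly one alpha >= 0 (the tangent
    case ``beta^2 = 4*cD`` gives alpha = 0).  For beta = 0 the host gradient
    is identically -cD, so the isocline is empty whenever cD > 0.
    """
    if beta == 0.0:
        return () if params.cD > 0 else (0.0,)
    c = params.cD / (beta * beta)
    if c > 0.25:
        return ()
    if params.cD == 0.0:
        return (0.0,)
    # f(1-f) = c  =>  f = (1 + sqrt(1-4c)) / 2 on the branch alpha*beta >= 0
    root = math.sqrt(1.0 - 4.0 * c)
    p = (1.0 + root) / 2.0
    u0 = math.log(p / (1.0 - p)) if p < 1.0 else math.inf
    return (u0 / abs(beta),)


def partner_isocline_beta(alpha: float, params: ModelParams) -> float:
    """The unique beta on the partner null-isocline at a given alpha > 0.

    Solves ``g(beta) = alpha*(1-f)*wP_hat(beta) - cP = 0``; g is strictly
    decreasing in beta, positive for beta -> -inf and equal to -cP at
    beta = beta_max, so a bracketed root always exists.  As alpha -> inf the
    solution tends to 0+ (near-commensal service suffices under strong
    discrimination); as alpha -> 0+ it diverges to -inf.
    """
    if alpha <= 0:
        raise ValueError("partner isocline requires alpha > 0")

    def g(beta: float) -> float:
        f = sigmoid(alpha * beta)
        return alpha * (1.0 - f) * partner_hat_fitness(beta, params) - params.cP

    hi = params.beta_max - 1e-12
    lo = -10.0
    while g(lo) < 0:
        lo *= 2.0
        if lo < -1e15:  # pragma: no cover - unreachable for valid params
            raise RuntimeError("failed to bracket partner isocline")
    return float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16))


def partner_isocline_alpha(beta: float, params: ModelParams) -> tuple[float, ...]:
    """All alpha > 0 on the partner null-isocline at a given beta.

    For beta <= 0 the root is unique.  For beta > 0, ``alpha*(1-f)`` is
    unimodal in alpha, so there are zero or two roots (one duplicated root at
    tangency); both are returned in increasing order.
    """
    wp = partner_hat_fitness(beta, params)
    if wp <= 0:
        return ()

    def g(alpha: float) -> float:
        f = sigmoid(alpha * beta)
        return alpha * (1.0 - f) * wp - params.cP

    if beta <= 0:
        hi = 1.0
        while g(hi) < 0:
            hi *= 2.0
            if hi > 1e15:  # pragma: no cover
                raise RuntimeError("failed to bracket partner isocline")
        return (float(optimize.brentq(g, 0.0, hi, xtol=1e-12, rtol=8.9e-16)),)

    # beta > 0: alpha*(1-sigmoid(alpha*beta)) peaks where u*sigmoid(u)=1,
    # u = alpha*beta  (u_peak ~ 1.27846)
    u_peak = float(optimize.brentq(lambda u: u * sigmoid(u) - 1.0, 1.0, 2.0))
    a_peak = u_peak / beta
    if g(a_peak) < 0:
        return ()
    if g(a_peak) == 0:
        return (a_peak, a_peak)
    lo_root = float(optimize.brentq(g, 0.0, a_peak, xtol=1e-12, rtol=8.9e-16))
    hi = 2.0 * a_peak
    while g(hi) > 0:
        hi *= 2.0
    hi_root = float(optimize.brentq(g, a_peak, hi, xtol=1e-12, rtol=8.9e-16))
    return (lo_root, hi_root)


def sample_isoclines(
    params: ModelParams,
    beta_range: tuple[float, float] = (-3.0, 3.0),
    n: int = 400,
) -> "pd.DataFrame":
    """Sample both null-isoclines for export/plotting.

    Returns a tidy table with columns (beta, alpha, isocline_id, branch);
    the partner isocline's two beta > 0 branches are labelled "lower" and
    "upper", single-valued segments "main".
    """
    import pandas as pd

    lo, hi = beta_range
    hi = min(hi, params.beta_max - 1e-6)
    betas = np.linspace(lo, hi, n)
    rows: list[tuple[float, float, str, str]] = []
    for b in betas:
        for a in host_isocline(float(b), params):
            rows.append((float(b), a, "host", "main"))
        roots = partner_isocline_alpha(float(b), params)
        if len(roots) == 1:
            rows.append((float(b), roots[0], "partner", "main"))
        elif len(roots) == 2:
            rows.append((float(b), roots[0], "partner", "lower"))
            rows.append((float(b), roots[1], "partner", "upper"))
    return pd.DataFrame(rows, columns=["beta", "alpha", "isocline_id", "branch"])


# ---------------------------------------------------------------------------
# Jacobian and stability
# ---------------------------------------------------------------------------

def gradient_vector(state: Sequence[float], params: ModelParams) -> np.ndarray:
    """(G_H, G_P) as an array; helper for root finding."""
    s = TraitState(float(state[0]), float(state[1]))
    return np.array(
        [host_selection_gradient(s, params), partner_selection_gradient(s, params)]
    )


def jacobian(state: TraitState, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of (vH*G_H, vP*G_P) with respect to (alpha, beta).

    Derivatives use f' = f(1-f) for f = sigmoid(alpha*beta):

        dG_H/da = beta^3 * s * (1-2f)
        dG_H/db = beta * s * (2 + alpha*beta*(1-2f))
        dG_P/da = beta*s*g + f*((1-f)*wp - alpha*beta*s*wp)
        dG_P/db = alpha*s*g + f*(-alpha^2*s*wp - alpha*(1-f)*cP)

    with s = f(1-f), wp = wP_hat(beta), g = alpha*(1-f)*wp - cP.

    Raises
    ------
    BoundaryJacobianError
        At alpha = 0, where the clamped alpha-dynamics are non-smooth.
    """
    alpha, beta = state
    if alpha <= 0:
        raise BoundaryJacobianError(
            "Jacobian undefined on the alpha=0 boundary (clamped dynamics)"
        )
    dG = _gradient_jacobian(state, params)
    return np.array([[params.vH], [params.vP]]) * dG


def _gradient_jacobian(state: TraitState, params: ModelParams) -> np.ndarray:
    """Jacobian of the raw gradient field (G_H, G_P), without the (vH, vP)
    row scaling."""
    alpha, beta = state
    f = sigmoid(alpha * beta)
    s = f * (1.0 - f)
    wp = partner_hat_fitness(beta, params)
    g = alpha * (1.0 - f) * wp - params.cP

    dGH_da = beta**3 * s * (1.0 - 2.0 * f)
    dGH_db = beta * s * (2.0 + alpha * beta * (1.0 - 2.0 * f))
    dGP_da = beta * s * g + f * ((1.0 - f) * wp - alpha * beta * s * wp)
    dGP_db = alpha * s * g + f * (-(alpha**2) * s * wp - alpha * (1.0 - f) * params.cP)

    return np.array([[dGH_da, dGH_db], [dGP_da, dGP_db]])


def _interaction_type(beta: float) -> str:
    if abs(beta) <= COMMENSAL_TOL:
        return "commensalistic"
    return "mutualistic" if beta > 0 else "antagonistic"


def classify_stability(
    fp: FixedPoint, params: ModelParams, tau: float = MARGINALITY_TAU
) -> FixedPoint:
    """Fill in eigenvalues, stability and interaction-type labels.

    Stable iff both eigenvalue real parts < -tau; unstable iff any real part
    > +tau; otherwise marginal (logged as a warning, never silently guessed).
    """
    eig = np.linalg.eigvals(jacobian(fp.state, params))
    re = np.real(eig)
    if np.all(re < -tau):
        stability = "stable"
    elif np.any(re > tau):
        stability = "unstable"
    else:
        stability = "marginal"
        logger.warning(
            "marginal fixed point at (%.6g, %.6g): eigenvalue real parts %s",
            fp.alpha,
            fp.beta,
            re,
        )
    return FixedPoint(
        alpha=fp.alpha,
        beta=fp.beta,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        stability=stability,
        interaction_type=_interaction_type(fp.beta),
    )


# ---------------------------------------------------------------------------
# Fixed-point location
# ---------------------------------------------------------------------------

def _fixed_points_isocline_scan(
    params: ModelParams,
    region: tuple[float, float, float, float],
    n_alpha: int,
) -> list[TraitState]:
    """Roots of G_H along the single-valued partner isocline beta(alpha).

    Exhaustive for interior fixed points at the scan resolution, since every
    fixed point lies on the partner isocline.
    """
    a_lo, a_hi, b_lo, b_hi = region
    alphas = np.linspace(max(a_lo, 1e-3), a_hi, n_alpha)

    def gh_on_isocline(alpha: float) -> float:
        beta = partner_isocline_beta(alpha, params)
        return host_selection_gradient(TraitState(alpha, beta), params)

    values = np.array([gh_on_isocline(a) for a in alphas])
    roots: list[TraitState] = []
    for i in range(len(alphas) - 1):
        if values[i] == 0.0 or values[i] * values[i + 1] < 0:
            a_star = float(
                optimize.brentq(
                    gh_on_isocline, alphas[i], alphas[i + 1], xtol=1e-13
                )
            )
            b_star = partner_isocline_beta(a_star, params)
            if b_lo - 1e-9 <= b_star <= b_hi + 1e-9:
                roots.append(TraitState(a_star, b_star))
    return roots


def _newton_seeds(
    region: tuple[float, float, float, float], grid: tuple[int, int]
) -> np.ndarray:
    a_lo, a_hi, b_lo, b_hi = region
    aa = np.linspace(max(a_lo, 1e-3), a_hi, grid[0])
    bb = np.linspace(b_lo, b_hi, grid[1])
    return np.array([(a, b) for a in aa for b in bb])


def _refine(seed: Sequence[float], params: ModelParams) -> TraitState | None:
    sol = optimize.root(
        gradient_vector,
        x0=np.asarray(seed, dtype=float),
        args=(params,),
        jac=lambda x, p: _gradient_jacobian(TraitState(*x), p),
        method="hybr",
        tol=1e-13,
    )
    if not sol.success:
        return None
    a, b = map(float, sol.x)
    if a <= 0:
        return None
    if np.max(np.abs(gradient_vector((a, b), params))) > ROOT_TOL:
        return None
    return TraitState(a, b)


def find_fixed_points(
    params: ModelParams,
    region: tuple[float, float, float, float] | None = None,
    grid_resolution: tuple[int, int] = (60, 60),
    method: str = "newton",
    classify: bool = True,
) -> list[FixedPoint]:
    """Locate all interior fixed points within ``region``.

    Parameters
    ----------
    region : (alpha_min, alpha_max, beta_min, beta_max); defaults to
        DEFAULT_REGION with the beta ceiling capped at beta_max - 0.01.
    grid_resolution : Newton seed grid (``method="newton"``) or the alpha
        scan resolution ``grid_resolution[0] * grid_resolution[1]`` points
        (``method="isocline"``).
    method : "newton" (multi-start Newton from grid seeds, the default) or
        "isocline" (scan of the host gradient along the partner isocline;
        faster, used internally by parameter sweeps).
    classify : also compute eigenvalues and stability labels.

    Seeds that fail to converge are dropped; candidates are Newton-refined,
    verified (both gradients < 1e-10) and deduplicated (distance 1e-4).
    An empty list is a valid result.
    """
    if region is None:
        region = DEFAULT_REGION
    a_lo, a_hi, b_lo, b_hi = region
    b_hi = min(b_hi, params.beta_max - 0.01)
    region = (a_lo, a_hi, b_lo, b_hi)

    if method == "isocline":
        candidates = _fixed_points_isocline_scan(
            params, region, n_alpha=grid_resolution[0] * grid_resolution[1]
        )
        candidates = [c for c in (_refine(c, params) for c in candidates) if c]
    elif method == "newton":
        candidates = []
        for seed in _newton_seeds(region, grid_resolution):
            cand = _refine(seed, params)
            if cand is not None:
                candidates.append(cand)
    else:
        raise ValueError(f"unknown method {method!r}")

    unique: list[TraitState] = []
    for cand in candidates:
        a, b = cand
        if not (a_lo <= a <= a_hi and b_lo - 1e-9 <= b <= b_hi + 1e-9):
            continue
        if any(math.hypot(a - u.alpha, b - u.beta) < DEDUP_TOL for u in unique):
            continue
        unique.append(cand)
    unique.sort(key=lambda s: (s.beta, s.alpha))

    points = [FixedPoint(alpha=s.alpha, beta=s.beta) for s in unique]
    if classify:
        points = [classify_stability(fp, params) for fp in points]
    return points
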