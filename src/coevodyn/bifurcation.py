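"""Parameter sweeps, saddle-node (fold) location and hysteresis.

As a cost or benefit parameter is varied, the stable and unstable
mutualistic fixed points approach each other, collide and annihilate in a
saddle-node bifurcation — an evolutionary tipping point.  Beyond the fold
only the antagonistic attractor remains, and because the antagonistic
attractor persists on both sides of the fold the transition is hysteretic:
restoring the original parameter value does not restore mutualism.

The fold is located by bisection on the number of mutualistic fixed points
(beta* > 1e-6): counting is cheap and unambiguous in this two-dimensional
system, so no continuation machinery is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import integrate_trajectory
from .equilibria import FixedPoint, find_fixed_points, partner_isocline_beta
from .model import ModelParams

__all__ = [
    "BifurcationBranch",
    "SWEEPABLE",
    "count_mutualistic",
    "sweep_parameter",
    "locate_fold",
    "equivalent_tipping_check",
    "hysteresis_experiment",
]

#: Parameters that may be swept.
SWEEPABLE = ("cP", "cH", "cD", "bP")

#: Default sweep step per parameter.
DEFAULT_STEP = {"cP": 0.005, "cH": 0.005, "cD": 0.005, "bP": 0.05}

#: beta* above which a fixed point counts as mutualistic for fold counting.
MUTUALISTIC_TOL = 1e-6


@dataclass
class BifurcationBranch:
    """Fixed-point families along a one-parameter sweep.

    ``points[k]`` lists the fixed points at ``parameter_values[k]``;
    ``branch_ids[k]`` assigns each of them to a continuity-linked branch.
    ``fold_estimate`` is the parameter value where the mutualistic pair
    merges, if the sweep brackets one.
    """

    swept_parameter: str
    parameter_values: np.ndarray
    points: list[list[FixedPoint]]
    branch_ids: list[list[int]]
    fold_estimate: float | None = None

    def to_dataframe(self) -> "pd.DataFrame":
        import pandas as pd

        rows = [
            (v, fp.alpha, fp.beta, fp.stability, bid)
            for v, fps, bids in zip(self.parameter_values, self.points, self.branch_ids)
            for fp, bid in zip(fps, bids)
        ]
        return pd.DataFrame(
            rows,
            columns=["parameter", "alpha_star", "beta_star", "stability", "branch_id"],
        )


def _check_name(name: str) -> None:
    if name not in SWEEPABLE:
        raise ValueError(f"swept parameter must be one of {SWEEPABLE}, got {name!r}")


def count_mutualistic(params: ModelParams, **find_kwargs) -> int:
    """Number of fixed points with beta* > MUTUALISTIC_TOL."""
    find_kwargs.setdefault("method", "isocline")
    find_kwargs.setdefault("classify", False)
    fps = find_fixed_points(params, **find_kwargs)
    return sum(1 for fp in fps if fp.beta > MUTUALISTIC_TOL)


def sweep_parameter(
    base_params: ModelParams,
    name: str,
    values: Sequence[float] | None = None,
    value_range: tuple[float, float] | None = None,
    step: float | None = None,
) -> BifurcationBranch:
    """Track all fixed points while one parameter varies.

    Fixed points at consecutive parameter values are linked into branches by
    nearest-neighbour matching in trait space.  Disappearance of the
    mutualistic pair terminates those branches (recorded, not an error); the
    midpoint of the bracketing step is stored as ``fold_estimate``.
    """
    _check_name(name)
    if values is None:
        if value_range is None:
            raise ValueError("provide either values or value_range")
        if step is None:
            step = DEFAULT_STEP[name]
        lo, hi = value_range
        values = np.arange(lo, hi + step / 2, step)
    values = np.asarray(sorted(values), dtype=float)

    points: list[list[FixedPoint]] = []
    branch_ids: list[list[int]] = []
    next_branch = 0
    prev: list[tuple[FixedPoint, int]] = []
    fold_estimate: float | None = None

    for k, v in enumerate(values):
        params = base_params.with_(**{name: float(v)})
        fps = find_fixed_points(params, method="isocline")
        ids: list[int] = []
        used: set[int] = set()
        for fp in fps:
            best, best_d = None, math.inf
            for q, (pfp, bid) in enumerate(prev):
                if q in used:
                    continue
                d = math.hypot(fp.alpha - pfp.alpha, fp.beta - pfp.beta)
                if d < best_d:
                    best, best_d = q, d
            # continuity bound: generous multiple of the step's trait drift
            if best is not None and best_d < 1.0:
                ids.append(prev[best][1])
                used.add(best)
            else:
                ids.append(next_branch)
                next_branch += 1
        n_mut_prev = sum(1 for fp, _ in prev if fp.beta > MUTUALISTIC_TOL)
        n_mut = sum(1 for fp in fps if fp.beta > MUTUALISTIC_TOL)
        if k > 0 and n_mut_prev >= 2 and n_mut == 0 and fold_estimate is None:
            fold_estimate = float((values[k - 1] + v) / 2)
        points.append(fps)
        branch_ids.append(ids)
        prev = list(zip(fps, ids))

    return BifurcationBranch(
        swept_parameter=name,
        parameter_values=values,
        points=points,
        branch_ids=branch_ids,
        fold_estimate=fold_estimate,
    )


def locate_fold(
    base_params: ModelParams,
    name: str,
    bracket: tuple[float, float],
    tol: float = 1e-3,
    **count_kwargs,
) -> float:
    """Saddle-node parameter value by bisection on the mutualistic count.

    ``bracket`` must straddle the fold: two mutualistic fixed points on one
    side, zero on the other (in either orientation).

    Raises
    ------
    ValueError
        If both bracket endpoints have the same mutualism status.
    """
    _check_name(name)
    lo, hi = bracket

    def has_mutualism(v: float) -> bool:
        return count_mutualistic(base_params.with_(**{name: float(v)}),
                                 **count_kwargs) >= 1

    m_lo, m_hi = has_mutualism(lo), has_mutualism(hi)
    if m_lo == m_hi:
        raise ValueError(
            f"invalid bracket {bracket} for {name}: mutualistic fixed points "
            f"{'exist' if m_lo else 'are absent'} at both endpoints"
        )
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if has_mutualism(mid) == m_lo:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def equivalent_tipping_check(
    base_params: ModelParams,
    transformed: ModelParams | None = None,
    alphas: Sequence[float] | None = None,
    tol: float = 1e-8,
) -> dict:
    """Verify that parameter changes preserving beta_max preserve the
    partner null-isocline.

    The partner gradient vanishes where ``alpha*(1-f)*(beta_max - beta) = 1``
    (after dividing by cP), so its zero set depends on (bP, cH, cP) only
    through ``beta_max = (1-cH*cP)*bP/cP``.  Raising cH, lowering bP and
    raising cP that keep beta_max fixed therefore shift the isocline — and
    the tipping point it produces — identically.  The check compares sampled
    isoclines pointwise.
    """
    if transformed is None:
        # raise cH by 10% and rescale bP to keep beta_max fixed
        cH2 = base_params.cH * 1.1
        bP2 = (
            base_params.beta_max
            * base_params.cP
            / (1.0 - cH2 * base_params.cP)
        )
        transformed = base_params.with_(cH=cH2, bP=bP2)
    if alphas is None:
        alphas = np.linspace(0.05, 8.0, 160)
    base_iso = np.array([partner_isocline_beta(a, base_params) for a in alphas])
    tr_iso = np.array([partner_isocline_beta(a, transformed) for a in alphas])
    max_dev = float(np.max(np.abs(base_iso - tr_iso)))
    return {
        "beta_max_base": base_params.beta_max,
        "beta_max_transformed": transformed.beta_max,
        "max_isocline_deviation": max_dev,
        "equivalent": max_dev <= tol,
        "tolerance": tol,
    }


def hysteresis_experiment(
    base_params: ModelParams,
    name: str,
    high_value: float,
    t_end: float = 1e6,
    escape_distance: float = 0.5,
) -> dict:
    """Push a parameter past the fold and test for irreversibility.

    Starting at the stable mutualistic attractor of ``base_params``:
    (i) set ``name`` to ``high_value`` and integrate — if the value lies
    beyond the fold the system falls to the antagonistic attractor;
    (ii) restore the base value and integrate from the state reached — after
    a genuine tipping event the system stays in the antagonistic basin
    (distance to the mutualistic attractor remains above
    ``escape_distance``).

    Returns a report dict; ``transition_occurred`` False (with
    ``recovered`` None) is the expected outcome for ``high_value`` below the
    fold (negative control).
    """
    _check_name(name)
    base_fps = find_fixed_points(base_params, method="isocline")
    mut = [
        fp for fp in base_fps
        if fp.stability == "stable" and fp.interaction_type == "mutualistic"
    ]
    if not mut:
        raise ValueError("base parameters admit no stable mutualistic attractor")
    start = mut[0]

    high_params = base_params.with_(**{name: float(high_value)})
    high_fps = find_fixed_points(high_params, method="isocline")
    high_stable = [fp for fp in high_fps if fp.stability == "stable"]
    fwd = integrate_trajectory(
        start.state, high_params, t_end=t_end, attractors=high_stable
    )
    fwd_target = fwd.converged_to
    transition = (
        fwd_target is not None and fwd_target.interaction_type == "antagonistic"
    )

    report = {
        "parameter": name,
        "base_value": getattr(base_params, name),
        "high_value": float(high_value),
        "mutualistic_start": (start.alpha, start.beta),
        "forward_final": tuple(map(float, fwd.final)),
        "transition_occurred": bool(transition),
        "recovered": None,
        "final_distance_to_mutualistic": None,
    }
    if not transition:
        return report

    back_stable = [fp for fp in base_fps if fp.stability == "stable"]
    back = integrate_trajectory(
        fwd.final, base_params, t_end=t_end, attractors=back_stable
    )
    dist_m = start.distance_to(back.final)
    report["back_final"] = tuple(map(float, back.final))
    report["final_distance_to_mutualistic"] = float(dist_m)
    report["recovered"] = bool(dist_m <= escape_distance)
    return report
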