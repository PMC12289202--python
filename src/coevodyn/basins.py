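"""Basins of attraction and transition-pathway censuses.

With two stable attractors — one mutualistic (M, beta* > 0), one
antagonistic (A, beta* < 0) — every initial trait state belongs to the basin
of one of them.  The relative speed of evolution vH/vP reshapes the
trajectories and hence the basin boundary without moving the fixed points.
Three named scenarios are analysed:

* ``fast-partner`` : vH = 0.001, vP = 0.02   (vH/vP = 0.05)
* ``equal``        : vH = 0.02,  vP = 0.02   (vH/vP = 1)
* ``fast-host``    : vH = 0.4,   vP = 0.02   (vH/vP = 20)

``preadaptation_threshold`` quantifies how much initial host discrimination
guarantees that an initially antagonistic partner is driven to stable
mutualism: for each initial beta0 it returns the smallest alpha0 above which
all tested starts converge to M (robust to non-monotone basin boundaries,
which do occur for strongly antagonistic starts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import integrate_trajectory
from .equilibria import FixedPoint, find_fixed_points
from .model import ModelParams, TraitState

__all__ = [
    "BasinGrid",
    "SCENARIOS",
    "MissingAttractorError",
    "stable_attractors",
    "classify_start",
    "classify_basins",
    "preadaptation_threshold",
    "pathway_census",
]

logger = logging.getLogger(__name__)

#: (vH, vP) for the three relative-speed scenarios.
SCENARIOS: dict[str, tuple[float, float]] = {
    "fast-partner": (0.001, 0.02),
    "equal": (0.02, 0.02),
    "fast-host": (0.4, 0.02),
}

#: Default initial-condition grid window and resolution.
DEFAULT_GRID = {"alpha0": (0.0, 4.0), "beta0": (-3.0, 3.0), "n": 81}


class MissingAttractorError(RuntimeError):
    """Basin classification requires both a mutualistic and an antagonistic
    stable attractor."""


@dataclass
class BasinGrid:
    """Attractor and pathway labels over an initial-condition grid.

    ``attractor_label[i, j]`` is the label ("M", "A" or "unresolved") for
    the start (alpha0_values[i], beta0_values[j]); ``pathway_label`` holds
    the transition classification of the same trajectory.
    """

    alpha0_values: np.ndarray
    beta0_values: np.ndarray
    attractor_label: np.ndarray
    pathway_label: np.ndarray
    scenario: tuple[float, float]
    params: ModelParams

    def to_dataframe(self) -> "pd.DataFrame":
        import pandas as pd

        vH, vP = self.scenario
        rows = [
            (a0, b0, vH, vP, self.attractor_label[i, j], self.pathway_label[i, j])
            for i, a0 in enumerate(self.alpha0_values)
            for j, b0 in enumerate(self.beta0_values)
        ]
        return pd.DataFrame(
            rows, columns=["alpha0", "beta0", "vH", "vP", "attractor", "pathway"]
        )

    def lookup(self, alpha: float, beta: float) -> str:
        """Attractor label of the nearest grid cell."""
        i = int(np.argmin(np.abs(self.alpha0_values - alpha)))
        j = int(np.argmin(np.abs(self.beta0_values - beta)))
        return str(self.attractor_label[i, j])


def stable_attractors(params: ModelParams) -> dict[str, FixedPoint]:
    """The mutualistic ("M") and antagonistic ("A") stable attractors.

    Raises
    ------
    MissingAttractorError
        Naming the missing attractor if fewer than two exist (e.g. beyond
        the fold in cP only the antagonistic one survives).
    """
    fps = find_fixed_points(params, method="isocline", grid_resolution=(40, 40))
    out: dict[str, FixedPoint] = {}
    for fp in fps:
        if fp.stability != "stable":
            continue
        if fp.interaction_type == "mutualistic":
            out["M"] = fp
        elif fp.interaction_type == "antagonistic":
            out["A"] = fp
    for name, label in (("mutualistic", "M"), ("antagonistic", "A")):
        if label not in out:
            raise MissingAttractorError(
                f"no stable {name} attractor exists for these parameters"
            )
    return out


def classify_start(
    initial: TraitState,
    params: ModelParams,
    attractors: dict[str, FixedPoint],
    t_end: float = 2e6,
    **integrate_kwargs,
) -> tuple[str, str]:
    """(attractor label, pathway label) for one initial condition."""
    traj = integrate_trajectory(
        initial,
        params,
        t_end=t_end,
        attractors=list(attractors.values()),
        **integrate_kwargs,
    )
    if traj.converged_to is attractors["M"]:
        return "M", traj.pathway_label
    if traj.converged_to is attractors["A"]:
        return "A", traj.pathway_label
    logger.warning("unresolved basin cell at %s (t_end=%g)", tuple(initial), t_end)
    return "unresolved", "unclassified"


def classify_basins(
    params: ModelParams,
    alpha0_values: Sequence[float] | None = None,
    beta0_values: Sequence[float] | None = None,
    t_end: float = 2e6,
    **integrate_kwargs,
) -> BasinGrid:
    """Integrate every grid start and label its basin and pathway.

    Cells whose trajectory hits ``t_end`` without converging are flagged
    "unresolved", never guessed.
    """
    if alpha0_values is None:
        lo, hi = DEFAULT_GRID["alpha0"]
        alpha0_values = np.linspace(lo, hi, DEFAULT_GRID["n"])
    if beta0_values is None:
        lo, hi = DEFAULT_GRID["beta0"]
        beta0_values = np.linspace(lo, hi, DEFAULT_GRID["n"])
    alpha0_values = np.asarray(alpha0_values, dtype=float)
    beta0_values = np.asarray(beta0_values, dtype=float)
    if alpha0_values.size == 0 or beta0_values.size == 0:
        raise ValueError("grid specification is empty")
    if np.any(beta0_values >= params.beta_max):
        raise ValueError("grid contains infeasible starts (beta0 >= beta_max)")

    attractors = stable_attractors(params)
    labels = np.empty((len(alpha0_values), len(beta0_values)), dtype=object)
    pathways = np.empty_like(labels)
    for i, a0 in enumerate(alpha0_values):
        for j, b0 in enumerate(beta0_values):
            labels[i, j], pathways[i, j] = classify_start(
                TraitState(float(a0), float(b0)),
                params,
                attractors,
                t_end=t_end,
                **integrate_kwargs,
            )
    return BasinGrid(
        alpha0_values=alpha0_values,
        beta0_values=beta0_values,
        attractor_label=labels,
        pathway_label=pathways,
        scenario=(params.vH, params.vP),
        params=params,
    )


def preadaptation_threshold(
    params: ModelParams,
    beta0_set: Sequence[float] | None = None,
    alpha_bracket: tuple[float, float] = (0.0, 3.0),
    tol: float = 0.01,
    scan_step: float = 0.1,
    t_end: float = 2e6,
) -> dict:
    """Initial discrimination guaranteeing convergence to mutualism.

    For each beta0, starts on an alpha0 scan grid are classified; the
    per-beta0 threshold is the basin boundary refined by bisection above the
    *largest* antagonistic-labelled alpha0 (so the returned value guarantees
    M even when the boundary is non-monotone, in which case the ambiguity is
    reported in ``non_monotone``).  Returns a dict with ``per_beta0``
    thresholds, ``threshold`` (their maximum) and ``non_monotone`` flags.

    Raises
    ------
    ValueError
        If for some beta0 both bracket ends lie in the same basin (no
        boundary to bisect and the start is not all-M).
    """
    if beta0_set is None:
        beta0_set = [-3.0, -2.5, -2.0, -1.5, -1.0, -0.5]
    attractors = stable_attractors(params)
    lo_a, hi_a = alpha_bracket
    per_beta0: dict[float, float] = {}
    non_monotone: dict[float, bool] = {}

    for b0 in beta0_set:
        grid = np.arange(lo_a, hi_a + scan_step / 2, scan_step)
        labels = [
            classify_start(TraitState(float(a0), float(b0)), params, attractors,
                           t_end=t_end)[0]
            for a0 in grid
        ]
        if labels[-1] != "M":
            raise ValueError(
                f"alpha_bracket upper end {hi_a} does not reach the "
                f"mutualistic basin at beta0={b0}"
            )
        a_idx = [k for k, lab in enumerate(labels) if lab == "A"]
        if not a_idx:
            per_beta0[float(b0)] = 0.0
            non_monotone[float(b0)] = False
            continue
        last_a = a_idx[-1]
        non_monotone[float(b0)] = labels[: last_a + 1].count("M") > 0
        lo, hi = float(grid[last_a]), float(grid[last_a + 1])
        while hi - lo > tol:
            mid = (lo + hi) / 2
            lab = classify_start(
                TraitState(mid, float(b0)), params, attractors, t_end=t_end
            )[0]
            if lab == "M":
                hi = mid
            else:
                lo = mid
        per_beta0[float(b0)] = (lo + hi) / 2

    return {
        "per_beta0": per_beta0,
        "threshold": max(per_beta0.values()),
        "non_monotone": non_monotone,
        "scenario": (params.vH, params.vP),
    }


def pathway_census(grid: BasinGrid) -> dict:
    """Tabulate pathway labels over a resolved basin grid.

    Returns counts per label plus the fraction of cells on each pathway
    (back-and-forth transitions are typically a narrow window of starts).
    """
    flat = [str(x) for x in grid.pathway_label.ravel()]
    n = len(flat)
    counts: dict[str, int] = {}
    for lab in flat:
        counts[lab] = counts.get(lab, 0) + 1
    fractions = {lab: c / n for lab, c in counts.items()}
    return {"counts": counts, "fractions": fractions, "n_cells": n}
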