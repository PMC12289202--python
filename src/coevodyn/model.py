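"""Core model: interaction frequency, fitness effects and selection gradients.

Two species interact: a *host* carrying a discrimination-ability trait
``alpha`` (how strongly interaction frequency tracks partner quality) and a
*partner* carrying the trait ``beta``, the net fitness effect of one realized
interaction on the host ("partner effect").  ``beta > 0`` is mutualism,
``beta < 0`` antagonism, ``beta = 0`` commensalism.

Per-capita interaction fitness:

    f(alpha, beta) = 1 / (1 + exp(-alpha * beta))        interaction frequency
    wH = f * beta - cD * alpha                           host
    wP = f * ((1 - cP*cH) * bP - cP * beta)              partner

Selection gradients (partial derivative of a species' fitness in its own
trait) drive the coupled trait dynamics; they are implemented analytically:

    G_H = d wH / d alpha = beta^2 * f * (1 - f) - cD
    G_P = d wP / d beta  = f * (alpha * (1 - f) * wP_hat - cP)

with ``wP_hat = (1 - cP*cH)*bP - cP*beta`` the partner's net gain from one
interaction.  All functions in this module are pure and side-effect free;
they are the single source of truth for the model's mathematics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "ModelParams",
    "TraitState",
    "FeasibilityError",
    "sigmoid",
    "interaction_frequency",
    "partner_hat_fitness",
    "host_fitness",
    "partner_fitness",
    "host_selection_gradient",
    "partner_selection_gradient",
    "is_feasible",
    "validate_state",
    "BASELINE",
]


class FeasibilityError(ValueError):
    """Raised when a trait state violates the partner-viability bound."""


@dataclass(frozen=True)
class ModelParams:
    """Model constants.

    Defaults are the baseline parameterization used throughout the analysis.

    Attributes
    ----------
    bP : benefit to the partner provided by the host per interaction (>= 0).
    cH : host cost factor per unit of service provided (dimensionless, >= 0).
    cP : partner cost factor per unit of service provided (> 0).
    cD : host cost per unit of discrimination ability (>= 0).
    vH : speed of host adaptation (additive genetic variance / generation
         time, >= 0).
    vP : speed of partner adaptation (>= 0).
    """

    bP: float = 5.0
    cH: float = 0.6
    cP: float = 0.6
    cD: float = 0.1
    vH: float = 0.02
    vP: float = 0.02

    def __post_init__(self) -> None:
        for name in ("bP", "cH", "cP", "cD", "vH", "vP"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")
        if self.cP == 0:
            raise ValueError("cP must be strictly positive")

    @property
    def beta_max(self) -> float:
        """Upper bound on beta keeping the interaction beneficial for the
        partner (wP_hat > 0): ``(1 - cH*cP) * bP / cP``."""
        return (1.0 - self.cH * self.cP) * self.bP / self.cP

    def with_(self, **kwargs: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: Baseline parameter set (standard values).
BASELINE = ModelParams()


class TraitState(NamedTuple):
    """A point in trait space: (host discrimination alpha, partner effect beta)."""

    alpha: float
    beta: float


def sigmoid(u: float) -> float:
    """Numerically stable logistic function 1/(1+exp(-u)).

    Evaluates exp only at negative arguments, so it never overflows
    regardless of |u|.
    """
    if u >= 0:
        return 1.0 / (1.0 + math.exp(-u))
    e = math.exp(u)
    return e / (1.0 + e)


def interaction_frequency(state: TraitState) -> float:
    """Interaction frequency f(alpha, beta) = sigmoid(alpha * beta) in (0, 1)."""
    alpha, beta = state
    return sigmoid(alpha * beta)


def partner_hat_fitness(beta: float, params: ModelParams) -> float:
    """Net effect of one realized interaction on the partner:
    ``wP_hat = (1 - cP*cH)*bP - cP*beta``.

    Linear and strictly decreasing in beta; positive iff beta < beta_max.
    """
    return (1.0 - params.cP * params.cH) * params.bP - params.cP * beta


def host_fitness(state: TraitState, params: ModelParams) -> float:
    """Host per-capita interaction fitness wH = f*beta - cD*alpha."""
    alpha, beta = state
    return sigmoid(alpha * beta) * beta - params.cD * alpha


def partner_fitness(state: TraitState, params: ModelParams) -> float:
    """Partner per-capita interaction fitness wP = f * wP_hat.

    Raises
    ------
    FeasibilityError
        If ``beta >= beta_max`` (the partner would lose from interacting,
        outside the model's domain of analysis).
    """
    alpha, beta = state
    if beta >= params.beta_max:
        raise FeasibilityError(
            f"beta={beta} violates the partner-viability bound "
            f"beta < beta_max={params.beta_max}"
        )
    return sigmoid(alpha * beta) * partner_hat_fitness(beta, params)


def host_selection_gradient(state: TraitState, params: ModelParams) -> float:
    """d wH / d alpha = beta^2 * f * (1-f) - cD."""
    alpha, beta = state
    f = sigmoid(alpha * beta)
    return beta * beta * f * (1.0 - f) - params.cD


def partner_selection_gradient(state: TraitState, params: ModelParams) -> float:
    """d wP / d beta = f * (alpha * (1-f) * wP_hat - cP).

    Strictly negative whenever alpha = 0 (a non-discriminating host never
    selects for mutualistic service).
    """
    alpha, beta = state
    f = sigmoid(alpha * beta)
    return f * (alpha * (1.0 - f) * partner_hat_fitness(beta, params) - params.cP)


def is_feasible(state: TraitState, params: ModelParams) -> bool:
    """True iff alpha >= 0 and beta < beta_max (wP_hat > 0)."""
    alpha, beta = state
    return alpha >= 0.0 and beta < params.beta_max


def validate_state(state: TraitState, params: ModelParams) -> TraitState:
    """Return ``state`` unchanged, raising if it is infeasible."""
    alpha, beta = state
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    if beta >= params.beta_max:
        raise FeasibilityError(
            f"beta={beta} >= beta_max={params.beta_max}: partner fitness "
            "effect would be non-positive"
        )
    return TraitState(alpha, beta)
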