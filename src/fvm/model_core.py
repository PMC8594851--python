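"""Pure mathematics of the force vector model of social influence.

Each agent is a vector in a continuous attribute space of dimension ``d``
(two by default).  The direction of the vector — the agent's *attribute
orientation* — determines the sign of its interaction with every other
agent: agents whose vectors subtend less than 90 degrees attract, agents
subtending more than 90 degrees repel.  The magnitude of the interaction
falls off as an inverse power of the attribute distance between the two
agents, in analogy with gravity and electrostatics, and is cut off
entirely beyond a confidence bound, the Attribute Influence Bound (AIB).

The force exerted by agent A on agent B is

    F_AonB = g * m_A * (A . B) / R**p * (R_vec / R)

where ``R_vec = A - B``, ``R`` is the (optionally metric-weighted)
distance between the agents, ``m_A`` is A's *active mass* (charisma:
how strongly A influences others), ``g`` a global force-scaling
constant and ``p`` the distance exponent (2 by default).  B responds to
the net force in inverse proportion to its *passive mass* M_B
(stubbornness); see :func:`displacement`.

This module is pure computation: no simulation state, no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ForceMode",
    "ModelParams",
    "AgentState",
    "PairInteraction",
    "attribute_distance",
    "pair_force",
    "net_force",
    "displacement",
]


class ForceMode(str, Enum):
    """Post-processing applied to the scalar force prefactor.

    NORMAL           sign follows the dot product (attract / repel).
    ATTRACT_ONLY     prefactor replaced by its absolute value.
    REPEL_ONLY       prefactor replaced by minus its absolute value.
    ZERO_REPULSIVE   negative-dot (repulsive) pairs are zeroed.
    ZERO_ATTRACTIVE  positive-dot (attractive) pairs are zeroed.
    INVERT           sign of the prefactor flipped.
    """

    NORMAL = "NORMAL"
    ATTRACT_ONLY = "ATTRACT_ONLY"
    REPEL_ONLY = "REPEL_ONLY"
    ZERO_REPULSIVE = "ZERO_REPULSIVE"
    ZERO_ATTRACTIVE = "ZERO_ATTRACTIVE"
    INVERT = "INVERT"


@dataclass(frozen=True)
class ModelParams:
    """Force-law constants and global model geometry.

    Parameters
    ----------
    g
        Global force scaling constant.  Under adaptive time stepping the
        trajectories are independent of ``g``; only elapsed time rescales.
    metric_weights
        Per-axis weights in the attribute distance (all 1 by default, the
        plain Euclidean metric).
    distance_exponent
        Power ``p`` of the distance in the force denominator.
    aib
        Attribute Influence Bound: agents farther apart than this cannot
        interact at all.
    coalescence_radius
        Distance below which agents merge permanently into a group; also
        the cap on any per-iteration displacement under adaptive stepping.
    force_mode
        See :class:`ForceMode`.
    dimension
        Dimensionality ``d`` of attribute space (>= 2).
    visible_half_width
        Half-width of the visible window per axis.  Initial positions are
        confined to it; during a run positions are unbounded (agents that
        leave it are "ghosts" and keep interacting normally).
    """

    g: float = 7.0e-5
    metric_weights: tuple[float, ...] | None = None
    distance_exponent: float = 2.0
    aib: float = 280.0
    coalescence_radius: float = 0.2
    force_mode: ForceMode = ForceMode.NORMAL
    dimension: int = 2
    visible_half_width: float = 100.0

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("g must be positive")
        if self.distance_exponent <= 0:
            raise ValueError("distance_exponent must be positive")
        if self.aib <= 0:
            raise ValueError("aib must be positive")
        if self.coalescence_radius <= 0:
            raise ValueError("coalescence_radius must be positive")
        if not self.coalescence_radius < self.aib:
            raise ValueError("coalescence_radius must be smaller than aib")
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.visible_half_width <= 0:
            raise ValueError("visible_half_width must be positive")
        if self.metric_weights is not None:
            w = tuple(float(x) for x in self.metric_weights)
            if len(w) != self.dimension:
                raise ValueError("metric_weights length must equal dimension")
            if any(x <= 0 for x in w):
                raise ValueError("metric_weights must all be positive")
            object.__setattr__(self, "metric_weights", w)
        if not isinstance(self.force_mode, ForceMode):
            object.__setattr__(self, "force_mode", ForceMode(self.force_mode))

    @property
    def weights_array(self) -> np.ndarray:
        if self.metric_weights is None:
            return np.ones(self.dimension)
        return np.asarray(self.metric_weights, dtype=float)

    @property
    def unit_weights(self) -> bool:
        return self.metric_weights is None or all(
            x == 1.0 for x in self.metric_weights
        )


@dataclass
class AgentState:
    """One live agent: an unmerged individual or a merged group.

    ``member_ids`` records the original ids absorbed into this agent;
    across a live population the member sets partition the original id
    set.  ``active_mass`` scales the force the agent exerts,
    ``passive_mass`` divides the force it receives.  Positions are in
    model units; the visible window is ``[-100, 100]`` per axis but
    values are unbounded.
    """

    id: int
    position: np.ndarray
    active_mass: float
    passive_mass: float
    member_ids: frozenset[int] = field(default=None)  # type: ignore[assignment]
    is_group: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.active_mass <= 0 or self.passive_mass <= 0:
            raise ValueError("masses must be positive")
        if self.member_ids is None:
            self.member_ids = frozenset([self.id])
        else:
            self.member_ids = frozenset(self.member_ids)
        if not self.member_ids:
            raise ValueError("member_ids must be non-empty")
        self.is_group = len(self.member_ids) > 1

    def out_of_visible(self, params: ModelParams) -> bool:
        """True when the agent has left the visible window (a "ghost")."""
        return bool(np.any(np.abs(self.position) > params.visible_half_width))


@dataclass(frozen=True)
class PairInteraction:
    """Fully resolved interaction of one ordered agent pair (A acting on B)."""

    r_vec: np.ndarray
    r_mag: float
    dot: float
    omega: float
    force_on_b: np.ndarray
    sign: str  # 'attractive' | 'repulsive' | 'zero' | 'blocked'


def attribute_distance(
    pos_a: Sequence[float] | np.ndarray,
    pos_b: Sequence[float] | np.ndarray,
    params: ModelParams,
) -> float:
    """Metric-weighted distance between two attribute vectors.

    ``sqrt(sum_k w_k (a_k - b_k)**2)``; the plain Euclidean distance for
    unit weights.
    """
    a = np.asarray(pos_a, dtype=float)
    b = np.asarray(pos_b, dtype=float)
    if a.shape != (params.dimension,) or b.shape != (params.dimension,):
        raise ValueError(
            f"position vectors must have dimension {params.dimension}"
        )
    d = a - b
    return float(math.sqrt(float(np.dot(params.weights_array, d * d))))


def _mode_adjust(scalar: float, dot: float, mode: ForceMode) -> float:
    if mode is ForceMode.NORMAL:
        return scalar
    if mode is ForceMode.ATTRACT_ONLY:
        return abs(scalar)
    if mode is ForceMode.REPEL_ONLY:
        return -abs(scalar)
    if mode is ForceMode.ZERO_REPULSIVE:
        return scalar if dot > 0 else 0.0
    if mode is ForceMode.ZERO_ATTRACTIVE:
        return scalar if dot < 0 else 0.0
    if mode is ForceMode.INVERT:
        return -scalar
    raise ValueError(f"unknown force mode {mode!r}")


def pair_force(a: AgentState, b: AgentState, params: ModelParams) -> PairInteraction:
    """Force exerted by agent ``a`` on agent ``b``.

    The force is ``g * m_A * (A.B) / R**p`` along the unit vector from B
    toward A, so positive dot products pull B toward A and negative ones
    push it away.  Pairs farther apart than the AIB are blocked (zero
    force); a zero dot product gives exactly zero force (no epsilon band
    around 90 degrees).  Coincident distinct agents are degenerate — the
    force is undefined there and returned as zero with sign ``'zero'``;
    the caller is expected to merge them.
    """
    if a.id == b.id:
        raise ValueError("pair_force requires two distinct agents")
    r_vec = a.position - b.position
    r_mag = attribute_distance(a.position, b.position, params)
    dot = float(np.dot(a.position, b.position))
    mag_a = float(np.linalg.norm(a.position))
    mag_b = float(np.linalg.norm(b.position))
    if mag_a > 0 and mag_b > 0:
        omega = math.degrees(math.acos(max(-1.0, min(1.0, dot / (mag_a * mag_b)))))
    else:
        omega = float("nan")
    zero = np.zeros(params.dimension)

    if r_mag > params.aib:
        return PairInteraction(r_vec, r_mag, dot, omega, zero, "blocked")
    if r_mag == 0.0:
        return PairInteraction(r_vec, r_mag, dot, omega, zero, "zero")

    scalar = params.g * a.active_mass * dot / r_mag**params.distance_exponent
    scalar = _mode_adjust(scalar, dot, params.force_mode)
    if scalar == 0.0:
        return PairInteraction(r_vec, r_mag, dot, omega, zero, "zero")
    force = scalar * (r_vec / r_mag)
    sign = "attractive" if scalar > 0 else "repulsive"
    return PairInteraction(r_vec, r_mag, dot, omega, force, sign)


def net_force(
    index: int, population: Sequence[AgentState], params: ModelParams
) -> np.ndarray:
    """Vector sum of the forces on agent ``index`` from all other agents."""
    receiver = None
    for agent in population:
        if agent.id == index:
            receiver = agent
            break
    if receiver is None:
        raise ValueError(f"no live agent with id {index}")
    total = np.zeros(params.dimension)
    for other in population:
        if other.id == receiver.id:
            continue
        total += pair_force(other, receiver, params).force_on_b
    return total


def displacement(
    force: np.ndarray, passive_mass: float, dt: float
) -> np.ndarray:
    """Attribute change of an agent under ``force`` over one time step.

    ``(force / passive_mass) * dt**2`` — the model's single integration
    step of Newton's law (the conventional 1/2 factor is deliberately
    absorbed into ``g``): linear in the force, quadratic in the step.
    """
    if passive_mass <= 0:
        raise ValueError("passive_mass must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.asarray(force, dtype=float) / passive_mass * dt**2
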