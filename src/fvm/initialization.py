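"""Initial populations: spatial/mass samplers, geometry presets, injection.

Agents start inside the visible window ([-100, 100] per axis by
default).  Coordinates and masses are drawn per-axis from uniform,
normal or exponential laws with *rejection*: a draw outside the visible
range (or a mass above the cap or non-positive) is discarded and
redrawn, and the number of rejected draws is reported.  All randomness
flows from a single integer seed, so the same spec and seed always
reproduce the identical population.

The "Standard Conditions" used throughout the baseline experiments are
100 agents, normal(0, 30) on both axes, masses normal(60, 15) capped at
120 with active mass equal to passive mass, CR = 0.2, g = 7e-5,
inverse-square force, adaptive stepping on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model_core import AgentState, ModelParams

__all__ = [
    "DistSpec",
    "Injection",
    "SquareGeometry",
    "TriangleGeometry",
    "RingGeometry",
    "InitSpec",
    "standard_spec",
    "sample_positions",
    "sample_masses",
    "geometry_preset",
    "inject_agent",
    "initial_population",
    "build_population",
]

#: draws allowed per coordinate/mass before declaring the spec infeasible
REJECTION_BUDGET = 1_000_000


class SamplingFailure(RuntimeError):
    """A distribution spec could not place a draw inside its bounds."""


@dataclass(frozen=True)
class DistSpec:
    """One scalar distribution: 'uniform', 'normal' or 'exponential'.

    uniform      over the full allowed range (no parameters).
    normal       mean, sd (sd = 0 degenerates to a point mass).
    exponential  one-sided from ``offset`` (the lower edge of the range
                 when omitted) with the given rate.
    """

    kind: str
    mean: float = 0.0
    sd: float = 0.0
    rate: float = 1.0
    offset: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "normal", "exponential"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "normal" and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.kind == "exponential" and self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass(frozen=True)
class Injection:
    """A manually placed agent."""

    position: tuple[float, ...]
    active_mass: float
    passive_mass: float

    def __post_init__(self) -> None:
        if self.active_mass <= 0 or self.passive_mass <= 0:
            raise ValueError("injected masses must be positive")


@dataclass(frozen=True)
class SquareGeometry:
    """Four agents on the corners of a square centered on the origin."""

    circumradius: float
    rotation: float = 0.0  # degrees


@dataclass(frozen=True)
class TriangleGeometry:
    """Three agents on an equilateral triangle centered on the origin."""

    circumradius: float
    rotation: float = 0.0


@dataclass(frozen=True)
class RingGeometry:
    """k agents equally spaced on a circle about the origin."""

    k: int
    radius: float
    rotation: float = 0.0


GeometryPreset = SquareGeometry | TriangleGeometry | RingGeometry


@dataclass(frozen=True)
class InitSpec:
    """Full recipe for an initial population.

    ``spatial`` holds one :class:`DistSpec` per axis (a single entry is
    replicated across axes).  ``seed`` = 0 means "draw a fresh seed"
    (the engine records the one it used).  When ``geometry`` is set the
    sampled positions are replaced by the preset's exact coordinates and
    ``n_agents`` is ignored in favor of the preset size.
    """

    n_agents: int = 100
    spatial: tuple[DistSpec, ...] = (DistSpec("normal", mean=0.0, sd=30.0),)
    mass: DistSpec = DistSpec("normal", mean=60.0, sd=15.0)
    max_mass: float = 120.0
    equal_masses: bool = True
    seed: int = 0
    injections: tuple[Injection, ...] = ()
    geometry: Optional[GeometryPreset] = None

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.max_mass <= 0:
            raise ValueError("max_mass must be positive")
        if isinstance(self.spatial, DistSpec):
            object.__setattr__(self, "spatial", (self.spatial,))
        else:
            object.__setattr__(self, "spatial", tuple(self.spatial))
        object.__setattr__(self, "injections", tuple(self.injections))

    def axis_dists(self, dimension: int) -> tuple[DistSpec, ...]:
        if len(self.spatial) == 1:
            return self.spatial * dimension
        if len(self.spatial) != dimension:
            raise ValueError(
                f"spatial has {len(self.spatial)} axes, model has {dimension}"
            )
        return self.spatial


def standard_spec(seed: int = 0, n_agents: int = 100, **overrides) -> InitSpec:
    """The Standard Conditions initial spec (see module docstring)."""
    return InitSpec(
        n_agents=n_agents,
        spatial=(DistSpec("normal", mean=0.0, sd=30.0),),
        mass=DistSpec("normal", mean=60.0, sd=15.0),
        max_mass=120.0,
        equal_masses=True,
        seed=seed,
        **overrides,
    )


def _draw_bounded(dist: DistSpec, lo: float, hi: float, rng) -> tuple[float, int]:
    """One accepted draw from ``dist`` inside [lo, hi], plus rejections."""
    rejected = 0
    for _ in range(REJECTION_BUDGET):
        if dist.kind == "uniform":
            x = rng.uniform(lo, hi)
        elif dist.kind == "normal":
            x = dist.mean + dist.sd * rng.standard_normal() if dist.sd > 0 else dist.mean
        else:  # exponential
            base = lo if dist.offset is None else dist.offset
            x = base + rng.exponential(1.0 / dist.rate)
        if lo <= x <= hi:
            return float(x), rejected
        rejected += 1
        if dist.kind == "normal" and dist.sd == 0:
            break  # point mass outside the range can never succeed
    raise SamplingFailure(
        f"could not draw from {dist} inside [{lo}, {hi}] "
        f"within {REJECTION_BUDGET} attempts"
    )


def sample_positions(
    spec: InitSpec, rng, params: ModelParams | None = None
) -> tuple[np.ndarray, int]:
    """Sample ``n_agents`` positions inside the visible window.

    Draws agent-by-agent, axis-by-axis; each coordinate is rejected and
    redrawn until it lands in ``[-visible_half_width, visible_half_width]``.
    Returns the (n, d) position array and the count of rejected draws.
    """
    params = params or ModelParams()
    hw = params.visible_half_width
    dists = spec.axis_dists(params.dimension)
    positions = np.empty((spec.n_agents, params.dimension))
    rejected = 0
    for i in range(spec.n_agents):
        for k, dist in enumerate(dists):
            x, rej = _draw_bounded(dist, -hw, hw, rng)
            positions[i, k] = x
            rejected += rej
    return positions, rejected


def sample_masses(spec: InitSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample positive masses, each at most ``max_mass``.

    Draws above the cap (or non-positive — masses must be positive) are
    rejected and redrawn.  With ``equal_masses`` the passive masses are
    the same array as the active ones.
    """
    mass_lo = np.nextafter(0.0, 1.0)  # masses are strictly positive
    active = np.empty(spec.n_agents)
    passive = np.empty(spec.n_agents)
    for i in range(spec.n_agents):
        active[i], _ = _draw_bounded(spec.mass, mass_lo, spec.max_mass, rng)
        if not spec.equal_masses:
            passive[i], _ = _draw_bounded(spec.mass, mass_lo, spec.max_mass, rng)
    if spec.equal_masses:
        passive = active.copy()
    return active, passive


def geometry_preset(
    preset: GeometryPreset, params: ModelParams | None = None
) -> np.ndarray:
    """Exact symmetric coordinates for a geometry preset (d = 2).

    Square: 4 points at the circumradius, at rotation + {45, 135, 225,
    315} degrees.  Triangle: 3 points at rotation + {90, 210, 330}.
    Ring(k, r): k equally spaced points starting at the rotation angle.
    """
    if isinstance(preset, SquareGeometry):
        angles = preset.rotation + np.array([45.0, 135.0, 225.0, 315.0])
        radius = preset.circumradius
    elif isinstance(preset, TriangleGeometry):
        angles = preset.rotation + np.array([90.0, 210.0, 330.0])
        radius = preset.circumradius
    elif isinstance(preset, RingGeometry):
        if preset.k < 2:
            raise ValueError("ring preset needs k >= 2")
        angles = preset.rotation + np.arange(preset.k) * (360.0 / preset.k)
        radius = preset.radius
    else:
        raise ValueError(f"unknown geometry preset {preset!r}")
    theta = np.deg2rad(angles)
    return radius * np.column_stack([np.cos(theta), np.sin(theta)])


def inject_agent(
    population: list[AgentState],
    position: Sequence[float],
    active_mass: float,
    passive_mass: float,
) -> list[AgentState]:
    """Append one manually placed agent with a fresh id."""
    if active_mass <= 0 or passive_mass <= 0:
        raise ValueError("injected masses must be positive")
    next_id = max((a.id for a in population), default=-1) + 1
    extended = list(population)
    extended.append(
        AgentState(
            id=next_id,
            position=np.asarray(position, dtype=float),
            active_mass=float(active_mass),
            passive_mass=float(passive_mass),
        )
    )
    return extended


def initial_population(
    spec: InitSpec, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Build the full initial arrays (positions, active, passive, ids).

    Draw order is fixed — all positions agent-by-agent (x then y then
    higher axes), then all masses agent-by-agent — so a seed pins the
    whole stream.  Geometry presets replace the sampled positions;
    injections are appended after the sampled agents with fresh ids.
    """
    rng = np.random.default_rng(spec.seed if spec.seed != 0 else None)
    rejected = 0
    if spec.geometry is not None:
        if params.dimension != 2:
            raise ValueError("geometry presets are defined for d=2 only")
        positions = geometry_preset(spec.geometry, params)
        spec = replace(spec, n_agents=len(positions))
    else:
        positions, rejected = sample_positions(spec, rng, params)
    active, passive = sample_masses(spec, rng)
    for inj in spec.injections:
        p = np.asarray(inj.position, dtype=float)
        if p.shape != (params.dimension,):
            raise ValueError("injection position has wrong dimension")
        positions = np.vstack([positions, p[None, :]])
        active = np.append(active, inj.active_mass)
        passive = np.append(passive, inj.passive_mass)
    ids = np.arange(len(positions), dtype=np.int64)
    return positions, active, passive, ids, rejected


def build_population(spec: InitSpec, params: ModelParams) -> list[AgentState]:
    """Initial population as a list of :class:`AgentState`."""
    pos, m, M, ids, _ = initial_population(spec, params)
    return [
        AgentState(
            id=int(ids[i]),
            position=pos[i],
            active_mass=float(m[i]),
            passive_mass=float(M[i]),
        )
        for i in range(len(pos))
    ]
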