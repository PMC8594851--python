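"""Monitored observables over a population or a finished run.

All distance-based metrics use the model's (metric-weighted) attribute
distance; angular metrics are defined for two-dimensional attribute
space and exclude agents sitting exactly on the origin (whose polar
angle is undefined — they are also dynamically inert).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import _net_forces, _pairwise
from .model_core import AgentState, ModelParams

__all__ = [
    "MetricsSnapshot",
    "center_of_attributes",
    "mdcn",
    "mean_pairwise_distance",
    "mean_distance_to_origin",
    "sector_histogram",
    "adjacent_angle_gaps",
    "minor_angle",
    "force_decomposition",
    "moment_of_inertia",
    "annular_histogram",
    "mass_histogram",
    "snapshot",
    "write_snapshot_csv",
]


class UndefinedMetric(ValueError):
    """Raised when a metric needs more agents than the population has."""


def _positions(population: Sequence[AgentState]) -> np.ndarray:
    return np.array([a.position for a in population], dtype=float)


def _active(population: Sequence[AgentState]) -> np.ndarray:
    return np.array([a.active_mass for a in population], dtype=float)


@dataclass(frozen=True)
class MetricsSnapshot:
    center_of_attributes: np.ndarray
    mdcn: float
    mean_pairwise: float
    mean_dist_origin: float
    sector_hist: np.ndarray | None
    annular_hist: np.ndarray
    mass_hist: np.ndarray
    moment_of_inertia: float
    sum_attractive: float
    sum_repulsive: float
    repulsive_pct: float


def center_of_attributes(population: Sequence[AgentState]) -> np.ndarray:
    """Active-mass-weighted mean attribute vector.

    Approximately conserved over a run: pair forces are asymmetric in the
    masses, so the conservation is statistical rather than exact.
    """
    if not len(population):
        raise UndefinedMetric("center_of_attributes needs >= 1 agent")
    m = _active(population)
    return (m[:, None] * _positions(population)).sum(axis=0) / m.sum()


def _dist_matrix(population, params: ModelParams) -> np.ndarray:
    _, r = _pairwise(_positions(population), params)
    return r  # diagonal is +inf


def mdcn(population: Sequence[AgentState], params: ModelParams) -> float:
    """Mean distance to closest neighbor."""
    if len(population) < 2:
        raise UndefinedMetric("mdcn needs >= 2 agents")
    return float(_dist_matrix(population, params).min(axis=1).mean())


def mean_pairwise_distance(
    population: Sequence[AgentState], params: ModelParams
) -> float:
    """Mean attribute distance over all agent pairs."""
    n = len(population)
    if n < 2:
        raise UndefinedMetric("mean_pairwise_distance needs >= 2 agents")
    r = _dist_matrix(population, params)
    return float(r[np.isfinite(r)].sum() / (n * (n - 1)))


def mean_distance_to_origin(population: Sequence[AgentState]) -> float:
    if not len(population):
        raise UndefinedMetric("mean_distance_to_origin needs >= 1 agent")
    return float(np.linalg.norm(_positions(population), axis=1).mean())


def _angles_deg(positions: np.ndarray) -> np.ndarray:
    """Polar angles in [0, 360) of all off-origin rows."""
    norms = np.linalg.norm(positions, axis=1)
    off = positions[norms > 0]
    return np.degrees(np.arctan2(off[:, 1], off[:, 0])) % 360.0


def sector_histogram(
    population_or_positions, n_sectors: int = 12
) -> np.ndarray:
    """Normalized angular histogram (d = 2).

    Sector 0 spans [0, 360/n_sectors) degrees counterclockwise from the
    +x axis; bins are half-open.  Counts are divided by total/n_sectors,
    so a uniform angular law gives 1.0 per sector in expectation and the
    mean over sectors is exactly 1.  Agents at the exact origin are
    excluded.
    """
    if isinstance(population_or_positions, np.ndarray):
        positions = population_or_positions
    else:
        positions = _positions(population_or_positions)
    angles = _angles_deg(positions)
    if len(angles) == 0:
        raise UndefinedMetric("sector_histogram needs off-origin agents")
    # snap angles an epsilon below a boundary upward, so exact symmetric
    # arrangements (whose atan2 angles carry ~1e-14 deg of rounding) bin
    # deterministically
    idx = np.floor((angles + 1e-9) / (360.0 / n_sectors)).astype(int) % n_sectors
    counts = np.bincount(idx, minlength=n_sectors).astype(float)
    return counts / (len(angles) / n_sectors)


def adjacent_angle_gaps(population_or_positions) -> np.ndarray:
    """Angular gaps (degrees) between adjacent agents around the origin.

    Agents are sorted by polar angle; consecutive differences including
    the wrap-around gap are returned, so the gaps sum to 360 exactly.
    For two agents this yields the minor and major angle between them.
    """
    if isinstance(population_or_positions, np.ndarray):
        positions = population_or_positions
    else:
        positions = _positions(population_or_positions)
    angles = np.sort(_angles_deg(positions))
    if len(angles) < 2:
        raise UndefinedMetric("adjacent_angle_gaps needs >= 2 off-origin agents")
    gaps = np.diff(angles, append=angles[0] + 360.0)
    return gaps


def minor_angle(population_or_positions) -> float:
    """Minor angle (<= 180 degrees) between exactly two agents."""
    gaps = adjacent_angle_gaps(population_or_positions)
    if len(gaps) != 2:
        raise UndefinedMetric("minor_angle is defined for exactly 2 agents")
    return float(gaps.min())


def force_decomposition(
    population: Sequence[AgentState], params: ModelParams
) -> tuple[float, float, float]:
    """(sum_attractive, sum_repulsive, repulsive_pct).

    Sums of pairwise force magnitudes over communicating directed pairs,
    classified by the sign of the scalar prefactor; the percentage is
    100 * repulsive / total, or 0 when no forces act.
    """
    if len(population) < 2:
        return 0.0, 0.0, 0.0
    pos = _positions(population)
    m = _active(population)
    _, sum_att, sum_rep, _, _ = _net_forces(pos, m, params)
    total = sum_att + sum_rep
    pct = 100.0 * sum_rep / total if total > 0 else 0.0
    return sum_att, sum_rep, pct


def moment_of_inertia(population: Sequence[AgentState]) -> float:
    """Sum of passive mass times squared Euclidean distance to origin."""
    if not len(population):
        return 0.0
    M = np.array([a.passive_mass for a in population])
    r2 = (_positions(population) ** 2).sum(axis=1)
    return float((M * r2).sum())


def annular_histogram(
    population: Sequence[AgentState], bin_width: float = 5.0
) -> np.ndarray:
    """Counts of agents binned by Euclidean distance to the origin."""
    r = np.linalg.norm(_positions(population), axis=1)
    n_bins = int(np.floor(r.max() / bin_width)) + 1 if len(r) else 1
    return np.bincount(
        np.floor(r / bin_width).astype(int), minlength=n_bins
    ).astype(float)


def mass_histogram(
    population: Sequence[AgentState], bin_width: float = 10.0
) -> np.ndarray:
    """Counts of agents binned by active mass."""
    m = _active(population)
    n_bins = int(np.floor(m.max() / bin_width)) + 1 if len(m) else 1
    return np.bincount(
        np.floor(m / bin_width).astype(int), minlength=n_bins
    ).astype(float)


def snapshot(
    population: Sequence[AgentState], params: ModelParams
) -> MetricsSnapshot:
    """All monitored quantities for one population state."""
    multi = len(population) >= 2
    sum_att, sum_rep, pct = force_decomposition(population, params)
    sector = None
    if params.dimension == 2:
        try:
            sector = sector_histogram(population)
        except UndefinedMetric:
            sector = None
    return MetricsSnapshot(
        center_of_attributes=center_of_attributes(population),
        mdcn=mdcn(population, params) if multi else float("nan"),
        mean_pairwise=mean_pairwise_distance(population, params)
        if multi
        else float("nan"),
        mean_dist_origin=mean_distance_to_origin(population),
        sector_hist=sector,
        annular_hist=annular_histogram(population),
        mass_hist=mass_histogram(population),
        moment_of_inertia=moment_of_inertia(population),
        sum_attractive=sum_att,
        sum_repulsive=sum_rep,
        repulsive_pct=pct,
    )


def write_snapshot_csv(result, params: ModelParams, path, run_id=0) -> None:
    """Per-iteration metric snapshots, one CSV row keyed by (run, iteration).

    Requires the run to have been executed with trajectory recording on;
    the scalar snapshot fields are recomputed post hoc from the stored
    per-iteration positions and masses.
    """
    import pandas as pd

    from .model_core import AgentState

    if result.trajectory is None:
        raise ValueError("run was executed without trajectory recording")
    rows = []
    for frame in result.trajectory:
        pop = [
            AgentState(
                id=a["id"],
                position=np.asarray(a["pos"]),
                active_mass=a["m"],
                passive_mass=a["M"],
            )
            for a in frame["agents"]
        ]
        s = snapshot(pop, params)
        center = s.center_of_attributes
        rows.append(
            {
                "run_id": run_id,
                "iteration": frame["iteration"],
                "et": frame["et"],
                "dt": frame["dt"],
                "n_agents": len(pop),
                "center_x": center[0],
                "center_y": center[1] if len(center) > 1 else float("nan"),
                "mdcn": s.mdcn,
                "mean_pairwise": s.mean_pairwise,
                "mean_dist_origin": s.mean_dist_origin,
                "moment_of_inertia": s.moment_of_inertia,
                "sum_attractive": s.sum_attractive,
                "sum_repulsive": s.sum_repulsive,
                "repulsive_pct": s.repulsive_pct,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
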