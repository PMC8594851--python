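"""Simulation loop: adaptive time stepping, simultaneous update, coalescence.

One iteration of the model:

1. net forces on every agent are computed from the pre-step state;
2. trial displacements at ``DT = 1`` give the *peak distance*, the
   largest trial move of any agent;
3. the actual step is rescaled via ``DT**2 = CR / PeakDistance`` so
   that the largest realized move is exactly the Coalescence Radius,
   keeping trajectories smooth and independent of the force scale ``g``;
4. all positions update simultaneously;
5. agents closer than CR merge permanently into groups (connected
   components, position of the heaviest member, masses summed).

Elapsed time is the running sum of the adaptive steps ``DT_i``; a large
DT signals weak forces (typically the final repulsive phase of
large-AIB runs).

The public operations (:func:`step`, :func:`merge_pass`, ...) work on
lists of :class:`~fvm.model_core.AgentState`; the run loop keeps the
population in flat arrays internally for speed, sharing the same kernel.
"""

from __future__ import annotations

import math
import secrets
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .model_core import AgentState, ForceMode, ModelParams

__all__ = [
    "EPS_EQUILIBRIUM",
    "EquilibriumSignal",
    "StopCriteria",
    "StepRecord",
    "RunResult",
    "compute_adaptive_dt",
    "merge_pass",
    "step",
    "check_termination",
    "run",
    "simulate",
]

#: Peak trial displacements below this count as "no more movement".
EPS_EQUILIBRIUM = 1e-12


class EquilibriumSignal(Exception):
    """Raised when no finite adaptive DT exists (peak distance ~ 0)."""


@dataclass(frozen=True)
class StopCriteria:
    """Optional early-stop settings; 0 disables each one.

    tickstop    halt after this many iterations.
    agent_stop  halt once this few agents (individuals + groups) remain.
    dt_stop     halt when the computed adaptive DT would exceed this,
                i.e. when forces have become correspondingly weak.
    """

    tickstop: int = 0
    agent_stop: int = 0
    dt_stop: float = 0.0

    def __post_init__(self) -> None:
        if self.tickstop < 0 or self.agent_stop < 0 or self.dt_stop < 0:
            raise ValueError("stop criteria must be >= 0")


@dataclass(frozen=True)
class StepRecord:
    """Per-iteration observables."""

    iteration: int
    dt: float
    elapsed_time: float
    peak_distance: float
    sum_attractive: float
    sum_repulsive: float
    repulsive_pct: float
    n_agents: int
    n_groups: int
    max_force: float


@dataclass
class RunResult:
    """Outcome of one full simulation."""

    final_population: list[AgentState]
    stop_reason: str
    records: list[StepRecord]
    config_echo: dict
    seed: int
    initial_population: list[AgentState] = field(default_factory=list)
    trajectory: Optional[list[dict]] = None

    @property
    def elapsed_time(self) -> float:
        return self.records[-1].elapsed_time if self.records else 0.0

    @property
    def iterations(self) -> int:
        return len(self.records)

    def snapshot_index(self, fraction: float) -> int:
        """Index of the first record with ET >= fraction * final ET."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        target = fraction * self.elapsed_time
        for i, rec in enumerate(self.records):
            if rec.elapsed_time >= target:
                return i
        return len(self.records) - 1


def compute_adaptive_dt(peak_distance: float, cr: float) -> float:
    """Adaptive time step ``sqrt(cr / peak_distance)``.

    Rescales the trial displacements so the largest realized move equals
    the Coalescence Radius exactly.  A vanishing peak distance means the
    system is at rest and no finite DT exists.
    """
    if peak_distance < 0:
        raise ValueError("peak_distance must be nonnegative")
    if peak_distance < EPS_EQUILIBRIUM:
        raise EquilibriumSignal("no movement: system is at equilibrium")
    return math.sqrt(cr / peak_distance)


# ---------------------------------------------------------------------------
# array kernel


def _pairwise_sq(pos: np.ndarray, params: ModelParams):
    """Difference tensor and squared weighted distances (diagonal = inf)."""
    diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = pos_j - pos_i
    if params.unit_weights:
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
    else:
        r2 = np.einsum("ijk,k->ij", diff * diff, params.weights_array)
    np.fill_diagonal(r2, np.inf)
    return diff, r2


def _pairwise(pos: np.ndarray, params: ModelParams):
    """Weighted distance matrix (diagonal = inf)."""
    diff, r2 = _pairwise_sq(pos, params)
    return diff, np.sqrt(r2)


def _net_forces(pos: np.ndarray, m: np.ndarray, params: ModelParams, pre=None):
    """Net force on every agent plus the monitored force sums.

    Returns ``(forces, sum_attractive, sum_repulsive, min_pair_dist,
    max_force)``.  Force sums are over ordered communicating pairs,
    classified by the sign of the realized scalar prefactor.  ``pre``
    optionally carries a precomputed ``(diff, r2)`` pair for this exact
    position array.
    """
    n = len(pos)
    if n == 1:
        z = np.zeros_like(pos)
        return z, 0.0, 0.0, np.inf, 0.0
    diff, r2 = pre if pre is not None else _pairwise_sq(pos, params)
    r = np.sqrt(r2)
    dots = pos @ pos.T
    if params.distance_exponent == 2.0:
        denom = r2
    else:
        denom = r**params.distance_exponent
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (params.g * m)[None, :] * dots / denom  # s[i, j]: j acting on i
    # blocked pairs and the (inf-distance) diagonal contribute nothing;
    # coincident distinct agents (r=0) are degenerate and zeroed here —
    # the merge pass is responsible for collapsing them
    s[r2 > params.aib * params.aib] = 0.0
    s[~np.isfinite(s)] = 0.0

    mode = params.force_mode
    if mode is not ForceMode.NORMAL:
        if mode is ForceMode.ATTRACT_ONLY:
            s = np.abs(s)
        elif mode is ForceMode.REPEL_ONLY:
            s = -np.abs(s)
        elif mode is ForceMode.ZERO_REPULSIVE:
            s = np.where(dots < 0, 0.0, s)
        elif mode is ForceMode.ZERO_ATTRACTIVE:
            s = np.where(dots > 0, 0.0, s)
        elif mode is ForceMode.INVERT:
            s = -s

    with np.errstate(divide="ignore", invalid="ignore"):
        coef = s / r
    coef[~np.isfinite(coef)] = 0.0
    forces = np.einsum("ij,ijk->ik", coef, diff)

    if params.unit_weights:
        abs_sum = float(np.abs(s).sum())
        signed_sum = float(s.sum())
        sum_att = 0.5 * (abs_sum + signed_sum)
        sum_rep = 0.5 * (abs_sum - signed_sum)
    else:
        eucl = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        with np.errstate(invalid="ignore"):
            mags = np.abs(s) * np.where(r > 0, eucl / r, 0.0)
        np.fill_diagonal(mags, 0.0)
        sum_att = float(mags[s > 0].sum())
        sum_rep = float(mags[s < 0].sum())
    min_pair = float(math.sqrt(r2.min()))
    max_force = float(np.sqrt((forces * forces).sum(axis=1).max()))
    return forces, sum_att, sum_rep, min_pair, max_force


def _merge_arrays(pos, m, M, ids, members, params):
    """Connected components of the closer-than-CR graph, merged.

    Returns the (possibly unchanged) arrays plus a cache slot: when no
    merge happened the ``(diff, r2)`` pair computed here is returned so
    the caller can reuse it for the next force evaluation; when the
    population changed the slot is None.  Each component collapses to
    one agent at the position of its greatest-active-mass member (ties:
    lowest id), with summed masses and unioned member sets.
    """
    n = len(pos)
    if n < 2:
        return pos, m, M, ids, members, None
    diff, r2 = _pairwise_sq(pos, params)
    adj = r2 < params.coalescence_radius**2
    if not adj.any():
        return pos, m, M, ids, members, (diff, r2)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, return_labels=True
    )
    new_pos = np.empty((n_comp, pos.shape[1]))
    new_m = np.empty(n_comp)
    new_M = np.empty(n_comp)
    new_ids = np.empty(n_comp, dtype=np.int64)
    new_members: list[frozenset[int]] = [frozenset()] * n_comp
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            i = idx[0]
            new_pos[c] = pos[i]
            new_m[c] = m[i]
            new_M[c] = M[i]
            new_ids[c] = ids[i]
            new_members[c] = members[i]
            continue
        comp_m = m[idx]
        best = comp_m.max()
        # winner: greatest active mass, ties broken by lowest id
        cand = idx[comp_m == best]
        winner = cand[np.argmin(ids[cand])]
        new_pos[c] = pos[winner]
        new_m[c] = comp_m.sum()
        new_M[c] = M[idx].sum()
        new_ids[c] = ids[winner]
        new_members[c] = frozenset().union(*(members[i] for i in idx))
    return new_pos, new_m, new_M, new_ids, new_members, None


def _to_arrays(population: Sequence[AgentState]):
    pos = np.array([a.position for a in population], dtype=float)
    m = np.array([a.active_mass for a in population], dtype=float)
    M = np.array([a.passive_mass for a in population], dtype=float)
    ids = np.array([a.id for a in population], dtype=np.int64)
    members = [a.member_ids for a in population]
    return pos, m, M, ids, members


def _to_population(pos, m, M, ids, members) -> list[AgentState]:
    return [
        AgentState(
            id=int(ids[i]),
            position=pos[i].copy(),
            active_mass=float(m[i]),
            passive_mass=float(M[i]),
            member_ids=members[i],
        )
        for i in range(len(pos))
    ]


# ---------------------------------------------------------------------------
# public operations


def merge_pass(
    population: Sequence[AgentState], params: ModelParams
) -> list[AgentState]:
    """Merge every connected component of agents closer than CR.

    Merging is transitive within one pass (a chain a-b-c with both links
    under CR becomes one 3-member group), which makes the outcome
    independent of pair enumeration order.  Ties at exactly CR do not
    merge.  Groups are permanent: nothing ever splits one.
    """
    pos, m, M, ids, members = _to_arrays(population)
    pos, m, M, ids, members, _ = _merge_arrays(pos, m, M, ids, members, params)
    return _to_population(pos, m, M, ids, members)


def step(
    population: Sequence[AgentState],
    params: ModelParams,
    adaptive: bool = True,
    iteration: int = 1,
    elapsed_before: float = 0.0,
) -> tuple[list[AgentState], StepRecord]:
    """One full iteration: forces, adaptive DT, simultaneous move, merge.

    Raises :class:`EquilibriumSignal` when adaptive stepping is on and no
    agent would move (peak trial displacement below tolerance).
    """
    if not len(population):
        raise ValueError("population must be non-empty")
    pos, m, M, ids, members = _to_arrays(population)
    forces, sum_att, sum_rep, _, max_force = _net_forces(pos, m, params)
    trial = forces / M[:, None]
    peak = float(np.sqrt((trial * trial).sum(axis=1).max()))
    if adaptive:
        dt = compute_adaptive_dt(peak, params.coalescence_radius)
    else:
        dt = 1.0
    pos = pos + trial * dt * dt
    pos, m, M, ids, members, _ = _merge_arrays(pos, m, M, ids, members, params)
    new_pop = _to_population(pos, m, M, ids, members)
    total = sum_att + sum_rep
    record = StepRecord(
        iteration=iteration,
        dt=dt,
        elapsed_time=elapsed_before + dt,
        peak_distance=peak,
        sum_attractive=sum_att,
        sum_repulsive=sum_rep,
        repulsive_pct=100.0 * sum_rep / total if total > 0 else 0.0,
        n_agents=len(new_pop),
        n_groups=sum(a.is_group for a in new_pop),
        max_force=max_force,
    )
    return new_pop, record


def check_termination(
    population: Sequence[AgentState],
    records: Sequence[StepRecord],
    stop: StopCriteria,
    params: ModelParams,
) -> Optional[str]:
    """Stop reason for the current state, or None to continue.

    Checked in order: all agents beyond the AIB (no interaction possible),
    equilibrium (no movement; also the single-agent case), tickstop,
    agent_stop, dt_stop (on the DT the *next* step would use).
    """
    pos, m, M, _, _ = _to_arrays(population)
    if len(population) > 1:
        _, r = _pairwise(pos, params)
        if float(r.min()) > params.aib:
            return "all_beyond_aib"
        forces, *_ = _net_forces(pos, m, params)
        trial = forces / M[:, None]
        peak = float(np.sqrt((trial * trial).sum(axis=1).max()))
    else:
        peak = 0.0
    if peak < EPS_EQUILIBRIUM:
        return "equilibrium"
    if 0 < stop.tickstop <= len(records):
        return "tickstop"
    if 0 < stop.agent_stop and len(population) <= stop.agent_stop:
        return "agent_stop"
    if stop.dt_stop > 0:
        next_dt = math.sqrt(params.coalescence_radius / peak)
        if next_dt > stop.dt_stop:
            return "dt_stop"
    return None


# ---------------------------------------------------------------------------
# full run


def simulate(
    positions: np.ndarray,
    active: np.ndarray,
    passive: np.ndarray,
    params: ModelParams,
    stop: StopCriteria = StopCriteria(),
    adaptive: bool = True,
    record_trajectory: bool = False,
    ids: np.ndarray | None = None,
) -> tuple[list[AgentState], str, list[StepRecord], Optional[list[dict]]]:
    """Core loop over a population given as flat arrays.

    Applies one merge pass at t=0 (resolving coincident injected agents),
    then iterates step / termination-check until a stop reason fires.
    """
    pos = np.asarray(positions, dtype=float).copy()
    m = np.asarray(active, dtype=float).copy()
    M = np.asarray(passive, dtype=float).copy()
    n = len(pos)
    if ids is None:
        ids = np.arange(n, dtype=np.int64)
    members = [frozenset([int(i)]) for i in ids]

    pos, m, M, ids, members, cache = _merge_arrays(pos, m, M, ids, members, params)

    records: list[StepRecord] = []
    trajectory: Optional[list[dict]] = [] if record_trajectory else None
    et = 0.0
    iteration = 0
    cr = params.coalescence_radius
    stop_reason = None

    while True:
        if len(pos) == 1:
            stop_reason = "equilibrium"
            break
        forces, sum_att, sum_rep, min_pair, max_force = _net_forces(
            pos, m, params, pre=cache
        )
        if min_pair > params.aib:
            stop_reason = "all_beyond_aib"
            break
        trial = forces / M[:, None]
        peak = float(np.sqrt((trial * trial).sum(axis=1).max()))
        if peak < EPS_EQUILIBRIUM:
            stop_reason = "equilibrium"
            break
        dt = math.sqrt(cr / peak) if adaptive else 1.0
        if 0 < stop.dt_stop < dt:
            stop_reason = "dt_stop"
            break
        pos = pos + trial * (dt * dt)
        pos, m, M, ids, members, cache = _merge_arrays(
            pos, m, M, ids, members, params
        )
        iteration += 1
        et += dt
        total = sum_att + sum_rep
        records.append(
            StepRecord(
                iteration=iteration,
                dt=dt,
                elapsed_time=et,
                peak_distance=peak,
                sum_attractive=sum_att,
                sum_repulsive=sum_rep,
                repulsive_pct=100.0 * sum_rep / total if total > 0 else 0.0,
                n_agents=len(pos),
                n_groups=sum(len(s) > 1 for s in members),
                max_force=max_force,
            )
        )
        if record_trajectory:
            trajectory.append(
                {
                    "iteration": iteration,
                    "et": et,
                    "dt": dt,
                    "agents": [
                        {
                            "id": int(ids[i]),
                            "pos": [float(x) for x in pos[i]],
                            "m": float(m[i]),
                            "M": float(M[i]),
                            "group": len(members[i]) > 1,
                        }
                        for i in range(len(pos))
                    ],
                }
            )
        if 0 < stop.tickstop <= iteration:
            stop_reason = "tickstop"
            break
        if 0 < stop.agent_stop and len(pos) <= stop.agent_stop:
            stop_reason = "agent_stop"
            break

    final = _to_population(pos, m, M, ids, members)
    return final, stop_reason, records, trajectory


def run(config) -> RunResult:
    """Run one full simulation from a :class:`~fvm.config.RunConfig`.

    Deterministic: the same config and non-zero seed reproduce identical
    records and final positions bit-for-bit on the same build.  A seed of
    0 draws a fresh seed and records it in the result.
    """
    from .initialization import initial_population

    seed = config.init.seed
    if seed == 0:
        seed = secrets.randbelow(2**31 - 2) + 1
        spec = replace(config.init, seed=seed)
    else:
        spec = config.init
    pos, m, M, ids, rejected = initial_population(spec, config.model)
    initial = _to_population(
        pos, m, M, ids, [frozenset([int(i)]) for i in ids]
    )
    final, stop_reason, records, trajectory = simulate(
        pos,
        m,
        M,
        config.model,
        stop=config.stop,
        adaptive=config.adaptive,
        record_trajectory=config.record_trajectory,
        ids=ids,
    )
    return RunResult(
        final_population=final,
        stop_reason=stop_reason,
        records=records,
        config_echo=config.to_dict() | {"realized_seed": seed},
        seed=seed,
        initial_population=initial,
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# exports


def write_step_log(records: Sequence[StepRecord], path, config_hash: str = "") -> None:
    """CSV step log, one row per iteration, with a provenance comment."""
    import pandas as pd

    df = pd.DataFrame([r.__dict__ for r in records])
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def write_trajectory(trajectory: Sequence[dict], path) -> None:
    """JSON-lines trajectory export, one object per iteration."""
    import json

    with open(path, "w") as fh:
        for rec in trajectory:
            fh.write(json.dumps(rec) + "\n")
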