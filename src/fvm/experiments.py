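"""Ensemble drivers and across-run statistics.

The model is deterministic, but the normal initial distributions make
every seed's outcome different; the regularities live in ensembles.
This module runs batches of simulations over distinct seeds and
aggregates the endpoint observables: final agent/group counts and their
decay with the Attribute Influence Bound, final-state geometry (angles
and masses of the survivors), and the consensus probability as a
function of where the initial distribution is centered.

Seeds within an ensemble are consecutive from a base seed, so every
summary is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics
from .config import RunConfig
from .engine import RunResult, run

__all__ = [
    "RunOutcome",
    "EnsembleSummary",
    "GeometryStats",
    "ConsensusCell",
    "run_ensemble",
    "sweep_aib",
    "fit_agent_decay",
    "final_state_geometry",
    "consensus_grid",
    "ensemble_dataframe",
    "write_sweep_csv",
]


@dataclass(frozen=True)
class RunOutcome:
    """Endpoint observables of one run, kept for pooling."""

    seed: int
    aib: float
    n_initial: int
    n_final_agents: int
    n_final_groups: int
    iterations: int
    elapsed_time: float
    stop_reason: str
    mdcn: float
    mean_pairwise: float
    mean_dist_origin: float
    centroid_drift: float
    repulsive_pct_final: float
    largest_mass_share: float
    consensus: bool
    final_positions: np.ndarray = field(repr=False)
    final_active: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class EnsembleSummary:
    """Across-run statistics for one swept value."""

    key: float | tuple
    n_runs: int
    mean_final_agents: float
    sd_final_agents: float
    mean_final_groups: float
    sd_final_groups: float
    mean_mdcn: float
    sd_mdcn: float
    median_mdcn: float
    mean_dist_origin: float
    mean_pairwise: float
    runs: tuple[RunOutcome, ...] = field(repr=False)


@dataclass(frozen=True)
class GeometryStats:
    """Pooled adjacent-gap and mass statistics of k-survivor runs."""

    k: int
    n_runs: int
    gap_mean: float
    gap_sd: float
    mass_mean: float
    mass_sd: float


@dataclass(frozen=True)
class ConsensusCell:
    """Consensus fractions for one initial-distribution center."""

    center: tuple[float, float]
    p_consensus: float
    p_90: float
    n_runs: int


def summarize_run(result: RunResult, params) -> RunOutcome:
    final = result.final_population
    n_final = len(final)
    aib = params.aib
    total_active = sum(a.active_mass for a in final)
    largest = max(a.active_mass for a in final)
    drift = float(
        np.linalg.norm(
            metrics.center_of_attributes(final)
            - metrics.center_of_attributes(result.initial_population)
        )
    )
    return RunOutcome(
        seed=result.seed,
        aib=aib,
        n_initial=len(result.initial_population),
        n_final_agents=n_final,
        n_final_groups=sum(a.is_group for a in final),
        iterations=result.iterations,
        elapsed_time=result.elapsed_time,
        stop_reason=result.stop_reason,
        mdcn=metrics.mdcn(final, params) if n_final >= 2 else float("nan"),
        mean_pairwise=metrics.mean_pairwise_distance(final, params)
        if n_final >= 2
        else float("nan"),
        mean_dist_origin=metrics.mean_distance_to_origin(final),
        centroid_drift=drift,
        repulsive_pct_final=result.records[-1].repulsive_pct
        if result.records
        else 0.0,
        largest_mass_share=largest / total_active,
        consensus=n_final == 1,
        final_positions=np.array([a.position for a in final]),
        final_active=np.array([a.active_mass for a in final]),
    )


def run_ensemble(
    config: RunConfig, n_runs: int, base_seed: int, key: float | tuple | None = None
) -> EnsembleSummary:
    """n_runs independent simulations with seeds base_seed .. base_seed+n-1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if base_seed < 1:
        raise ValueError("base_seed must be >= 1 (0 means a fresh seed)")
    outcomes = []
    for i in range(n_runs):
        seed = base_seed + i
        cfg = replace(config, init=replace(config.init, seed=seed))
        try:
            result = run(cfg)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"run with seed {seed} failed: {exc}") from exc
        outcomes.append(summarize_run(result, config.model))
    return _summarize(outcomes, config.model.aib if key is None else key)


def _summarize(outcomes: Sequence[RunOutcome], key) -> EnsembleSummary:
    n_final = np.array([o.n_final_agents for o in outcomes], dtype=float)
    n_groups = np.array([o.n_final_groups for o in outcomes], dtype=float)
    mdcn_vals = np.array([o.mdcn for o in outcomes])
    pooled_dist = np.concatenate(
        [np.linalg.norm(o.final_positions, axis=1) for o in outcomes]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN mdcn slices
        return EnsembleSummary(
            key=key,
            n_runs=len(outcomes),
            mean_final_agents=float(n_final.mean()),
            sd_final_agents=float(n_final.std(ddof=1)) if len(outcomes) > 1 else 0.0,
            mean_final_groups=float(n_groups.mean()),
            sd_final_groups=float(n_groups.std(ddof=1)) if len(outcomes) > 1 else 0.0,
            mean_mdcn=float(np.nanmean(mdcn_vals)),
            sd_mdcn=float(np.nanstd(mdcn_vals, ddof=1))
            if np.isfinite(mdcn_vals).sum() > 1
            else 0.0,
            median_mdcn=float(np.nanmedian(mdcn_vals)),
            mean_dist_origin=float(pooled_dist.mean()),
            mean_pairwise=float(
                np.nanmean([o.mean_pairwise for o in outcomes])
            ),
            runs=tuple(outcomes),
        )


def sweep_aib(
    aib_values: Sequence[float],
    base_config: RunConfig,
    n_runs: int,
    base_seed: int = 1,
) -> list[EnsembleSummary]:
    """One ensemble per AIB value, all else fixed.

    Every AIB reuses the same seed block, so the sweep isolates the
    effect of the confidence bound on identical initial arrangements.
    """
    if not len(aib_values):
        raise ValueError("aib_values must be non-empty")
    out = []
    for aib in aib_values:
        cfg = replace(base_config, model=replace(base_config.model, aib=aib))
        out.append(run_ensemble(cfg, n_runs, base_seed, key=aib))
    return out


def fit_agent_decay(
    summaries: Sequence[EnsembleSummary], floor: float = 2.2
) -> tuple[float, float, float]:
    """OLS fit of ln(mean_final_agents - floor) against AIB.

    The mean number of survivors decays exponentially toward a floor of
    about 2.2 agents as the AIB grows; the fitted slope is the decay
    rate (per unit AIB).  Returns (slope, intercept, r_squared); points
    at or below the floor are excluded with a warning.
    """
    xs, ys = [], []
    for s in summaries:
        if s.mean_final_agents > floor:
            xs.append(float(s.key))
            ys.append(np.log(s.mean_final_agents - floor))
        else:
            warnings.warn(
                f"AIB={s.key}: mean {s.mean_final_agents} <= floor {floor}; "
                "point excluded from decay fit"
            )
    if len(xs) < 2:
        raise ValueError("need >= 2 usable points for the decay fit")
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def final_state_geometry(
    runs_or_summaries, k: int
) -> GeometryStats:
    """Angle/mass statistics pooled over runs ending with exactly k agents.

    All k wrap-around adjacent gaps of each qualifying run are pooled,
    so the gap mean is forced to 360/k by normalization and the SD
    measures the scatter of the endpoint geometry around the perfectly
    symmetric arrangement (for k = 2 both gaps theta and 360 - theta
    enter, making the statistic the RMS deviation from antipodal).
    Masses are pooled over all survivors.
    """
    runs = _flatten_runs(runs_or_summaries)
    qualifying = [r for r in runs if r.n_final_agents == k]
    if not qualifying:
        raise ValueError(f"no runs ended with exactly {k} agents")
    gaps, masses = [], []
    for r in qualifying:
        gaps.extend(metrics.adjacent_angle_gaps(r.final_positions))
        masses.extend(r.final_active)
    gaps = np.asarray(gaps)
    masses = np.asarray(masses)
    return GeometryStats(
        k=k,
        n_runs=len(qualifying),
        gap_mean=float(gaps.mean()),
        gap_sd=float(gaps.std(ddof=1)) if len(gaps) > 1 else 0.0,
        mass_mean=float(masses.mean()),
        mass_sd=float(masses.std(ddof=1)) if len(masses) > 1 else 0.0,
    )


def _flatten_runs(runs_or_summaries) -> list[RunOutcome]:
    runs: list[RunOutcome] = []
    for item in runs_or_summaries:
        if isinstance(item, EnsembleSummary):
            runs.extend(item.runs)
        else:
            runs.append(item)
    return runs


def consensus_grid(
    centers: Sequence[tuple[float, float]],
    base_config: RunConfig,
    n_runs: int,
    base_seed: int = 1,
) -> list[ConsensusCell]:
    """Consensus fractions over a grid of initial-distribution centers.

    Each cell recenters the (normal) spatial distribution at the given
    point and runs ``n_runs`` seeds.  ``p_consensus`` counts runs whose
    single final agent absorbed every original member; ``p_90`` counts
    runs whose largest final agent holds at least 90% of the total
    active mass (so p_consensus <= p_90 by construction).
    """
    cells = []
    for j, (cx, cy) in enumerate(centers):
        spatial = base_config.init.axis_dists(base_config.model.dimension)
        new_spatial = tuple(
            replace(d, mean=c) if d.kind == "normal" else d
            for d, c in zip(spatial, (cx, cy))
        )
        cfg = replace(
            base_config,
            init=replace(base_config.init, spatial=new_spatial),
        )
        summary = run_ensemble(
            cfg, n_runs, base_seed + j * n_runs, key=(cx, cy)
        )
        n_cons = sum(o.consensus for o in summary.runs)
        n_90 = sum(o.largest_mass_share >= 0.9 for o in summary.runs)
        cells.append(
            ConsensusCell(
                center=(cx, cy),
                p_consensus=n_cons / n_runs,
                p_90=n_90 / n_runs,
                n_runs=n_runs,
            )
        )
    return cells


def ensemble_dataframe(
    summaries: Sequence[EnsembleSummary],
) -> pd.DataFrame:
    """One row per run, in the sweep-output schema."""
    rows = []
    for s in summaries:
        for o in s.runs:
            rows.append(
                {
                    "seed": o.seed,
                    "aib": o.aib,
                    "n_initial": o.n_initial,
                    "n_final_agents": o.n_final_agents,
                    "n_final_groups": o.n_final_groups,
                    "iterations": o.iterations,
                    "elapsed_time": o.elapsed_time,
                    "stop_reason": o.stop_reason,
                    "mdcn": o.mdcn,
                    "mean_pairwise": o.mean_pairwise,
                    "mean_dist_origin": o.mean_dist_origin,
                    "centroid_drift": o.centroid_drift,
                    "repulsive_pct_final": o.repulsive_pct_final,
                    "largest_mass_share": o.largest_mass_share,
                }
            )
    return pd.DataFrame(rows)


def write_sweep_csv(
    summaries: Sequence[EnsembleSummary], path, config_hash: str = ""
) -> None:
    """Sweep CSV, one row per run, with a provenance comment line."""
    df = ensemble_dataframe(summaries)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)
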