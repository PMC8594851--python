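# Methods

## Model

Each agent is a vector **A** = (x_A, y_A, …) in a continuous attribute
space of dimension d (default 2).  The vector's direction — the agent's
*attribute orientation* — encodes what the agent believes; its length
encodes how far from neutral it sits.  The force exerted by agent A on
agent B is

    F_AonB = g · m_A · (A·B) / R^p · (R_vec / R),      R_vec = A − B,

with R the metric-weighted attribute distance
`sqrt(Σ_k w_k (a_k − b_k)²)` and p the distance exponent (2 by
default, the inverse-square law).  The dot product makes the sign of
the interaction a function of relative orientation alone: vectors
subtending less than 90° attract, more than 90° repel, exactly 90°
gives exactly zero force (no epsilon band; the sign decision uses the
dot product directly, never `acos`).  Pairs farther apart than the
Attribute Influence Bound (AIB) — the model's confidence bound — do not
interact at all.  An agent at the origin is a null vector: it neither
exerts nor receives force.

The force is deliberately asymmetric: it scales with the *active mass*
m_A of the acting agent (charisma) and is resisted by the *passive
mass* M_B of the receiving agent (stubbornness).  One integration step
moves B by

    ΔB = F_AonB / M_B · DT².

The conventional ½ of Newtonian kinematics is absorbed into g; the
update rule is implemented exactly as stated, since g is a pure scale
that provably does not affect trajectories under adaptive stepping
(only elapsed time rescales — the g-invariance test verifies bit-level
trajectory identity and the constancy of g·ET²).

All agents update simultaneously from the pre-step state.

## Adaptive time stepping

Each iteration first computes trial displacements at DT = 1; the
largest trial move is the *peak distance*.  The realized step uses
DT² = CR / PeakDistance, so the largest realized move is exactly the
Coalescence Radius CR.  This keeps trajectories smooth (0.1% of the
visible width per step at defaults), makes the simulation independent
of g, and lets weak-force phases (the repulsive endgame of large-AIB
runs, where DT grows past 100) complete in a bounded number of
iterations.  Elapsed time is ET = Σ DT_i.

## Group formation

After each movement, every connected component of the
"closer-than-CR" graph merges into one permanent group positioned at
its greatest-active-mass member (ties broken by lowest id), with summed
active and passive masses and unioned member sets.  Reading "less than
CR" strictly, a pair at exactly CR does not merge.  Merging by
connected components (transitive within one pass) makes the outcome
independent of pair enumeration order; the original description is
pairwise and silent on ordering.  One merge pass also runs at t = 0 so
coincident injected agents never produce singular forces.  Groups are
permanent: no operation splits one, and total active and passive mass
are conserved exactly.

## Termination

A run stops when one of these fires (checked in this order):

1. **all_beyond_aib** — every pairwise distance exceeds the AIB, so no
   further interaction is possible.  This is checked first: a
   population that is both motionless and fully disconnected is
   reported as disconnected, which is the more informative reason.
2. **equilibrium** — the peak trial displacement falls below
   ε = 1e-12 model units ("no more movement"; exact zero is
   float-fragile).  A single surviving agent also reports equilibrium.
3. **tickstop / agent_stop / dt_stop** — optional user stops on the
   iteration count, the surviving agent count, and the computed DT.
   The dt_stop check fires *before* the offending step executes, so no
   recorded step ever used a DT above the limit.

## Initial conditions

Positions are drawn per axis (uniform over the visible window,
normal, or one-sided exponential from the lower edge); coordinates
outside the visible window ([−100, 100] per axis) are rejected and
redrawn, with the rejection count reported.  Masses are drawn the same
way, rejecting draws above the cap `max_mass` — and, additionally,
non-positive draws, since masses are strictly positive model
quantities (probability ~3e-5 per draw under the standard mass law).
The rejection budget is 1e6 draws per coordinate, after which the spec
is declared infeasible rather than looping forever.

Draw order is fixed — all positions agent-by-agent (x, then y, then
higher axes), then all masses agent-by-agent — so one integer seed
pins the entire stream (NumPy PCG64).  Seed 0 means "draw a fresh
seed"; the realized seed is recorded in the result.  Ensembles use
consecutive seeds from a base seed.

**Standard Conditions** (the baseline for every reported ensemble):
100 agents, normal(0, 30) on both axes, masses normal(60, 15) with
active = passive, mass cap 120 (mean + 4 SD; the cap's exact value is
a free choice and is exposed — truncation shifts the realized mean
mass only ~0.05 below 60), CR = 0.2, g = 7e-5, exponent 2, adaptive
stepping on.

Geometry presets (square/triangle at a circumradius, ring of k) place
exact symmetric coordinates for studying the model's symmetries, and
single agents of any mass can be injected at chosen positions.

During a run positions are never clamped: an agent that leaves the
visible window (a "ghost") keeps interacting normally; the window is
reporting metadata only.

## Observables

Per iteration: DT, ET, peak distance, the sums of attractive and
repulsive pairwise force magnitudes and the repulsive percentage, agent
and group counts, and the maximum net force.  The force sums are taken
over *directed* communicating pairs (the two directions of a pair have
different magnitudes because the force scales with the actor's active
mass; the percentage is insensitive to this factor-of-two convention).

Per population: the Center of Attributes (active-mass-weighted mean
position, approximately conserved over a run), MDCN (mean distance to
closest neighbor), mean pairwise distance, mean distance to origin,
a 12-sector normalized angular histogram (sector 0 = [0°, 30°) from
the +x axis, half-open bins, origin agents excluded; angles within
1e-9° below a bin boundary snap upward so exact symmetric arrangements
bin deterministically), adjacent-angle gaps (wrap-around included, sum
exactly 360°; for two agents the "angle between them" is the minor
angle ≤ 180°), annular and mass histograms (default bin widths 5 model
units and 10 mass units), and a moment of inertia defined here as
Σ M_i |r_i|² about the origin with passive-mass weighting (the choice
of weighting and reference point is ours; it is asserted only against
hand-computed oracles).

## Ensemble experiments

- **AIB sweep / agent decay**: ensembles of runs per AIB value; the
  mean number of survivors decays approximately exponentially toward a
  floor of ~2.2 agents, fitted as OLS of ln(mean − 2.2) on AIB, with
  sub-floor points excluded with a warning.
- **Final-state geometry**: runs ending with exactly k agents pool all
  k wrap-around adjacent gaps and the survivor masses.  The gap mean is
  then forced to 360/k by normalization and the SD measures scatter
  around the symmetric endpoint; for k = 2 both gaps θ and 360° − θ
  enter, making the statistic the RMS deviation from antipodal (a
  per-run minor-angle helper exists separately for reporting).  The 2-
  and 3-survivor statistics are pooled over AIB 60–100, the regime
  where those endpoints dominate.
- **Consensus grid**: the center of the normal spatial distribution
  sweeps a grid; per cell, `p_consensus` is the fraction of runs whose
  single survivor absorbed every original member (membership counted
  by member ids), and `p_90` the fraction whose largest survivor holds
  ≥ 90% of total active mass.  By construction p_consensus ≤ p_90.

## Problem sizes and statistical floors

Desk-scale replicate counts are configuration, not code; the sizes used
by the shipped acceptance script are: 100 runs per AIB for the decay
points, 500 runs at AIB = 100 for the pooled final-state geometry, a
21×21 consensus grid (step 5 over [−50, 50]²) at 3 runs per cell, and
25 runs per far-from-origin center.  For the consensus grid the full
grid geometry is kept and the replication reduced rather than the
reverse: coarsening the grid to step 10 over-weights its boundary
cells (2 of 11 rows versus 2 of 21), and consensus probability is
highest exactly there, so the coarse design biases the overall
fraction upward by about one percentage point.

One floor is worth stating: the SD of the 12-sector normalized
histogram cannot fall below its binomial sampling floor
≈ sqrt(12 / N_pooled) even for a perfectly uniform angular law.  With
~2.2 survivors per run this floor is ~0.16 at 200 runs and ~0.10 at
500 runs, which is why the pooled-geometry ensemble uses 500 runs and
why the uniformity assertion is a bound (< 0.15), not a point value.

## What the generator does and does not emulate

The synthetic initial conditions are the model's *study conditions*,
not a fit to any empirical population: independent per-axis normals,
i.i.d. truncated-normal masses, no correlation between position and
mass, no network structure, and attributes with no assigned meaning.
Passing ensembles therefore demonstrate the model's internal
regularities (decay, symmetry, polarization, consensus basins) under
those conditions; they say nothing about how real attitude data would
behave under the force law.

## Numerical choices

- Equilibrium tolerance 1e-12 model units on the peak trial
  displacement.
- Merge threshold strict (< CR); merge-position tie-break by lowest id.
- Degenerate coincident pairs (distance exactly 0) carry zero force
  and are collapsed by the merge pass.
- Distances are compared squared where possible; the adaptive DT and
  all reported distances use exact square roots.
- CSV outputs are written at full double precision with a config-hash
  comment line for provenance.

## Known limitations

- Angular statistics are defined for d = 2 only; higher dimensions get
  the distance- and mass-based observables.
- The repulsive endgame can push groups far outside the visible
  window; reported positions are unbounded by design.
- The merge rule destroys information about within-group dispersion; a
  group is a point mass from the moment it forms.
- Elapsed time is a model-internal clock (it rescales with g and CR),
  comparable only across runs with identical g and CR.
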