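# fvm — a force vector model of social influence

`fvm` simulates opinion dynamics for populations of agents whose
attitudes are *vectors* in a continuous, unbounded attribute space.
It is a deterministic, physics-styled alternative to bounded-confidence
averaging models (Hegselmann–Krause and relatives), aimed at people who
study grouping, fragmentation, polarization and consensus with
agent-based models and want a simulator with exact, testable
symmetries plus the ensemble tooling to measure endpoint statistics.

## The model

Agent A is a vector **A** = (x_A, y_A); its direction (*attribute
orientation*) is what it believes, and the force it exerts on agent B is

```
F_AonB = g · m_A · (A·B)/R² · R̂ ,   R = |A − B|
```

- the **dot product** sets the sign: vectors subtending < 90° attract
  (attitudes converge), > 90° repel (attitudes diverge);
- the **inverse-square law** makes similar agents interact strongly —
  the opposite of the spring-like forces in averaging models;
- interaction is cut off beyond a confidence bound, the **Attribute
  Influence Bound (AIB)**;
- `m_A` is A's *active mass* (charisma); B resists in proportion to its
  *passive mass* M_B, moving by `ΔB = F/M_B · DT²`.

Adaptive time stepping (`DT² = CR / PeakDistance`) caps every move at
the **Coalescence Radius** CR; agents closer than CR merge into
permanent groups with summed masses.  Runs end at equilibrium, when all
survivors are mutually beyond the AIB, or at user stops.

Small AIB leaves many locally-consensual groups scattered through
attribute space; large AIB connects everyone and drives two or three
big groups to opposite sides of the origin, about one AIB apart —
strong polarization in a fully connected world.  Populations confined
to a single quadrant (all pairwise angles < 90°) always reach full
consensus.

## Worked example

One simulation under Standard Conditions (100 agents, positions
normal(0, 30) per axis, masses normal(60, 15) with active = passive,
g = 7·10⁻⁵, CR = 0.2) at AIB = 100:

```
$ fvm run --preset standard --aib 100 --seed 61 --summary out.csv
seed=61 stop=all_beyond_aib iterations=2261 et=26503.6 final_agents=3
```

Reading: from 100 initial agents, coalescence left 3 groups after 2261
iterations; the run ended because every surviving pair is farther apart
than the AIB (`all_beyond_aib`), i.e. the groups were driven apart by
the repulsive end phase until they could no longer communicate.  The
summary row in `out.csv` adds the endpoint metrics — here the mean
distance to the closest neighbor (`mdcn`) is 100.3 ≈ AIB, and the final
repulsive share is 100%: a polarized endpoint.

The same library calls from Python:

```python
from fvm import standard_conditions, run
result = run(standard_conditions(aib=100, seed=61))
print(result.stop_reason, len(result.final_population))  # all_beyond_aib 3
```

Ensembles, AIB sweeps and the consensus grid live in
`fvm.experiments` and behind the `fvm sweep` / `fvm grid` commands;
per-iteration step logs, JSON-lines trajectories and per-iteration
metric snapshots are available from every run.

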