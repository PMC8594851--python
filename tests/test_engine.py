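"""Engine tests: adaptive stepping, merging, termination, run invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest

from fvm import (
    ModelParams,
    StopCriteria,
    check_termination,
    compute_adaptive_dt,
    merge_pass,
    run,
    standard_conditions,
    step,
)
from fvm.engine import EquilibriumSignal, simulate
from fvm.initialization import initial_population
from fvm.model_core import displacement, pair_force
from conftest import make_agent


class TestAdaptiveDt:
    def test_fixed_point(self):
        assert compute_adaptive_dt(0.2, 0.2) == pytest.approx(1.0)

    def test_weak_forces_stretch_the_step(self):
        assert compute_adaptive_dt(0.2 / 16, 0.2) == pytest.approx(4.0)

    def test_zero_peak_signals_equilibrium(self):
        with pytest.raises(EquilibriumSignal):
            compute_adaptive_dt(0.0, 0.2)


class TestStep:
    def test_orthogonal_pair_is_at_equilibrium(self, params):
        pop = [make_agent(0, (10.0, 0.0)), make_agent(1, (0.0, 10.0))]
        with pytest.raises(EquilibriumSignal):
            step(pop, params)

    def test_max_displacement_equals_cr(self):
        """Adaptive rescaling caps the largest move at exactly CR."""
        cfg = standard_conditions(aib=100.0, seed=7)
        pos, m, M, ids, _ = initial_population(cfg.init, cfg.model)
        pop = [make_agent(int(i), pos[i], m[i], M[i]) for i in ids]
        new_pop, record = step(pop, cfg.model)
        assert len(new_pop) == len(pop)  # no merge in this arrangement
        moved = {a.id: a.position for a in new_pop}
        disp = max(
            np.linalg.norm(moved[a.id] - a.position) for a in pop
        )
        assert disp == pytest.approx(cfg.model.coalescence_radius, rel=1e-12)
        assert record.dt == pytest.approx(
            math.sqrt(cfg.model.coalescence_radius / record.peak_distance)
        )

    def test_same_ray_pair_matches_pair_oracles(self, params):
        """Step displacements compose pair_force and displacement exactly."""
        a = make_agent(0, (10.0, 0.0), m=60.0)
        b = make_agent(1, (20.0, 0.0), m=60.0)
        new_pop, record = step([a, b], params)
        dt = record.dt
        exp_a = displacement(pair_force(b, a, params).force_on_b, 60.0, dt)
        exp_b = displacement(pair_force(a, b, params).force_on_b, 60.0, dt)
        moved = {ag.id: ag.position for ag in new_pop}
        assert np.allclose(moved[0], a.position + exp_a, rtol=1e-12)
        assert np.allclose(moved[1], b.position + exp_b, rtol=1e-12)
        # they approach each other
        assert moved[0][0] > 10.0 and moved[1][0] < 20.0


class TestMergePass:
    def test_merge_takes_heavier_position_and_sums_masses(self, params):
        a = make_agent(0, (10.0, 10.0), m=60.0)
        b = make_agent(1, (10.1, 10.0), m=70.0)
        merged = merge_pass([a, b], params)
        assert len(merged) == 1
        g = merged[0]
        assert np.allclose(g.position, (10.1, 10.0))
        assert g.active_mass == pytest.approx(130.0)
        assert g.passive_mass == pytest.approx(130.0)
        assert g.is_group and g.member_ids == frozenset({0, 1})

    def test_no_close_pair_is_identity(self, params):
        pop = [make_agent(0, (0.0, 5.0)), make_agent(1, (5.0, 0.0))]
        out = merge_pass(pop, params)
        assert [a.id for a in out] == [0, 1]
        assert all(not a.is_group for a in out)

    def test_chain_merges_transitively(self, params):
        # d(a,b) and d(b,c) < CR, d(a,c) >= CR: one 3-member group
        pop = [
            make_agent(0, (0.0, 0.0), m=10.0),
            make_agent(1, (0.15, 0.0), m=30.0),
            make_agent(2, (0.30, 0.0), m=20.0),
        ]
        out = merge_pass(pop, params)
        assert len(out) == 1
        assert out[0].member_ids == frozenset({0, 1, 2})
        assert np.allclose(out[0].position, (0.15, 0.0))  # heaviest member

    def test_tie_on_active_mass_lowest_id_wins(self, params):
        pop = [
            make_agent(5, (1.0, 0.0), m=50.0),
            make_agent(2, (1.1, 0.0), m=50.0),
        ]
        out = merge_pass(pop, params)
        assert np.allclose(out[0].position, (1.1, 0.0))
        assert out[0].id == 2

    def test_exactly_cr_apart_does_not_merge(self, params):
        pop = [make_agent(0, (0.0, 0.0)), make_agent(1, (0.2, 0.0))]
        assert len(merge_pass(pop, params)) == 2

    def test_components_match_networkx_oracle(self, params, rng):
        networkx = pytest.importorskip("networkx")
        for _ in range(10):
            pts = rng.uniform(-1.0, 1.0, size=(12, 2))
            pop = [make_agent(i, p) for i, p in enumerate(pts)]
            out = merge_pass(pop, params)
            g = networkx.Graph()
            g.add_nodes_from(range(12))
            for i in range(12):
                for j in range(i + 1, 12):
                    if np.linalg.norm(pts[i] - pts[j]) < 0.2:
                        g.add_edge(i, j)
            expected = {
                frozenset(c) for c in networkx.connected_components(g)
            }
            assert {a.member_ids for a in out} == expected


class TestTermination:
    def test_separated_pair_reports_all_beyond_aib(self):
        p = ModelParams(aib=30.0)
        pop = [make_agent(0, (0.0, 0.0)), make_agent(1, (31.0, 0.0))]
        assert check_termination(pop, [], StopCriteria(), p) == "all_beyond_aib"

    def test_orthogonal_pair_reports_equilibrium(self, params):
        pop = [make_agent(0, (10.0, 0.0)), make_agent(1, (0.0, 10.0))]
        assert check_termination(pop, [], StopCriteria(), params) == "equilibrium"

    def test_tickstop_halts_with_exact_record_count(self):
        cfg = standard_conditions(aib=60.0, seed=3, tickstop=5)
        res = run(cfg)
        assert res.stop_reason == "tickstop"
        assert len(res.records) == 5

    def test_agent_stop_truncates_the_unstopped_run(self):
        free = run(standard_conditions(aib=60.0, seed=3, tickstop=300))
        counts = [r.n_agents for r in free.records]
        target = 70
        assert min(counts) <= target  # enough coalescence happens in 300 steps
        stopped = run(
            standard_conditions(aib=60.0, seed=3, agent_stop=target, tickstop=300)
        )
        assert stopped.stop_reason == "agent_stop"
        first = next(i for i, c in enumerate(counts) if c <= target)
        assert len(stopped.records) == first + 1
        assert stopped.records[-1].n_agents <= target

    def test_dt_stop(self):
        cfg = standard_conditions(aib=100.0, seed=3, dt_stop=5.0)
        res = run(cfg)
        assert res.stop_reason == "dt_stop"
        assert all(r.dt <= 5.0 for r in res.records)

    def test_all_beyond_aib_initially_means_zero_steps(self):
        from fvm.initialization import DistSpec, Injection, InitSpec

        spec = InitSpec(
            n_agents=1,
            spatial=(DistSpec("normal", mean=-50.0, sd=0.0),),
            mass=DistSpec("normal", mean=60.0, sd=0.0),
            seed=1,
            injections=(Injection((50.0, 50.0), 60.0, 60.0),),
        )
        cfg = replace(standard_conditions(aib=30.0), init=spec)
        res = run(cfg)
        assert res.stop_reason == "all_beyond_aib"
        assert res.records == []


class TestRunInvariants:
    def test_determinism_same_seed(self):
        a = run(standard_conditions(aib=60.0, seed=11))
        b = run(standard_conditions(aib=60.0, seed=11))
        assert a.stop_reason == b.stop_reason
        assert len(a.records) == len(b.records)
        assert a.elapsed_time == b.elapsed_time
        pa = np.array([x.position for x in a.final_population])
        pb = np.array([x.position for x in b.final_population])
        assert np.array_equal(pa, pb)

    def test_mass_conservation_and_member_partition(self):
        cfg = standard_conditions(aib=60.0, seed=13)
        res = run(cfg)
        m0 = sum(a.active_mass for a in res.initial_population)
        M0 = sum(a.passive_mass for a in res.initial_population)
        assert sum(a.active_mass for a in res.final_population) == pytest.approx(
            m0, rel=1e-12
        )
        assert sum(a.passive_mass for a in res.final_population) == pytest.approx(
            M0, rel=1e-12
        )
        all_members = [a.member_ids for a in res.final_population]
        union = frozenset().union(*all_members)
        assert union == frozenset(a.id for a in res.initial_population)
        assert sum(len(s) for s in all_members) == len(union)  # disjoint

    def test_g_invariance(self):
        """Trajectories are independent of g; g*ET**2 is invariant."""
        base = standard_conditions(aib=60.0, seed=17)
        big = replace(base, model=replace(base.model, g=base.model.g * 100))
        ra, rb = run(base), run(big)
        assert len(ra.records) == len(rb.records)
        pa = np.array([x.position for x in ra.final_population])
        pb = np.array([x.position for x in rb.final_population])
        assert np.allclose(pa, pb, rtol=1e-9, atol=1e-9)
        ga = base.model.g * ra.elapsed_time**2
        gb = big.model.g * rb.elapsed_time**2
        assert ga == pytest.approx(gb, rel=1e-6)

    def test_rotational_equivariance_of_whole_run(self):
        cfg = standard_conditions(aib=100.0, seed=19)
        pos, m, M, ids, _ = initial_population(cfg.init, cfg.model)
        theta = np.deg2rad(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        stop = StopCriteria(tickstop=400)
        fa, _, recs_a, _ = simulate(pos, m, M, cfg.model, stop=stop)
        fb, _, recs_b, _ = simulate(pos @ rot.T, m, M, cfg.model, stop=stop)
        assert len(recs_a) == len(recs_b)
        pa = np.array([x.position for x in fa])
        pb = np.array([x.position for x in fb])
        assert np.allclose(pa @ rot.T, pb, atol=1e-6)

    def test_cr_robustness(self):
        """CR in {0.1, 0.2, 0.3}: same endpoint within 2 model units."""
        finals = {}
        for cr in (0.1, 0.2, 0.3):
            cfg = standard_conditions(aib=60.0, seed=23, coalescence_radius=cr)
            res = run(cfg)
            finals[cr] = np.array(
                sorted(
                    (tuple(a.position) for a in res.final_population),
                )
            )
        counts = {cr: len(f) for cr, f in finals.items()}
        assert len(set(counts.values())) == 1
        for cr in (0.1, 0.3):
            deltas = np.linalg.norm(finals[cr] - finals[0.2], axis=1)
            assert deltas.max() < 2.0

    def test_elapsed_time_grows_with_aib(self):
        """Larger confidence bounds stretch the repulsive end phase."""
        small = run(standard_conditions(aib=30.0, seed=61))
        large = run(standard_conditions(aib=180.0, seed=61))
        assert large.elapsed_time / small.elapsed_time > 2.0

    def test_elapsed_time_strictly_increasing(self):
        res = run(standard_conditions(aib=60.0, seed=29, tickstop=200))
        ets = [r.elapsed_time for r in res.records]
        assert all(b > a for a, b in zip(ets, ets[1:]))

    def test_bounded_step_throughout(self):
        """No agent ever moves farther than CR in one adaptive iteration.

        Persisting ids track their own motion (a merged group keeps its
        heaviest member's id and position), so frame-to-frame deltas are
        pure step displacements.
        """
        cfg = replace(
            standard_conditions(aib=60.0, seed=31, tickstop=150),
            record_trajectory=True,
        )
        res = run(cfg)
        prev = {a.id: np.array(a.position) for a in res.initial_population}
        cr = cfg.model.coalescence_radius
        per_frame_max = []
        for frame in res.trajectory:
            cur = {a["id"]: np.array(a["pos"]) for a in frame["agents"]}
            deltas = [
                np.linalg.norm(cur[i] - prev[i]) for i in cur if i in prev
            ]
            per_frame_max.append(max(deltas))
            prev = cur
        assert max(per_frame_max) <= cr + 1e-9
        # the largest move each iteration equals CR, except in frames
        # where the peak mover itself was absorbed into a group
        hit = np.isclose(per_frame_max, cr, rtol=1e-9).mean()
        assert hit > 0.5
        assert max(per_frame_max) == pytest.approx(cr, rel=1e-9)
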