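"""Exact SSA (direct method) and tau-leaping with critical reactions."""

import math

import numpy as np
import pytest

from stochpn import (
    LeapConfig,
    PetriNet,
    SSASimulator,
    build_birth_death,
    build_dependency_graph,
    build_ir_model,
    classify_critical,
    draw_waiting_time,
    is_enabled,
    propensity,
    run,
    select_reaction,
    select_tau_noncritical,
)
from stochpn.gillespie import max_firings
from stochpn.state import STATUS_DEAD
from .conftest import make_random_net


def _unimolecular_net():
    net = PetriNet()
    net.add_place("A")
    net.add_place("B")
    net.add_transition("T")
    net.add_arc("A", "T")
    net.add_arc("T", "B")
    return net


def _dimerization_net():
    net = PetriNet()
    net.add_place("A")
    net.add_place("B")
    net.add_transition("T")
    net.add_arc("A", "T", 2)
    net.add_arc("T", "B")
    return net


class TestPropensity:
    def test_bimolecular(self):
        net = PetriNet()
        for p in "AB":
            net.add_place(p)
        net.add_place("C")
        net.add_transition("T")
        net.add_arc("A", "T")
        net.add_arc("B", "T")
        net.add_arc("T", "C")
        assert propensity(net, {"A": 10, "B": 5}, "T", 0.1) == pytest.approx(5.0)

    def test_dimerization_counts_pairs(self):
        net = _dimerization_net()
        assert propensity(net, {"A": 4}, "T", 1.0) == pytest.approx(6.0)  # C(4,2)

    def test_insufficient_tokens_gives_zero(self):
        net = _dimerization_net()
        assert propensity(net, {"A": 1}, "T", 1.0) == 0.0

    def test_positive_iff_enabled_on_random_nets(self):
        """Def.-2 enablement and positive propensity coincide, constant
        places included."""
        for seed in range(150):
            net, m = make_random_net(seed)
            for t in net.transitions:
                r = propensity(net, m, t, 1.0)
                assert (r > 0) == is_enabled(net, m, t)


class TestDirectMethodPrimitives:
    def test_zero_uniform_gives_zero_wait(self):
        assert draw_waiting_time(5.0, 0.0) == 0.0

    def test_inversion_closed_form(self):
        assert draw_waiting_time(2.0, 1.0 - math.exp(-2.0)) == pytest.approx(1.0)

    def test_sample_mean(self):
        rng = np.random.default_rng(0)
        n, a0 = 100_000, 4.0
        draws = [draw_waiting_time(a0, rng.random()) for _ in range(n)]
        assert abs(np.mean(draws) - 0.25) < 3 * 0.25 / math.sqrt(n)

    def test_nonpositive_total_rate_rejected(self):
        with pytest.raises(ValueError):
            draw_waiting_time(0.0, 0.5)

    @pytest.mark.parametrize(
        "rates,u2,expected",
        [
            ((1.0, 1.0), 0.25, 0),
            ((1.0, 1.0), 0.75, 1),
            ((0.0, 2.0, 0.0), 0.01, 1),
            ((0.0, 2.0, 0.0), 0.99, 1),
        ],
    )
    def test_select_reaction_cumulative_inequality(self, rates, u2, expected):
        assert select_reaction(rates, u2) == expected

    def test_select_reaction_all_zero_rejected(self):
        with pytest.raises(ValueError):
            select_reaction([0.0, 0.0], 0.5)


class TestDependencyGraph:
    def test_chain_dependencies(self, chain_net):
        depends = build_dependency_graph(chain_net)
        assert "T2" in depends["T1"] and "T1" in depends["T1"]

    def test_disjoint_transitions_independent(self):
        net = PetriNet()
        for p in ("A", "B", "C", "D"):
            net.add_place(p)
        net.add_transition("T1")
        net.add_transition("T2")
        net.add_arc("A", "T1")
        net.add_arc("T1", "B")
        net.add_arc("C", "T2")
        net.add_arc("T2", "D")
        depends = build_dependency_graph(net)
        assert "T2" not in depends["T1"]

    def test_ir_graph_matches_place_overlap_scan(self):
        """Oracle: t' depends on t iff a pre-place of t' changes when t
        fires; brute force over the insulin-receptor net."""
        net, _ = build_ir_model()
        depends = build_dependency_graph(net)
        for t in net.transitions:
            pre = net.pre_arcs(t)
            post = net.post_arcs(t)
            changed = {
                p
                for p in set(pre) | set(post)
                if not net.is_constant(p) and post.get(p, 0) != pre.get(p, 0)
            }
            expected = {
                t2
                for t2 in net.transitions
                if set(net.pre_arcs(t2)) & changed
            }
            assert depends[t] == expected
        assert "Bind_Insulin" in depends["Diss_Insulin"]


class TestCriticalClassification:
    @pytest.mark.parametrize("tokens,critical", [(19, True), (20, False), (0, True)])
    def test_unimolecular_threshold(self, tokens, critical):
        net = _unimolecular_net()
        assert classify_critical(net, {"A": tokens}, "T", LeapConfig()) is critical

    def test_dimerization_floor(self):
        net = _dimerization_net()
        # floor(39/2) = 19 possible firings -> critical
        assert classify_critical(net, {"A": 39}, "T", LeapConfig())
        assert not classify_critical(net, {"A": 40}, "T", LeapConfig())
        # oracle: repeated firing until disabled
        m, fired = {"A": 39, "B": 0}, 0
        while is_enabled(net, m, "T"):
            m = {"A": m["A"] - 2, "B": m["B"] + 1}
            fired += 1
        assert fired == 19

    def test_source_transition_never_critical(self):
        net = PetriNet()
        net.add_place("A")
        net.add_transition("T")
        net.add_arc("T", "A")
        assert max_firings(net, {"A": 0}, "T") == math.inf
        assert not classify_critical(net, {"A": 0}, "T", LeapConfig())


class TestTauSelection:
    def test_no_noncritical_propensity_gives_infinity(self):
        net = _unimolecular_net()
        tau = select_tau_noncritical(net, {"A": 0}, {"T": 0.0}, ["T"], LeapConfig())
        assert tau == math.inf

    def test_bounds_relative_propensity_change(self):
        """Over the chosen leap the expected propensity drift stays within
        epsilon, checked by direct evaluation of the mean state change."""
        net = _unimolecular_net()
        m = {"A": 10_000, "B": 0}
        cfg = LeapConfig(epsilon=0.03)
        c = 1.0
        props = {"T": propensity(net, m, "T", c)}
        tau = select_tau_noncritical(net, m, props, ["T"], cfg)
        drift = props["T"] * tau  # expected A consumed during the leap
        new_prop = propensity(net, {"A": round(m["A"] - drift)}, "T", c)
        rel_change = abs(new_prop - props["T"]) / props["T"]
        assert rel_change <= cfg.epsilon * 1.05  # rounding slack only

    def test_halving_epsilon_never_increases_tau(self):
        net = _dimerization_net()
        m = {"A": 5000}
        props = {"T": propensity(net, m, "T", 0.01)}
        eps = 0.3
        prev = math.inf
        for _ in range(6):
            tau = select_tau_noncritical(net, m, props, ["T"], LeapConfig(epsilon=eps))
            assert tau <= prev
            prev = tau
            eps /= 2


def _time_weighted_mean(times, counts, burn_in):
    times = np.asarray(times)
    counts = np.asarray(counts, dtype=float)
    keep = times >= burn_in
    t = times[keep]
    x = counts[keep]
    w = np.diff(t)
    return float((x[:-1] * w).sum() / w.sum()), t, x


def _batch_se(t, x, n_batches=20):
    edges = np.linspace(t[0], t[-1], n_batches + 1)
    means = []
    for a, b in zip(edges[:-1], edges[1:]):
        keep = (t >= a) & (t <= b)
        tt, xx = t[keep], x[keep]
        if len(tt) > 1:
            w = np.diff(tt)
            means.append((xx[:-1] * w).sum() / w.sum())
    means = np.asarray(means)
    return float(means.std(ddof=1) / math.sqrt(len(means)))


class TestExactSSA:
    def test_immigration_death_stationary_mean(self):
        """Stationary occupancy of the immigration-death process is
        Poisson(c_birth/c_death); long-run time average within 3 batch-mean
        standard errors of 10."""
        net, setup = build_birth_death(1.0, 0.1, events=60_000, seed=2)
        traj = run(net, setup)
        mean, t, x = _time_weighted_mean(traj.times, [c[0] for c in traj.counts], burn_in=100.0)
        se = _batch_se(t, x)
        assert abs(mean - 10.0) < 3 * se

    def test_dependency_graph_is_pure_optimization(self):
        """With and without the dependency graph, identical RNG streams give
        bitwise-identical trajectories on three different nets."""
        nets = []
        bd_net, bd_setup = build_birth_death(1.0, 0.1, events=1000, seed=0)
        nets.append((bd_net, bd_setup.initial_marking(bd_net), bd_setup.rates, None, None))
        dim = _dimerization_net()
        nets.append((dim, {"A": 500, "B": 0}, {"T": 0.01}, None, None))
        ir_net, ir_setup = build_ir_model()
        nets.append(
            (
                ir_net,
                ir_setup.initial_marking(ir_net),
                ir_setup.rates,
                ir_setup.conversion(),
                ir_setup.compiled_constant_expressions(),
            )
        )
        for net, m, rates, ctx, exprs in nets:
            results = []
            for use_graph in (True, False):
                sim = SSASimulator(
                    net,
                    m,
                    rates,
                    np.random.default_rng(42),
                    conversion=ctx,
                    constant_exprs=exprs,
                    use_dependency_graph=use_graph,
                )
                states = []
                for _ in range(1000):
                    if not sim.step_exact():
                        break
                    states.append((sim.state.clock, dict(sim.state.marking)))
                results.append(states)
            assert results[0] == results[1]

    def test_dead_marking_terminates(self, chain_net):
        sim = SSASimulator(
            chain_net, {"A": 0, "B": 0, "C": 0}, {"T1": 1.0, "T2": 1.0},
            np.random.default_rng(0),
        )
        assert not sim.step_exact()
        assert sim.state.status == STATUS_DEAD

    def test_pure_death_extinction_time(self):
        """Mean extinction time of A -> 0 from n0 is sum_{j=1..n0} 1/(c j)."""
        net = PetriNet()
        net.add_place("A")
        net.add_transition("death")
        net.add_arc("A", "death")
        n0, c, reps = 30, 1.0, 400
        expected = sum(1.0 / (c * j) for j in range(1, n0 + 1))
        sd = math.sqrt(sum(1.0 / (c * j) ** 2 for j in range(1, n0 + 1)))
        times = []
        for seed in range(reps):
            sim = SSASimulator(net, {"A": n0}, {"death": c}, np.random.default_rng(seed))
            while sim.step_exact():
                pass
            times.append(sim.state.clock)
        assert abs(np.mean(times) - expected) < 3 * sd / math.sqrt(reps)

    def test_clock_strictly_increases(self):
        net, setup = build_birth_death(1.0, 0.1, events=500, seed=9)
        traj = run(net, setup)
        assert all(b > a for a, b in zip(traj.times, traj.times[1:]))


class TestTauLeaping:
    def test_only_critical_reactions_reduce_to_exact_ssa(self):
        """A net whose reactions are all critical is simulated exactly,
        with the identical RNG discipline as the direct method."""
        net = _unimolecular_net()
        runs = []
        for stepper in ("step_exact", "step_tau_leap"):
            sim = SSASimulator(net, {"A": 10, "B": 0}, {"T": 1.0}, np.random.default_rng(5))
            states = []
            while getattr(sim, stepper)():
                states.append((sim.state.clock, dict(sim.state.marking)))
            runs.append(states)
        assert runs[0] == runs[1]
        assert len(runs[0]) == 10

    def test_long_run_mean_matches_exact_ssa(self):
        """Both samplers target the same master equation: long-run means of
        the immigration-death count agree within 5%."""
        means = {}
        for mode in ("ssa", "tau"):
            net, setup = build_birth_death(100.0, 0.1, n0=1000, events=60_000, seed=6)
            setup.mode = mode
            traj = run(net, setup)
            means[mode], _, _ = _time_weighted_mean(
                traj.times, [c[0] for c in traj.counts], burn_in=10.0
            )
        assert means["tau"] == pytest.approx(means["ssa"], rel=0.05)

    def test_poisson_occurrence_mean_in_pure_leap(self):
        """A single non-critical reaction fires Poisson(r*tau1) times per
        leap; the empirical mean matches over repeated single leaps."""
        net = _unimolecular_net()
        c, n0 = 0.01, 100_000
        cfg = LeapConfig()
        counts = []
        sim0 = SSASimulator(net, {"A": n0, "B": 0}, {"T": c}, np.random.default_rng(0), leap=cfg)
        tau1 = select_tau_noncritical(net, sim0.state.marking, sim0.propensities(), ["T"], cfg)
        lam = c * n0 * tau1
        for seed in range(4000):
            sim = SSASimulator(net, {"A": n0, "B": 0}, {"T": c}, np.random.default_rng(seed), leap=cfg)
            assert sim.step_tau_leap()
            counts.append(sim.state.firing_counts.get("T", 0))
        se = math.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_never_goes_negative_on_stiff_dimerization(self):
        """1e4 leaps on a stiff birth/dimerization/decay net keep every
        count non-negative."""
        net = PetriNet()
        net.add_place("A")
        net.add_place("B")
        for t in ("birth", "dimerize", "decay"):
            net.add_transition(t)
        net.add_arc("birth", "A")
        net.add_arc("A", "dimerize", 2)
        net.add_arc("dimerize", "B")
        net.add_arc("B", "decay")
        rates = {"birth": 500.0, "dimerize": 5.0, "decay": 1.0}
        sim = SSASimulator(net, {"A": 10, "B": 0}, rates, np.random.default_rng(8))
        prev_clock = 0.0
        for _ in range(10_000):
            if not sim.step_tau_leap():
                break
            assert all(v >= 0 for v in sim.state.marking.values())
            assert sim.state.clock > prev_clock
            prev_clock = sim.state.clock
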