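"""Run orchestration, replicates, and TSV/XML/PNML persistence."""

import io as stringio
import math

import numpy as np
import pandas as pd
import pytest

from stochpn import (
    RateSpec,
    SimulationSetup,
    build_birth_death,
    build_ir_model,
    export_tsv,
    load_setup,
    read_pnml,
    run,
    run_replicates,
    save_setup,
    write_pnml,
)
from stochpn.io import PnmlFormatError, SetupFormatError
from stochpn.state import STATUS_DEAD


class TestRun:
    def test_fixed_seed_reproducibility(self):
        net, setup = build_birth_death(1.0, 0.1, events=2000, seed=42)
        a = run(net, setup)
        b = run(net, setup)
        assert a.times == b.times and a.counts == b.counts
        assert a.firing_counts == b.firing_counts

    def test_firing_counts_sum_to_step_count(self):
        net, setup = build_birth_death(1.0, 0.1, events=3000, seed=1)
        traj = run(net, setup)
        assert sum(traj.firing_counts.values()) == traj.step_count == 3000

    def test_dead_marking_truncates_run(self, chain_net):
        setup = SimulationSetup(
            mode="ssa",
            t_end=1e6,
            seed=0,
            initial_counts={"A": 2},
            rates={"T1": RateSpec.stochastic(1.0), "T2": RateSpec.stochastic(1.0)},
        )
        traj = run(chain_net, setup)
        assert traj.status == STATUS_DEAD
        assert traj.step_count == 4  # 2 tokens * 2 hops
        assert traj.final_marking() == {"A": 0, "B": 0, "C": 2}
        assert traj.times[-1] < 1e6

    def test_invalid_setup_rejected_before_simulation(self, chain_net):
        setup = SimulationSetup(mode="ssa", steps=10, initial_counts={"nope": 1},
                                rates={"T1": RateSpec.stochastic(1.0),
                                       "T2": RateSpec.stochastic(1.0)})
        with pytest.raises(ValueError, match="nope"):
            run(chain_net, setup)
        with pytest.raises(ValueError, match="mode"):
            run(chain_net, SimulationSetup(mode="warp", steps=1))

    def test_first_record_is_initial_marking(self):
        net, setup = build_birth_death(1.0, 0.1, n0=7, events=10, seed=0)
        traj = run(net, setup)
        assert traj.times[0] == 0.0 and traj.marking_at(0) == {"A": 7}


class TestReplicates:
    def test_pair_reproducible_from_master_seed(self):
        net, setup = build_birth_death(1.0, 0.1, events=500)
        r1 = run_replicates(net, setup, 2, master_seed=99)
        r2 = run_replicates(net, setup, 2, master_seed=99)
        for a, b in zip(r1.trajectories, r2.trajectories):
            assert a.times == b.times and a.counts == b.counts
        # different replicates differ
        assert r1.trajectories[0].times != r1.trajectories[1].times

    def test_replicate_count_bounds(self):
        net, setup = build_birth_death(1.0, 0.1, events=10)
        with pytest.raises(ValueError):
            run_replicates(net, setup, 0, master_seed=0)
        with pytest.raises(ValueError):
            run_replicates(net, setup, 501, master_seed=0)

    def test_stationary_mean_across_replicates(self):
        """Final counts of 100 replicates at stationarity average to the
        analytic mean c_birth/c_death within 3 standard errors."""
        net, setup = build_birth_death(1.0, 0.1, events=2000, seed=0)
        result = run_replicates(net, setup, 100, master_seed=5)
        finals = np.array([tr.final_marking()["A"] for tr in result.trajectories])
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - 10.0) < 3 * se

    def test_summary_grid(self):
        net, setup = build_birth_death(1.0, 0.1, events=200)
        result = run_replicates(net, setup, 5, master_seed=1)
        summary = result.summary(np.linspace(0, 10, 11))
        assert list(summary.columns) == ["time", "A_mean", "A_sd"]
        assert len(summary) == 11


class TestTsvExport:
    def test_header_plus_one_row_per_record(self, tmp_path):
        net, setup = build_birth_death(1.0, 0.1, events=2, seed=0)
        traj = run(net, setup)  # initial + 2 events = 3 records
        dest = tmp_path / "traj.tsv"
        export_tsv(traj, dest)
        lines = dest.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0].split("\t") == ["time", "fired", "A"]

    def test_round_trip_preserves_counts_exactly(self, tmp_path):
        net, setup = build_birth_death(1.0, 0.1, events=50, seed=3)
        traj = run(net, setup)
        dest = tmp_path / "traj.tsv"
        export_tsv(traj, dest)
        frame = pd.read_csv(dest, sep="\t")
        assert frame["A"].tolist() == [c[0] for c in traj.counts]

    def test_empty_trajectory_rejected(self):
        from stochpn.state import Trajectory

        with pytest.raises(ValueError):
            export_tsv(Trajectory(places=["A"]), stringio.StringIO())


class TestSetupXml:
    def test_ir_setup_round_trips(self, tmp_path):
        _, setup = build_ir_model()
        dest = tmp_path / "setup.xml"
        save_setup(setup, str(dest))
        loaded = load_setup(str(dest))
        assert loaded == setup

    def test_missing_volume_with_concentrations(self, tmp_path):
        text = """<?xml version='1.0' encoding='utf-8'?>
<simulation-setup mode="ssa" seed="1" replicates="1">
  <end steps="10"/>
  <places><place name="A" concentration="1e-9"/></places>
</simulation-setup>"""
        p = tmp_path / "bad.xml"
        p.write_text(text)
        with pytest.raises(SetupFormatError, match="volume"):
            load_setup(str(p))

    def test_unknown_element_rejected_not_ignored(self, tmp_path):
        text = """<?xml version='1.0' encoding='utf-8'?>
<simulation-setup mode="ssa" seed="1" replicates="1">
  <end steps="10"/>
  <mystery/>
</simulation-setup>"""
        p = tmp_path / "bad.xml"
        p.write_text(text)
        with pytest.raises(SetupFormatError, match="mystery"):
            load_setup(str(p))

    def test_byte_stable_output(self, tmp_path):
        _, setup = build_ir_model()
        a, b = tmp_path / "a.xml", tmp_path / "b.xml"
        save_setup(setup, str(a))
        save_setup(setup, str(b))
        assert a.read_bytes() == b.read_bytes()


class TestPnml:
    def test_ir_net_round_trips(self, tmp_path):
        net, setup = build_ir_model()
        marking = setup.initial_marking(net)
        exprs = setup.constant_expressions
        dest = tmp_path / "ir.pnml"
        write_pnml(net, marking, str(dest), constant_expressions=exprs)
        net2, marking2, exprs2 = read_pnml(str(dest))
        assert net2.places == net.places
        assert net2.transitions == net.transitions
        assert exprs2 == exprs
        for t in net.transitions:
            assert net2.pre_arcs(t) == net.pre_arcs(t)
            assert net2.post_arcs(t) == net.post_arcs(t)
        for p in net.places:
            assert net2.is_constant(p) == net.is_constant(p)
            assert marking2[p] == marking[p]

    def test_arc_without_inscription_defaults_to_weight_one(self, tmp_path):
        text = """<?xml version='1.0'?>
<pnml xmlns="http://www.pnml.org/version-2009/grammar/pnml">
 <net id="n" type="http://www.pnml.org/version-2009/grammar/ptnet">
  <page id="p">
   <place id="A"/><transition id="T"/>
   <arc id="a1" source="A" target="T"/>
  </page>
 </net>
</pnml>"""
        p = tmp_path / "min.pnml"
        p.write_text(text)
        net, marking, _ = read_pnml(str(p))
        assert net.pre_arcs("T") == {"A": 1}
        assert marking == {"A": 0}

    def test_unsupported_net_type_rejected(self, tmp_path):
        text = """<?xml version='1.0'?>
<pnml xmlns="http://www.pnml.org/version-2009/grammar/pnml">
 <net id="n" type="http://www.pnml.org/version-2009/grammar/symmetricnet">
  <page id="p"/>
 </net>
</pnml>"""
        p = tmp_path / "colored.pnml"
        p.write_text(text)
        with pytest.raises(PnmlFormatError, match="unsupported"):
            read_pnml(str(p))
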