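"""Tests for the hybrid trajectory generator and FBA coupling."""

import json
import math

import numpy as np
import pytest

from qsspn.fixtures import (build_birth_death, build_gene_expression_fixture,
                            build_immediate_livelock)
from qsspn.petri import ActivityTable, Edge, NetState, PetriNet, Place, Transition
from qsspn.simulate import (LivelockError, QsspnModel, SimulationConfig, Simulator,
                            run_ensemble, simulate)


def make_sim(model, seed=0, **cfg):
    return Simulator(model, SimulationConfig(seed=seed, **cfg))


class TestSettleImmediate:
    def test_transcription_runs_to_inhibitory_stop(self, gene_model):
        sim = make_sim(gene_model)
        state = gene_model.net.initial_state()
        state.tokens.update({"Active_Gene": 1, "dNTPs": 1, "AAs": 1})
        state = sim.settle_immediate(state)
        assert state.tokens["mRNA"] == 2  # two-token maximum, then propensity 0
        assert state.tokens["Protein"] == 2

    def test_no_enabled_immediates_is_noop(self):
        model = build_birth_death().model
        sim = make_sim(model)
        state = model.net.initial_state()
        assert sim.settle_immediate(state).tokens == state.tokens

    def test_two_immediate_cycle_raises_livelock(self):
        model = build_immediate_livelock()
        sim = Simulator(model, SimulationConfig(max_immediate_iterations=500))
        with pytest.raises(LivelockError) as err:
            sim.settle_immediate(model.net.initial_state())
        assert "a_to_b" in str(err.value) or "b_to_a" in str(err.value)


class TestSampleStochasticEvent:
    def test_selection_proportional_to_propensity(self):
        net = PetriNet(
            places=[Place("x", tokens=1, capacity=1)],
            transitions=[
                Transition("fast", "stochastic", 3.0, post=(Edge("x"),)),
                Transition("slow", "stochastic", 1.0, post=(Edge("x"),))])
        sim = make_sim(QsspnModel(net=net), seed=7)
        state = net.initial_state()
        picks = [sim.sample_stochastic_event(state)[0].id for _ in range(4000)]
        frac_fast = picks.count("fast") / len(picks)
        assert frac_fast == pytest.approx(0.75, abs=0.03)

    def test_all_zero_propensity_returns_none(self):
        net = PetriNet(places=[Place("x", tokens=0, capacity=1)],
                       transitions=[Transition("t", "stochastic", 1.0,
                                               pre=(Edge("x", "standard"),))])
        sim = make_sim(QsspnModel(net=net))
        trans, wait = sim.sample_stochastic_event(net.initial_state())
        assert trans is None and wait == math.inf

    def test_waiting_times_exponential_in_total_propensity(self):
        net = PetriNet(places=[Place("x", tokens=1, capacity=1)],
                       transitions=[Transition("t", "stochastic", 2.5,
                                               pre=(Edge("x", "read",
                                                         table=ActivityTable.step(1)),))])
        sim = make_sim(QsspnModel(net=net), seed=11)
        state = net.initial_state()
        waits = np.array([sim.sample_stochastic_event(state)[1] for _ in range(2000)])
        assert waits.mean() == pytest.approx(1 / 2.5, rel=0.1)


def continuous_model(rate, source_tokens=10, sink_cap=10):
    net = PetriNet(
        places=[Place("s", tokens=source_tokens, capacity=100),
                Place("d", tokens=0, capacity=sink_cap)],
        transitions=[Transition("flow", "continuous", rate,
                                pre=(Edge("s", "standard", table=ActivityTable.step(1)),),
                                post=(Edge("d"),))])
    return QsspnModel(net=net)


class TestApplyContinuous:
    def test_whole_tokens_move(self):
        model = continuous_model(2.0)
        sim = make_sim(model)
        acc = {}
        state = sim.apply_continuous(model.net.initial_state(), 0.5, acc)
        assert state.tokens["d"] == 1  # propensity 2 x dt 0.5

    def test_fractional_carry_accumulates(self):
        model = continuous_model(0.4)
        sim = make_sim(model)
        acc = {}
        state = model.net.initial_state()
        moved = []
        for _ in range(5):
            state = sim.apply_continuous(state, 0.5, acc)
            moved.append(state.tokens["d"])
        assert moved == [0, 0, 0, 0, 1]  # 5 x 0.2 accumulates to one token

    def test_substrate_exhaustion_clamps(self):
        model = continuous_model(100.0, source_tokens=3)
        sim = make_sim(model)
        state = sim.apply_continuous(model.net.initial_state(), 1.0, {})
        assert state.tokens["s"] == 0 and state.tokens["d"] == 3


class TestRefreshCouplings:
    def test_constraint_change_updates_objective_place(self, gene_model):
        sim = make_sim(gene_model)
        state = gene_model.net.initial_state()
        sim.refresh_couplings(state)
        assert state.tokens["agonist"] == 0  # enzyme closed at Protein=0
        assert state.tokens["dNTPs"] == 1 and state.tokens["AAs"] == 1
        state.tokens["Protein"] = 2
        sim.refresh_couplings(state)
        assert state.tokens["agonist"] == 1  # bound opened, objective crossed 1e-3

    def test_unchanged_constraints_hit_cache(self, gene_model):
        sim = make_sim(gene_model)
        state = gene_model.net.initial_state()
        sim.refresh_couplings(state)
        calls = sim.couplings.fba_calls
        for _ in range(5):
            sim.refresh_couplings(state)
        assert sim.couplings.fba_calls == calls

    def test_fba_calls_bounded_by_distinct_override_maps(self, gene_model):
        sim = make_sim(gene_model)
        state = gene_model.net.initial_state()
        for level in [0, 1, 2, 1, 0, 2, 2, 0]:
            state.tokens["Protein"] = level
            sim.refresh_couplings(state)
        # two distinct override maps (enzyme closed / open) x three objectives
        assert sim.couplings.fba_calls <= 2 * 3


class TestSimulate:
    def test_no_enabled_transitions_gives_flat_trajectory(self):
        net = PetriNet(places=[Place("x", tokens=1, capacity=1)],
                       transitions=[Transition("t", "stochastic", 0.0,
                                               pre=(Edge("x", "standard"),))])
        traj = simulate(QsspnModel(net=net), SimulationConfig(t_max=5.0, seed=0))
        assert traj.events == [] and traj.t_end == 5.0

    def test_identical_seed_gives_identical_trajectory(self, gene_model):
        cfg = SimulationConfig(t_max=10.0, seed=42)
        t1 = simulate(gene_model, cfg)
        t2 = simulate(gene_model, cfg)
        assert t1.events == t2.events and t1.initial_state == t2.initial_state

    def test_birth_death_stationary_mean(self):
        # M/M/inf-type process: stationary token mean is birth/death = 5
        doc = build_birth_death(birth_rate=5.0, death_rate=1.0, t_max=60.0)
        means = []
        for traj in run_ensemble(doc.model, SimulationConfig(t_max=60.0, seed=3), 20):
            grid = np.linspace(10.0, 60.0, 100)
            means.append(np.mean([traj.state_at(t)["X"] for t in grid]))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 5.0) < 3 * se + 1e-9

    def test_delayed_transition_fires_after_delay(self):
        net = PetriNet(
            places=[Place("a", tokens=1, capacity=1), Place("b", tokens=0, capacity=1)],
            transitions=[Transition("delayed", "stochastic", 100.0, delay=2.0,
                                    pre=(Edge("a", "standard"),), post=(Edge("b"),))])
        traj = simulate(QsspnModel(net=net), SimulationConfig(t_max=10.0, seed=1))
        (t_fire, place, tokens, source) = traj.events[-1]
        assert place == "b" and tokens == 1 and source == "delayed"
        assert t_fire > 2.0  # selection time + 2 a.u. delay

    def test_continuous_flow_in_full_simulation(self):
        model = continuous_model(2.0, source_tokens=10, sink_cap=10)
        traj = simulate(model, SimulationConfig(t_max=10.0, max_timestep=0.25, seed=0))
        assert traj.final_state["d"] == 10  # all tokens moved at rate ~2/a.u.

    def test_event_provenance_tags(self, gene_model):
        traj = simulate(gene_model, SimulationConfig(t_max=15.0, seed=5))
        for _t, place, _n, source in traj.events:
            kind = gene_model.net.places[place].kind
            if kind == "objective":
                assert source == "coupling"
            else:
                assert source != "coupling"

    def test_quiescence_after_every_event(self, gene_model):
        """No immediate transition is enabled at any recorded state."""
        from qsspn.petri import is_enabled
        traj = simulate(gene_model, SimulationConfig(t_max=10.0, seed=9))
        immediates = gene_model.net.transitions_of_klass("immediate")
        times = sorted({t for t, *_ in traj.events})
        sim = make_sim(gene_model)
        for t in times:
            state = NetState(traj.state_at(t), t)
            sim.refresh_couplings(state)  # couplings settled too
            enabled = [tr.id for tr in immediates if is_enabled(state, tr)]
            assert enabled == [], f"immediates {enabled} enabled at t={t}"


class TestRunEnsemble:
    def test_single_trajectory_matches_simulate_contract(self, gene_model):
        sample = run_ensemble(gene_model, SimulationConfig(t_max=5.0, seed=1), 1)
        assert len(sample) == 1 and not sample.errors

    def test_same_master_seed_identical_sets(self, gene_model):
        cfg = SimulationConfig(t_max=8.0, seed=123)
        s1 = run_ensemble(gene_model, cfg, 10)
        s2 = run_ensemble(gene_model, cfg, 10)
        assert [t.events for t in s1] == [t.events for t in s2]

    def test_trajectories_differ_across_streams(self, gene_model):
        sample = run_ensemble(gene_model, SimulationConfig(t_max=8.0, seed=123), 10)
        assert len({json.dumps(t.events) for t in sample}) > 1


class TestTrajectoryExport:
    def test_tsv_and_sidecar(self, gene_model, tmp_path):
        traj = simulate(gene_model, SimulationConfig(t_max=5.0, seed=2))
        path = tmp_path / "traj.tsv"
        traj.to_tsv(str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "time\tplace\ttokens\tsource"
        meta = json.loads((tmp_path / "traj.tsv.json").read_text())
        assert meta["t_end"] == 5.0 and "model_hash" in meta

    def test_grid_export_matches_state_at(self, gene_model):
        traj = simulate(gene_model, SimulationConfig(t_max=5.0, seed=2))
        frame = traj.to_grid(0.5)
        for t in frame.index:
            expected = traj.state_at(t)
            for place in frame.columns:
                assert frame.loc[t, place] == expected[place]
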