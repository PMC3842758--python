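"""Tests for behaviour detection, binomial statistics and the knockout screen."""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from qsspn.analysis import (BehaviourDefinition, Perturbation, behaviour_fraction,
                            clopper_pearson, compare, detect, encode_perturbation,
                            knockout_screen)
from qsspn.simulate import SimulationConfig, Trajectory, run_ensemble, simulate

from oracles import binomial_ci_exact_cdf


def trace(points, t_end=10.0, place="mRNA"):
    """Synthetic trajectory from (time, tokens) points; starts at the first."""
    first = points[0]
    events = [(t, place, n, "stochastic") for t, n in points[1:]]
    return Trajectory({place: first[1]}, events, t_end)


class TestDetect:
    def test_burst_on_rise_and_decay(self):
        traj = trace([(0, 0), (1, 1), (1.5, 2), (4, 1), (5, 0)])
        assert detect(traj, BehaviourDefinition("mRNA", "burst"))
        assert not detect(traj, BehaviourDefinition("mRNA", "activation"))

    def test_flat_trace_constant_not_activation(self):
        traj = trace([(0, 0)])
        assert detect(traj, BehaviourDefinition("mRNA", "constant"))
        assert not detect(traj, BehaviourDefinition("mRNA", "activation"))

    def test_sustained_rise_is_activation_not_burst(self):
        # hand-evaluated 5-event synthetic trace: reaches 2 and stays
        traj = trace([(0, 0), (0.5, 1), (1, 2), (2, 2), (3, 2)])
        assert detect(traj, BehaviourDefinition("mRNA", "activation"))
        assert not detect(traj, BehaviourDefinition("mRNA", "burst"))

    def test_activation_hold_flag(self):
        traj = trace([(0, 0), (1, 2), (5, 1)])
        assert not detect(traj, BehaviourDefinition("mRNA", "activation", hold_to_end=True))
        assert detect(traj, BehaviourDefinition("mRNA", "activation", hold_to_end=False))

    def test_inhibition(self):
        traj = trace([(0, 2), (2, 1), (3, 0)])
        assert detect(traj, BehaviourDefinition("mRNA", "inhibition", lower=0))

    def test_constant_with_equilibration_offset(self):
        traj = trace([(0, 0), (0.5, 2), (9, 2)])
        assert detect(traj, BehaviourDefinition("mRNA", "constant", equilibration=1.0))

    def test_window_restricts_activation(self):
        traj = trace([(0, 0), (8, 2)])
        assert not detect(traj, BehaviourDefinition("mRNA", "activation", window=(0, 5)))

    def test_custom_predicate(self):
        traj = trace([(0, 0), (1, 2)])
        beh = BehaviourDefinition("mRNA", "custom",
                                  predicate=lambda t, x: bool(x.max() == 2))
        assert detect(traj, beh)

    def test_fixture_mrna_trace_is_burst(self, gene_model):
        traj = simulate(gene_model, SimulationConfig(t_max=30.0, seed=1))
        assert detect(traj, BehaviourDefinition("mRNA", "burst"))

    def test_grid_invariance(self, gene_model):
        """Event-mode and fine fixed-grid exports give identical verdicts."""
        traj = simulate(gene_model, SimulationConfig(t_max=20.0, seed=4))
        times = sorted({t for t, *_ in traj.events})
        min_gap = min(np.diff(times)) if len(times) > 1 else 1.0
        grid_dt = min(min_gap / 2, 0.01)
        frame = traj.to_grid(grid_dt)
        for place in ("mRNA", "Protein", "agonist"):
            gridded = trace([(float(t), int(frame.loc[t, place])) for t in frame.index],
                            t_end=traj.t_end, place=place)
            for pattern in ("activation", "burst", "constant", "inhibition"):
                beh = BehaviourDefinition(place, pattern)
                assert detect(traj, beh) == detect(gridded, beh)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n", [(0, 20), (20, 20), (60, 120), (1, 120), (119, 120)])
    def test_matches_exact_binomial_cdf_oracle(self, k, n):
        low, high = clopper_pearson(k, n)
        o_low, o_high = binomial_ci_exact_cdf(k, n)
        assert low == pytest.approx(o_low, abs=1e-7)
        assert high == pytest.approx(o_high, abs=1e-7)

    def test_matches_statsmodels_beta_interval(self):
        for k, n in [(0, 120), (60, 120), (120, 120), (7, 33)]:
            low, high = clopper_pearson(k, n)
            s_low, s_high = proportion_confint(k, n, alpha=0.05, method="beta")
            assert low == pytest.approx(float(s_low), abs=1e-10)
            assert high == pytest.approx(float(s_high), abs=1e-10)

    def test_degenerate_fractions(self):
        low, high = clopper_pearson(0, 20)
        assert low == 0.0 and high < 1.0
        low, high = clopper_pearson(120, 120)
        assert high == 1.0 and low > 0.9


class TestBehaviourFraction:
    def test_counts_and_ci(self, gene_model):
        sample = run_ensemble(gene_model, SimulationConfig(t_max=20.0, seed=2), 20)
        bf = behaviour_fraction(sample, BehaviourDefinition("mRNA", "burst"))
        assert bf.n_trajectories == 20
        assert bf.fraction == bf.n_positive / 20
        assert bf.ci95[0] <= bf.fraction <= bf.ci95[1]


class TestCompare:
    def test_extreme_fractions_significant(self):
        beh = BehaviourDefinition("x", "activation")
        from qsspn.analysis import BehaviourFraction
        a = BehaviourFraction(beh, 120, 0, 0.0, clopper_pearson(0, 120))
        b = BehaviourFraction(beh, 120, 120, 1.0, clopper_pearson(120, 120))
        assert compare(a, b) and compare(b, a)

    def test_identical_fractions_not_significant(self):
        beh = BehaviourDefinition("x", "activation")
        from qsspn.analysis import BehaviourFraction
        a = BehaviourFraction(beh, 120, 60, 0.5, clopper_pearson(60, 120))
        assert not compare(a, a)

    def test_moderate_difference_decided_by_ci_overlap(self):
        from qsspn.analysis import BehaviourFraction
        beh = BehaviourDefinition("x", "activation")
        a = BehaviourFraction(beh, 120, 50, 50 / 120, clopper_pearson(50, 120))
        b = BehaviourFraction(beh, 120, 70, 70 / 120, clopper_pearson(70, 120))
        # oracle CIs: [0.325, 0.510] vs [0.490, 0.676] overlap -> not significant
        assert binomial_ci_exact_cdf(50, 120)[1] > binomial_ci_exact_cdf(70, 120)[0]
        assert not compare(a, b)


class TestEncodePerturbation:
    def test_force_level_holds_constant(self, gene_model):
        forced = encode_perturbation(gene_model, Perturbation("force_level", "Protein", level=2))
        traj = simulate(forced, SimulationConfig(t_max=15.0, seed=3))
        times, tokens = traj.timecourse("Protein")
        assert np.all(tokens == 2)

    def test_sirna_knockdown_abolishes_expression(self, gene_model):
        perturbed = encode_perturbation(
            gene_model, Perturbation("sirna_knockdown", "mRNA", translation="translation"))
        assert "mRNA_siRNA" in perturbed.net.places
        deg = perturbed.net.transitions["mRNA_siRNA_degradation"]
        assert deg.rate == 1000.0
        sample = run_ensemble(perturbed, SimulationConfig(t_max=20.0, seed=6), 20)
        prot_max = max(max(t.timecourse("Protein")[1]) for t in sample)
        assert prot_max == 0  # translation inhibited; transcript destroyed at rate 1000

    def test_gene_deletion_zeroes_tokens(self, gene_model):
        deleted = encode_perturbation(gene_model, Perturbation("gene_deletion", "Gene"))
        assert deleted.net.places["Gene"].tokens == 0
        assert gene_model.net.places["Gene"].tokens == 1  # input untouched

    def test_unknown_place_rejected(self, gene_model):
        with pytest.raises(KeyError):
            encode_perturbation(gene_model, Perturbation("gene_deletion", "ghost"))


class TestKnockoutScreen:
    def test_gene_deletion_abolishes_transcription(self, gene_model):
        beh = BehaviourDefinition("mRNA", "activation", hold_to_end=False,
                                  name="mRNA reaches 2")
        matrix = knockout_screen(gene_model, ["Gene"], [beh],
                                 SimulationConfig(t_max=15.0, seed=7), n=30)
        wt = matrix.rows["WT"]["mRNA reaches 2"]
        ko = matrix.rows["Gene"]["mRNA reaches 2"]
        assert wt.fraction == 1.0 and ko.fraction == 0.0
        assert matrix.significant["Gene"]["mRNA reaches 2"]

    def test_empty_gene_list_gives_wt_only(self, gene_model):
        beh = BehaviourDefinition("mRNA", "burst")
        matrix = knockout_screen(gene_model, [], [beh],
                                 SimulationConfig(t_max=10.0, seed=7), n=5)
        assert list(matrix.rows) == ["WT"]

    def test_wt_row_equals_plain_ensemble(self, gene_model):
        """Screen WT row reproduces the unperturbed ensemble exactly."""
        beh = BehaviourDefinition("mRNA", "burst")
        cfg = SimulationConfig(t_max=10.0, seed=8)
        matrix = knockout_screen(gene_model, [], [beh], cfg, n=10)
        direct = behaviour_fraction(run_ensemble(gene_model, cfg, 10), beh)
        cell = matrix.rows["WT"][beh.label]
        assert (cell.n_positive, cell.fraction) == (direct.n_positive, direct.fraction)

    def test_matrix_export(self, gene_model, tmp_path):
        beh = BehaviourDefinition("mRNA", "burst")
        matrix = knockout_screen(gene_model, ["Gene"], [beh],
                                 SimulationConfig(t_max=10.0, seed=7), n=5)
        out = tmp_path / "matrix.tsv"
        matrix.to_tsv(str(out))
        lines = out.read_text().splitlines()
        assert lines[0] == "row\tbehaviour\tfraction\tci_low\tci_high\tsignificant"
        assert len(lines) == 3  # WT + Gene

    def test_monotone_stimulus(self, gene_model):
        """Forcing an activator to max never lowers its target's max-fraction."""
        beh = BehaviourDefinition("mRNA", "activation", hold_to_end=False)
        cfg = SimulationConfig(t_max=15.0, seed=9)
        wt = behaviour_fraction(run_ensemble(gene_model, cfg, 20), beh)
        forced_model = encode_perturbation(
            gene_model, Perturbation("permanent_activation", "Active_Gene"))
        forced = behaviour_fraction(run_ensemble(forced_model, cfg, 20), beh)
        assert forced.fraction >= wt.fraction
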