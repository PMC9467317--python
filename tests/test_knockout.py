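"""In-silico knockouts: affected sets, matrices, rankings, presets."""

import itertools

import pytest

from ptnet.invariants import place_invariants, transition_invariants
from ptnet.manatee import ManateeInvariant, manatee_invariants
from ptnet.knockout import (
    ConfigurationError,
    KnockoutExperiment,
    knockout_affected,
    knockout_matrix,
    matrix_to_csv,
    multiple_knockout_preset,
    rank_proteins,
)
from ptnet.net import PetriNet, UnknownIdError
from ptnet.synth import MotifSpec, generate_motif_net


def three_branch_net() -> PetriNet:
    """One synthesis feeding a branch point with three output routes."""
    net = PetriNet("branch")
    net.add_place("S")
    net.add_place("A")
    net.add_place("B")
    net.add_transition("syn")
    net.add_arc("syn", "S")
    net.add_transition("toA")
    net.add_arc("S", "toA")
    net.add_arc("toA", "A")
    net.add_transition("toB")
    net.add_arc("S", "toB")
    net.add_arc("toB", "B")
    net.add_transition("degS")
    net.add_arc("S", "degS")
    net.add_transition("degA")
    net.add_arc("A", "degA")
    net.add_transition("degB")
    net.add_arc("B", "degB")
    return net


def analyse(net):
    tis = transition_invariants(net)
    pis = place_invariants(net)
    mis = manatee_invariants(net, tis, pis=pis).mis
    return tis, pis, mis


class TestAffected:
    def test_unknown_transition_raises(self, chain_net):
        _, _, mis = analyse(chain_net)
        with pytest.raises(UnknownIdError):
            knockout_affected(
                chain_net, mis, KnockoutExperiment.single("nope")
            )

    def test_non_synthesis_transition_rejected(self, cycle_net):
        _, _, mis = analyse(cycle_net)
        with pytest.raises(ConfigurationError):
            knockout_affected(cycle_net, mis, KnockoutExperiment.single("t"))

    def test_knockout_of_uninvolved_transition_affects_nothing(self):
        net = three_branch_net()
        net.add_place("iso")
        net.add_transition("syn_iso")
        net.add_arc("syn_iso", "iso")  # iso never consumed: in no MI
        _, _, mis = analyse(net)
        aff = knockout_affected(net, mis, KnockoutExperiment.single("syn_iso"))
        assert aff == set()

    def test_matches_delete_and_recompute(self):
        """MI-based affected places equal recomputing MIs on the net with
        the knocked transition physically deleted."""
        net = three_branch_net()
        _, pis, mis = analyse(net)
        for knocked in net.input_transitions():
            aff = knockout_affected(
                net, mis, KnockoutExperiment.single(knocked)
            )
            covered = set()
            for mi in mis:
                covered |= net.induced_places(mi.support)
            reduced = net.without_transitions([knocked])
            _, _, mis2 = analyse(reduced)
            surviving = set()
            for mi in mis2:
                surviving |= reduced.induced_places(mi.support)
            assert aff == covered - surviving


class TestMatrix:
    def test_empty_experiment_list_rejected(self, chain_net):
        _, pis, mis = analyse(chain_net)
        with pytest.raises(ConfigurationError):
            knockout_matrix(chain_net, mis, experiments=[], pis=pis)

    def test_default_rows_and_pi_column_exclusion(self, gene_motif_net):
        tis, pis, mis = analyse(gene_motif_net)
        mat = knockout_matrix(gene_motif_net, mis, pis=pis)
        assert [e.name for e in mat.rows] == ["syn_TF"]
        # conserved gene places are excluded from the columns
        assert "g" not in mat.columns and "TFg" not in mat.columns

    def test_monotonicity_under_experiment_union(self):
        net, _ = generate_motif_net(
            [MotifSpec("complex_formation"), MotifSpec("feedback_loop")],
            seed=3,
        )
        _, pis, mis = analyse(net)
        singles = [
            KnockoutExperiment.single(t) for t in net.input_transitions()
        ]
        for a, b in itertools.combinations(singles, 2):
            union = KnockoutExperiment(
                "u", a.knocked_transitions | b.knocked_transitions
            )
            aff_u = knockout_affected(net, mis, union)
            assert aff_u >= knockout_affected(net, mis, a)
            assert aff_u >= knockout_affected(net, mis, b)

    def test_direct_product_place_always_affected(self):
        net = three_branch_net()
        _, pis, mis = analyse(net)
        aff = knockout_affected(net, mis, KnockoutExperiment.single("syn"))
        assert "S" in aff

    def test_csv_export(self, tmp_path):
        net = three_branch_net()
        _, pis, mis = analyse(net)
        mat = knockout_matrix(net, mis, pis=pis)
        out = tmp_path / "m.csv"
        matrix_to_csv(mat, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].split(",")[0] == "experiment"
        assert len(lines) == 1 + len(mat.rows)


class TestRanking:
    def test_manual_count_on_small_fixture(self):
        """Fractions equal hand counts over a five-MI list."""
        net = PetriNet()
        for p in ("A", "B"):
            net.add_place(p)
        for t in ("sa", "sb", "da", "db"):
            net.add_transition(t)
        net.add_arc("sa", "A")
        net.add_arc("A", "da")
        net.add_arc("sb", "B")
        net.add_arc("B", "db")
        mis = [
            ManateeInvariant({0: 1}, {"sa": 1, "da": 1}, []),
            ManateeInvariant({0: 1}, {"sa": 2, "da": 2}, []),
            ManateeInvariant({1: 1}, {"sb": 1, "db": 1}, []),
            ManateeInvariant({1: 1}, {"sb": 2, "db": 2}, []),
            ManateeInvariant({0: 1, 1: 1}, {"sa": 1, "da": 1, "sb": 1, "db": 1}, []),
        ]
        mat = knockout_matrix(
            net, mis,
            experiments=[KnockoutExperiment.single("sa"),
                         KnockoutExperiment.single("sb")],
        )
        rank = rank_proteins(mat, mis)
        fractions = rank.as_dict()
        assert fractions["sa"]["mi_fraction"] == pytest.approx(3 / 5)
        assert fractions["sb"]["mi_fraction"] == pytest.approx(3 / 5)
        # tie broken lexicographically
        assert [e[0] for e in rank.entries] == ["sa", "sb"]

    def test_protein_in_no_mi_ranks_last_with_zero(self):
        net = three_branch_net()
        net.add_place("iso")
        net.add_transition("syn_iso")
        net.add_arc("syn_iso", "iso")
        _, pis, mis = analyse(net)
        mat = knockout_matrix(net, mis, pis=pis)
        rank = rank_proteins(mat, mis)
        assert rank.entries[-1][0] == "syn_iso"
        assert rank.entries[-1][1] == 0.0


class TestPresets:
    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            multiple_knockout_preset("nope", {"a": ["t"]})

    def test_singleton_preset_equals_single_knockout(self):
        net = three_branch_net()
        _, pis, mis = analyse(net)
        exp = multiple_knockout_preset("solo", {"solo": ["syn"]})
        assert knockout_affected(net, mis, exp) == knockout_affected(
            net, mis, KnockoutExperiment.single("syn")
        )
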