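"""Manatee invariants: realizable TI combinations and outcome labels."""

import pytest

from ptnet.invariants import place_invariants, transition_invariants
from ptnet.manatee import (
    ManateeInvariant,
    OutcomeRules,
    classification_summary,
    classify_mi,
    classify_ti,
    manatee_invariants,
)
from ptnet.net import Marking, PetriNet


@pytest.fixture
def pc_analysis(provider_consumer_net):
    net = provider_consumer_net
    tis = transition_invariants(net)
    res = manatee_invariants(net, tis, pis=place_invariants(net))
    return net, tis, res


class TestProviderConsumer:
    def test_ti_structure(self, pc_analysis):
        net, tis, _ = pc_analysis
        assert sorted(sorted(t.support) for t in tis) == [
            ["act", "out_x", "syn_a"],
            ["borrow", "deg_d", "ret", "syn_c"],
        ]

    def test_mi_set_is_provider_and_provider_plus_consumer(self, pc_analysis):
        """The catalytic consumer is a dissected pathway: it only appears
        combined with the provider; the provider stands alone."""
        net, tis, res = pc_analysis
        supports = sorted(sorted(mi.support) for mi in res.mis)
        assert supports == sorted(
            [
                ["act", "out_x", "syn_a"],
                ["act", "borrow", "deg_d", "out_x", "ret", "syn_a", "syn_c"],
            ]
        )

    def test_exhaustive_combination_oracle(self, pc_analysis):
        """Independent check: enumerate every TI multiset with coefficients
        <= 2 and test realizability directly; the minimal realizable
        combinations per anchor TI must equal the MI set."""
        net, tis, res = pc_analysis
        from itertools import product

        realizable = []
        for coeffs in product(range(3), repeat=len(tis)):
            if not any(coeffs):
                continue
            parikh: dict[str, int] = {}
            for c, ti in zip(coeffs, tis):
                for t, v in ti.coefficients:
                    parikh[t] = parikh.get(t, 0) + c * v
            if net.realize_parikh(parikh, Marking()).realized:
                realizable.append(coeffs)
        minimal = []
        for anchor in range(len(tis)):
            anchored = [c for c in realizable if c[anchor]]
            for c in anchored:
                if not any(
                    o != c and all(a <= b for a, b in zip(o, c))
                    for o in anchored
                ):
                    if c not in minimal:
                        minimal.append(c)
        got = sorted(tuple(sorted(mi.ti_coefficients.items())) for mi in res.mis)
        exp = sorted(
            tuple((i, v) for i, v in enumerate(c) if v) for c in minimal
        )
        assert got == exp

    def test_witness_replays_to_initial_marking(self, pc_analysis):
        net, _, res = pc_analysis
        for mi in res.mis:
            m = net.initial_marking.copy()
            for t in mi.witness:
                m = net.fire(m, t)
            assert m == net.initial_marking

    def test_parikh_in_ti_cone(self, pc_analysis):
        import numpy as np

        net, tis, res = pc_analysis
        C = net.incidence_matrix().astype(object)
        order = net.transition_ids
        for mi in res.mis:
            vec = np.array([mi.parikh.get(t, 0) for t in order], dtype=object)
            assert not np.any(C @ vec)

    def test_singleton_mis_equal_complete_tis(self, pc_analysis):
        net, tis, res = pc_analysis
        singles = {
            next(iter(mi.ti_coefficients)) for mi in res.mis if mi.is_singleton
        }
        complete = {
            i for i, ti in enumerate(tis)
            if classify_ti(net, ti, res.mis, tis=tis) in ("complete", "trivial")
        }
        assert singles == complete

    def test_anchored_minimality(self, pc_analysis):
        """Every MI is minimal for some anchor TI: a TI it contains such
        that no proper sub-combination still containing that TI is
        realizable."""
        from itertools import chain, combinations

        net, tis, res = pc_analysis

        def realizable(idxs):
            parikh: dict[str, int] = {}
            for j in idxs:
                for t, v in tis[j].coefficients:
                    parikh[t] = parikh.get(t, 0) + v
            return net.realize_parikh(parikh, Marking()).realized

        for mi in res.mis:
            members = sorted(mi.ti_coefficients)
            anchored = False
            for anchor in members:
                subsets = chain.from_iterable(
                    combinations([m for m in members if m != anchor], r)
                    for r in range(len(members) - 1)
                )
                if not any(realizable(set(s) | {anchor}) for s in subsets):
                    anchored = True
                    break
            assert anchored

    def test_trivial_vs_complete_vs_dissected(self):
        net = PetriNet()
        net.add_place("N")
        net.add_transition("syn")
        net.add_transition("deg")
        net.add_arc("syn", "N")
        net.add_arc("N", "deg")
        tis = transition_invariants(net)
        res = manatee_invariants(net, tis)
        assert classify_ti(net, tis[0], res.mis, tis=tis) == "trivial"

    def test_consumer_alone_is_dissected(self, pc_analysis):
        net, tis, res = pc_analysis
        consumer = next(
            i for i, ti in enumerate(tis) if "borrow" in ti.support
        )
        assert classify_ti(net, tis[consumer], res.mis, tis=tis) == "dissected"


class TestOutcomeRules:
    def _mi(self, support):
        return ManateeInvariant({0: 1}, {t: 1 for t in support}, [])

    @pytest.fixture
    def rules(self):
        return OutcomeRules(
            response_outputs={
                "Apoptosis": "apoptosis",
                "Necroptosis": "necroptosis",
                "Survival": "survival",
            },
            resolution_rules=[
                {
                    "requires_transitions": ["momp_block", "extr_casp3"],
                    "requires_labels": ["apoptosis"],
                    "label": "apoptosis",
                }
            ],
        )

    def test_single_output(self, rules):
        assert classify_mi(self._mi({"t1", "Apoptosis"}), rules) == "apoptosis"

    def test_housekeeping_without_response_output(self, rules):
        assert classify_mi(self._mi({"syn", "deg"}), rules) == "housekeeping"

    def test_resolution_rule_applies_in_order(self, rules):
        mi = self._mi({"Apoptosis", "Survival", "momp_block", "extr_casp3"})
        assert classify_mi(mi, rules) == "apoptosis"

    def test_unresolved_multi_response_is_ambiguous(self, rules):
        mi = self._mi({"Apoptosis", "Necroptosis"})
        assert classify_mi(mi, rules) == "ambiguous"

    def test_summary_counts(self, rules):
        mis = [
            self._mi({"Apoptosis"}),
            self._mi({"Survival"}),
            self._mi({"Survival"}),
            self._mi({"syn", "deg"}),
            self._mi({"Apoptosis", "Necroptosis"}),
        ]
        counts = classification_summary(mis, rules)
        assert counts["survival"] == 2
        assert counts["apoptosis"] == 1
        assert counts["ambiguous"] == 1
        assert counts["housekeeping"] == 1
        assert counts["counted"] == 3
        assert counts["total"] == 5

    def test_rules_validate_unknown_transition(self, chain_net):
        rules = OutcomeRules(response_outputs={"nope": "apoptosis"})
        with pytest.raises(KeyError):
            rules.validate(chain_net)
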