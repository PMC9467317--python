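import pytest

from ptnet.net import PetriNet


@pytest.fixture
def demo_net() -> PetriNet:
    """Five-place/two-transition worked example: weighted arc and read arc.

    p1 --2--> t1, p2 -> t1, t1 -> p3, p3 <-> t2 (read), p4 -> t2, t2 -> p5;
    initial marking (2, 1, 0, 1, 0).
    """
    net = PetriNet("demo")
    for pid, tok in [("p1", 2), ("p2", 1), ("p3", 0), ("p4", 1), ("p5", 0)]:
        net.add_place(pid, tokens=tok)
    net.add_transition("t1")
    net.add_transition("t2")
    net.add_arc("p1", "t1", 2)
    net.add_arc("p2", "t1")
    net.add_arc("t1", "p3")
    net.add_read_arc("p3", "t2")
    net.add_arc("p4", "t2")
    net.add_arc("t2", "p5")
    return net


@pytest.fixture
def chain_net() -> PetriNet:
    """Open turnover chain syn -> A -> deg."""
    net = PetriNet("chain")
    net.add_place("A")
    net.add_transition("syn")
    net.add_transition("deg")
    net.add_arc("syn", "A")
    net.add_arc("A", "deg")
    return net


@pytest.fixture
def cycle_net() -> PetriNet:
    """Closed two-place cycle: one conserved token."""
    net = PetriNet("cycle")
    net.add_place("A", tokens=1)
    net.add_place("B")
    net.add_transition("t")
    net.add_transition("t2")
    net.add_arc("A", "t")
    net.add_arc("t", "B")
    net.add_arc("B", "t2")
    net.add_arc("t2", "A")
    return net


@pytest.fixture
def gene_motif_net() -> PetriNet:
    """Gene-expression conservation motif: a transcription factor binds a
    conserved gene locus, transcription releases both plus an mRNA."""
    net = PetriNet("gene")
    net.add_place("g", tokens=1)
    net.add_place("TFg")
    net.add_place("TF")
    net.add_place("mRNA")
    net.add_place("P")
    for t in ("syn_TF", "bind", "release", "translate", "deg_P"):
        net.add_transition(t)
    net.add_arc("syn_TF", "TF")
    net.add_arc("TF", "bind")
    net.add_arc("g", "bind")
    net.add_arc("bind", "TFg")
    net.add_arc("TFg", "release")
    net.add_arc("release", "g")
    net.add_arc("release", "mRNA")
    net.add_arc("mRNA", "translate")
    net.add_arc("translate", "P")
    net.add_arc("P", "deg_P")
    return net


@pytest.fixture
def provider_consumer_net() -> PetriNet:
    """Two-TI net: a provider flow feeds X, a catalytic consumer borrows it.

    Provider: syn_a -> A -> X -> out_x.  Consumer: syn_c -> C; C + X -> CX;
    CX -> X + D; D -> deg_d.  The consumer alone is a dissected pathway.
    """
    net = PetriNet("provider-consumer")
    for p in ("A", "X", "C", "CX", "D"):
        net.add_place(p)
    for t in ("syn_a", "act", "out_x", "syn_c", "borrow", "ret", "deg_d"):
        net.add_transition(t)
    net.add_arc("syn_a", "A")
    net.add_arc("A", "act")
    net.add_arc("act", "X")
    net.add_arc("X", "out_x")
    net.add_arc("syn_c", "C")
    net.add_arc("C", "borrow")
    net.add_arc("X", "borrow")
    net.add_arc("borrow", "CX")
    net.add_arc("CX", "ret")
    net.add_arc("ret", "X")
    net.add_arc("ret", "D")
    net.add_arc("D", "deg_d")
    return net


# -- session-scoped TNFR1 analysis bundle (computed once; the MI search is
#    the expensive step of the whole suite) --------------------------------


@pytest.fixture(scope="session")
def tnfr1_bundle():
    from ptnet.invariants import place_invariants, transition_invariants
    from ptnet.manatee import manatee_invariants
    from ptnet.tnfr1 import load_tnfr1

    net, manifest = load_tnfr1()
    tis = transition_invariants(net)
    pis = place_invariants(net)
    result = manatee_invariants(net, tis, pis=pis)
    return {
        "net": net,
        "manifest": manifest,
        "tis": tis,
        "pis": pis,
        "result": result,
        "mis": result.mis,
    }
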