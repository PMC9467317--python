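"""Synthetic nets with planted, analytically known invariant structure.

The motifs mirror the building blocks of signal-transduction P/T models:

``synthesis_degradation``
    open turnover ``syn -> X -> deg``; one TI (trivial), no PI.
``gene_expression_cycle``
    a conserved gene place bound and released by a transcription factor,
    emitting an mRNA that is translated and degraded; one PI of support 2
    (gene + bound gene) and one TI spanning the whole expression flow.
``linear_cascade(k)``
    ``syn -> X1 -> ... -> Xk -> deg``; one TI with k+1 transitions.
``complex_formation``
    two syntheses joining into a degraded complex; one TI, no PI.
``feedback_loop``
    a provider flow feeding a shared intermediate that a second, catalytic
    consumer flow borrows and returns: two TIs of which only the provider
    is realizable alone, so the Manatee invariants are {provider} and
    {provider + consumer} — the smallest net exhibiting a dissected
    pathway.

Motifs are composed as a disjoint union under per-motif id namespaces,
which keeps the planted truth exact: supports of PIs/TIs, the complete-TI
subset and per-synthesis knockout effects are unions over motifs.  The
inter-TI dependency that Manatee analysis exercises lives inside the
``feedback_loop`` motif rather than in cross-motif wiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .net import PetriNet

__all__ = [
    "MotifSpec",
    "PlantedTruth",
    "GenerationError",
    "generate_motif_net",
    "generate_random_net",
]


class GenerationError(ValueError):
    pass


_MOTIF_KINDS = {
    "synthesis_degradation",
    "gene_expression_cycle",
    "linear_cascade",
    "complex_formation",
    "feedback_loop",
}


@dataclass(frozen=True)
class MotifSpec:
    kind: str
    multiplicity: int = 1
    length: int = 3  # linear_cascade only

    def __post_init__(self):
        if self.kind not in _MOTIF_KINDS:
            raise GenerationError(f"unknown motif kind {self.kind!r}")
        if self.multiplicity < 1:
            raise GenerationError("multiplicity must be >= 1")
        if self.kind == "linear_cascade" and self.length < 1:
            raise GenerationError("cascade length must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth the analysis pipeline must recover exactly."""

    pi_supports: list[frozenset[str]] = field(default_factory=list)
    ti_supports: list[frozenset[str]] = field(default_factory=list)
    complete_ti_supports: list[frozenset[str]] = field(default_factory=list)
    mi_count: int = 0
    knockout_affected: dict[str, frozenset[str]] = field(default_factory=dict)
    # per synthesis input: places unproducible after its deletion


def _build_motif(net: PetriNet, spec: MotifSpec, ns: str, truth: PlantedTruth):
    k = spec.kind
    if k == "synthesis_degradation":
        x = f"{ns}_X"
        net.add_place(x)
        net.add_transition(f"{ns}_syn")
        net.add_transition(f"{ns}_deg")
        net.add_arc(f"{ns}_syn", x)
        net.add_arc(x, f"{ns}_deg")
        sup = frozenset({f"{ns}_syn", f"{ns}_deg"})
        truth.ti_supports.append(sup)
        truth.complete_ti_supports.append(sup)
        truth.mi_count += 1
        truth.knockout_affected[f"{ns}_syn"] = frozenset({x})
    elif k == "gene_expression_cycle":
        g, bound = f"{ns}_gene", f"{ns}_TF_gene"
        tf, mrna, prot = f"{ns}_TF", f"{ns}_mRNA", f"{ns}_P"
        for pid, tok in [(g, 1), (bound, 0), (tf, 0), (mrna, 0), (prot, 0)]:
            net.add_place(pid, tokens=tok)
        for tid in ("syn_TF", "bind", "release", "translate", "deg_P"):
            net.add_transition(f"{ns}_{tid}")
        net.add_arc(f"{ns}_syn_TF", tf)
        net.add_arc(tf, f"{ns}_bind")
        net.add_arc(g, f"{ns}_bind")
        net.add_arc(f"{ns}_bind", bound)
        net.add_arc(bound, f"{ns}_release")
        net.add_arc(f"{ns}_release", g)
        net.add_arc(f"{ns}_release", mrna)
        net.add_arc(mrna, f"{ns}_translate")
        net.add_arc(f"{ns}_translate", prot)
        net.add_arc(prot, f"{ns}_deg_P")
        truth.pi_supports.append(frozenset({g, bound}))
        sup = frozenset(
            {f"{ns}_{t}" for t in ("syn_TF", "bind", "release", "translate", "deg_P")}
        )
        truth.ti_supports.append(sup)
        truth.complete_ti_supports.append(sup)
        truth.mi_count += 1
        truth.knockout_affected[f"{ns}_syn_TF"] = frozenset(
            {tf, bound, mrna, prot}
        )
    elif k == "linear_cascade":
        L = spec.length
        places = [f"{ns}_X{i}" for i in range(1, L + 1)]
        for p in places:
            net.add_place(p)
        net.add_transition(f"{ns}_syn")
        net.add_arc(f"{ns}_syn", places[0])
        tids = [f"{ns}_syn"]
        for i in range(L - 1):
            tid = f"{ns}_conv{i + 1}"
            net.add_transition(tid)
            net.add_arc(places[i], tid)
            net.add_arc(tid, places[i + 1])
            tids.append(tid)
        net.add_transition(f"{ns}_deg")
        net.add_arc(places[-1], f"{ns}_deg")
        tids.append(f"{ns}_deg")
        sup = frozenset(tids)
        truth.ti_supports.append(sup)
        truth.complete_ti_supports.append(sup)
        truth.mi_count += 1
        truth.knockout_affected[f"{ns}_syn"] = frozenset(places)
    elif k == "complex_formation":
        a, b, ab = f"{ns}_A", f"{ns}_B", f"{ns}_AB"
        for p in (a, b, ab):
            net.add_place(p)
        for t in ("syn_A", "syn_B", "join", "deg"):
            net.add_transition(f"{ns}_{t}")
        net.add_arc(f"{ns}_syn_A", a)
        net.add_arc(f"{ns}_syn_B", b)
        net.add_arc(a, f"{ns}_join")
        net.add_arc(b, f"{ns}_join")
        net.add_arc(f"{ns}_join", ab)
        net.add_arc(ab, f"{ns}_deg")
        sup = frozenset({f"{ns}_{t}" for t in ("syn_A", "syn_B", "join", "deg")})
        truth.ti_supports.append(sup)
        truth.complete_ti_supports.append(sup)
        truth.mi_count += 1
        # the only MI contains both syntheses: either knockout strands all
        # three places (the partner stays producible but uncovered)
        truth.knockout_affected[f"{ns}_syn_A"] = frozenset({a, b, ab})
        truth.knockout_affected[f"{ns}_syn_B"] = frozenset({a, b, ab})
    elif k == "feedback_loop":
        a, x = f"{ns}_A", f"{ns}_X"
        c, cx, d = f"{ns}_C", f"{ns}_CX", f"{ns}_D"
        for p in (a, x, c, cx, d):
            net.add_place(p)
        for t in ("syn_A", "act", "out_X", "syn_C", "borrow", "return", "deg_D"):
            net.add_transition(f"{ns}_{t}")
        net.add_arc(f"{ns}_syn_A", a)
        net.add_arc(a, f"{ns}_act")
        net.add_arc(f"{ns}_act", x)
        net.add_arc(x, f"{ns}_out_X")
        net.add_arc(f"{ns}_syn_C", c)
        net.add_arc(c, f"{ns}_borrow")
        net.add_arc(x, f"{ns}_borrow")
        net.add_arc(f"{ns}_borrow", cx)
        net.add_arc(cx, f"{ns}_return")
        net.add_arc(f"{ns}_return", x)
        net.add_arc(f"{ns}_return", d)
        net.add_arc(d, f"{ns}_deg_D")
        provider = frozenset({f"{ns}_syn_A", f"{ns}_act", f"{ns}_out_X"})
        consumer = frozenset(
            {f"{ns}_syn_C", f"{ns}_borrow", f"{ns}_return", f"{ns}_deg_D"}
        )
        truth.ti_supports.extend([provider, consumer])
        truth.complete_ti_supports.append(provider)
        truth.mi_count += 2  # {provider} and {provider + consumer}
        # losing the provider kills both MIs, so the consumer's places are
        # stranded too (C stays producible but lies in no surviving MI)
        truth.knockout_affected[f"{ns}_syn_A"] = frozenset({a, x, c, cx, d})
        truth.knockout_affected[f"{ns}_syn_C"] = frozenset({c, cx, d})


def generate_motif_net(
    specs: list[MotifSpec], seed: int = 0
) -> tuple[PetriNet, PlantedTruth]:
    """Disjoint composition of motifs; deterministic for a given seed.

    The seed shuffles the motif instantiation order (and hence id
    numbering), exercising order-independence of the analyses without
    disturbing the planted truth.
    """
    rng = np.random.default_rng(seed)
    net = PetriNet(name=f"motifs-{seed}")
    truth = PlantedTruth()
    instances: list[MotifSpec] = []
    for spec in specs:
        instances.extend([spec] * spec.multiplicity)
    order = rng.permutation(len(instances))
    for n, idx in enumerate(order):
        _build_motif(net, instances[idx], f"m{n}", truth)
    net.validate()
    return net, truth


def generate_random_net(
    n_places: int,
    n_transitions: int,
    arc_density: float,
    seed: int = 0,
    read_arc_prob: float = 0.0,
    max_weight: int = 2,
) -> PetriNet:
    """Seeded random connected bipartite net with weights in 1..max_weight."""
    if n_places < 1 or n_transitions < 1:
        raise GenerationError("need at least one place and one transition")
    if not (0 < arc_density <= 1):
        raise GenerationError("arc_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    net = PetriNet(name=f"random-{seed}")
    pids = [f"p{i}" for i in range(n_places)]
    tids = [f"t{j}" for j in range(n_transitions)]
    for p in pids:
        net.add_place(p, tokens=int(rng.integers(0, 3)))
    for t in tids:
        net.add_transition(t)
    existing: set[tuple[str, str]] = set()

    def put(src: str, tgt: str):
        if (src, tgt) in existing:
            return
        w = int(rng.integers(1, max_weight + 1))
        if read_arc_prob and rng.random() < read_arc_prob:
            p, t = (src, tgt) if src in net.places else (tgt, src)
            if (t, p) not in existing and (p, t) not in existing:
                existing.add((p, t))
                existing.add((t, p))
                net.add_read_arc(p, t, w)
                return
        existing.add((src, tgt))
        net.add_arc(src, tgt, w)

    for p in pids:
        for t in tids:
            if rng.random() < arc_density:
                if rng.random() < 0.5:
                    put(p, t)
                else:
                    put(t, p)
    # connect isolated vertices and components through a random spine
    import networkx as nx

    while True:
        g = nx.Graph()
        g.add_nodes_from(pids + tids)
        g.add_edges_from((a.source, a.target) for a in net.arcs)
        comps = list(nx.connected_components(g))
        if len(comps) <= 1:
            break
        a = sorted(comps[0])
        b = sorted(comps[1])
        pa = [v for v in a if v in net.places]
        ta = [v for v in a if v in net.transitions]
        pb = [v for v in b if v in net.places]
        tb = [v for v in b if v in net.transitions]
        if pa and tb:
            put(pa[int(rng.integers(len(pa)))], tb[int(rng.integers(len(tb)))])
        elif ta and pb:
            put(ta[int(rng.integers(len(ta)))], pb[int(rng.integers(len(pb)))])
        else:
            # both components are pure place sets (or pure transition
            # sets): bridge through any transition (place) of the net
            if pa and pb:
                t_any = sorted(net.transitions)[0]
                put(pa[0], t_any)
                put(t_any, pb[0])
            else:
                p_any = sorted(net.places)[0]
                put(ta[0], p_any)
                put(p_any, tb[0])
    net.validate()
    return net
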