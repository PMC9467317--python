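# ptnet — invariant and knockout analysis of signalling Petri nets

`ptnet` is a toolkit for the qualitative analysis of discrete
place/transition (P/T) nets of signal-transduction pathways, built for the
situation every modeller of signalling faces: plenty of reliable
qualitative knowledge (which complexes form, what activates what), almost
no kinetic parameters. It implements the full invariant-based analysis
chain used for such models, together with a reconstruction of a TNFR1
(tumor necrosis factor receptor 1) molecular-switch model covering NF-κB
survival signalling, apoptosis and necroptosis.

## What it computes

For a net N = (P, T, F, W, m0) with incidence matrix C (tokens produced
minus consumed per place and transition):

- **Place invariants (PIs)** — minimal semi-positive integer y with
  y·C = 0: conserved weighted token sums (substance conservation, e.g. a
  gene locus that is bound and released but never produced or degraded).
- **Transition invariants (TIs)** — minimal semi-positive integer x with
  C·x = 0: steady-state pathways; coverage of every transition by TIs
  (CTI) is the standard structural consistency check.
- **Manatee invariants (MIs)** — minimal combinations of TIs whose summed
  firing-count vector is actually realizable from the initial marking,
  with an explicit witness firing sequence. TIs of signalling nets are
  frequently *dissected* (they borrow tokens other pathways produce); MIs
  are the complete receptor-to-response pathways.
- **Outcome classification** — MIs are labelled survival / apoptosis /
  necroptosis / ambiguous / housekeeping from their response output
  transitions via a declarative rule file.
- **In-silico knockouts** — deleting synthesis transitions; a species is
  affected iff no surviving MI-induced subnetwork contains it. Includes
  single and multiple knockouts (drug-mimicking presets), affected-species
  matrices and protein rankings.
- **Knockout-profile clustering** — UPGMA with Pearson-correlation
  distance over binary knockout rows, exported as Newick trees.

Exact integer arithmetic is used throughout the invariant computations;
every search that could be unbounded carries an explicit budget and
reports its cuts.

## Worked example

A provider pathway feeds an intermediate `X` that a catalytic consumer
borrows and returns — the smallest net with a dissected pathway:

```python
from ptnet import PetriNet, transition_invariants, manatee_invariants

net = PetriNet("provider-consumer")
for p in ("A", "X", "C", "CX", "D"):
    net.add_place(p)
for t in ("syn_a", "act", "out_x", "syn_c", "borrow", "ret", "deg_d"):
    net.add_transition(t)
for src, tgt in [("syn_a", "A"), ("A", "act"), ("act", "X"), ("X", "out_x"),
                 ("syn_c", "C"), ("C", "borrow"), ("X", "borrow"),
                 ("borrow", "CX"), ("CX", "ret"), ("ret", "X"),
                 ("ret", "D"), ("D", "deg_d")]:
    net.add_arc(src, tgt)

tis = transition_invariants(net)
for ti in tis:
    print(sorted(ti.support))
result = manatee_invariants(net, tis)
for mi in result.mis:
    print(sorted(mi.support), mi.witness)
```

prints

```
['act', 'out_x', 'syn_a']
['borrow', 'deg_d', 'ret', 'syn_c']
['act', 'out_x', 'syn_a'] ['syn_a', 'act', 'out_x']
['act', 'borrow', 'deg_d', 'out_x', 'ret', 'syn_a', 'syn_c'] ['syn_c', 'syn_a', 'act', 'borrow', 'ret', 'out_x', 'deg_d']
```

The two TIs are the provider flow and the consumer flow. Only the provider
is realizable on its own (it is a complete pathway and hence an MI); the
consumer's tokens must be lent by the provider, so its only MI is the
combination of both — the witness shows the interleaving: the provider
produces `X`, the consumer borrows and returns it, the provider finishes.

## The TNFR1 model

```python
from ptnet import load_tnfr1, place_invariants, transition_invariants, \
    manatee_invariants

net, manifest = load_tnfr1()          # 118 places, 130 transitions, 299 edges
pis = place_invariants(net)           # 5 conservation cycles (gene loci)
tis = transition_invariants(net)      # 124 TIs, net is CTI
mis = manatee_invariants(net, tis, pis=pis).mis   # 280 MIs (depth <= 3)
```

The model is a reconstruction built from the published description of a
TNFR1 switch model (see `docs/methods.md` for exactly which properties
hold by construction and which analysis results are properties of the
reconstruction). The analysis reproduces the published qualitative
knockout behaviour — e.g. knocking out TNF, TNFR1 or TRADD blocks every
selected pathway entity except nuclear NF-κB, and knocking out MLKL blocks
only membrane-bound MLKL.

The same pipeline runs from the command line:

```
ptnet analyze --model tnfr1 --all --out results/
ptnet knockout --model tnfr1 --preset smac_mimetic --submatrix
ptnet generate --kind feedback_loop --seed 1 --out toy.pnml
```

`analyze` writes invariant JSON/TSV, the MI list with witnesses, the
classification summary, the knockout matrix (CSV), the protein ranking and
the UPGMA tree (Newick), plus a machine-readable `summary.json`.

Nets are read and written as PNML (ISO 15909-2 core model) and as a
species/reaction SBML dialect (species = places with `initialAmount`
markings, reactions = transitions with stoichiometric weights).

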