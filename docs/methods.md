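# Methods

`ptnet` analyses discrete place/transition (P/T) nets of signal-transduction
pathways: exact invariant computation, Manatee-invariant construction,
MI-based in-silico knockouts, and hierarchical clustering of knockout
profiles. This note records the models, algorithms, defaults and design
choices, and what the shipped TNFR1 reconstruction does and does not claim.

## The net model

A net is the quintuple N = (P, T, F, W, m0): places (biochemical entities),
transitions (reactions), weighted directed arcs between them, and an initial
marking of token counts. Enabling and firing follow the standard P/T rule: a
transition is enabled when every pre-place holds at least the arc weight;
firing consumes and produces in one step. Read arcs (bidirectional test
arcs) are stored as flagged opposite pairs; they gate enabling but move no
tokens and contribute zero to the incidence matrix, which therefore always
describes the pure skeleton of the net. All enabling logic consults the arc
list, never the incidence matrix. Nets may be open: input transitions (no
pre-places) model protein synthesis, output transitions (no post-places)
model degradation, complex disassembly, and cellular responses.

Ordering is canonical everywhere (lexicographic by id) so that matrices,
invariant lists and downstream results are reproducible regardless of
construction order.

## Invariants

A transition invariant (TI) is a minimal semi-positive integer vector x with
C·x = 0: firing each transition x[t] times returns every marking to itself —
a steady-state pathway. A place invariant (PI) is a minimal semi-positive y
with y·C = 0: the weighted token sum y·m is conserved — a substance
conservation law. Minimality means gcd 1 and no other solution's support
strictly contained in it; equal supports are both kept only when neither
vector divides the other.

Enumeration is the classical Farkas/Fourier–Motzkin column elimination on
[Aᵀ | I], keeping non-negative combinations, with support-minimality pruning
after each elimination step and rows processed in ascending density order to
limit intermediate growth. All arithmetic is exact Python integers; no
floating point appears anywhere in invariant computation. The test-suite
cross-checks the enumeration against a bounded brute-force oracle
(exhaustive vectors with entries ≤ 4–6) on every generated small net.

## Manatee invariants

A TI guarantees balance but not executability: a dissected pathway borrows
tokens (an activated kinase, a nuclear transcription factor) that only other
TIs produce. A Manatee invariant (MI) is a realizable combination of TIs:
positive integer coefficients whose summed Parikh vector admits a firing
sequence from the initial marking. MIs are the complete
receptor-to-response pathways of the model; each carries an explicit
witness sequence, replayable in the tests, that returns the net to its
initial marking.

Minimality is per anchor TI: for every TI, the MIs containing it are the
set-inclusion-minimal realizable combinations that contain it, and the MI
set of the model is their union, deduplicated by Parikh vector. This is
deliberate: a complete pathway routinely contains a smaller self-sufficient
combination (the transcription-factor turnover flow is itself an MI), so
global minimality over all combinations would reject most real pathways.

The search has three layers:

1. **Saturation gate.** A transition of a candidate combination can
   eventually fire only if every pre-place has initial tokens or an
   in-support producer that can itself eventually fire (computed as a
   worklist fixpoint). In any realizable sequence, the first firing of each
   transition draws on the initial marking or on earlier firings, so a
   transition excluded by the saturation can never fire: a non-saturating
   combination is *proven* unrealizable without search.
2. **Branching.** A stuck combination is extended along one dependency
   chain: at a stuck transition any one unavailable pre-place may be chosen
   (an AND node); the place's alternatives — TIs providing it externally,
   or unsticking one of its in-support producers — form an OR node. The
   walk follows in-support producers until a dead end or until the chain
   closes into a borrowing cycle, collecting the external providers of the
   places passed; these are the branch candidates. The walk is a single
   global breadth-first search over TI sets; a set on the path from an
   anchor to one of its minimal completions is never itself realizable, so
   branching only from stuck sets is complete.
3. **Witness search.** Saturating combinations are checked by depth-first
   backtracking over firing orders with memoization of failed
   (remaining-counts, marking) states, trying transitions in the
   saturation discovery order (producers before their consumers), which
   finds witnesses with little backtracking in practice.

Budgets bound an otherwise undecidable search and every cut is explicit:
combinations are capped at 3 distinct TIs (`max_combination`), single-TI
multiplicities at 3 (`max_coefficient`; multiplicities above 1 are only
needed when arc weights above 1 force parallel runs), the witness search at
200 000 nodes (`node_budget`), and the overall exploration at 2 000 000
states (`max_states`). Combinations cut by a budget are returned in the
result's `inconclusive` list, never silently dropped. Published pathway
examples for this model class combine up to four TIs; on the shipped
reconstruction the depth-3 enumeration is complete in about a minute while
depth 4 is combinatorially out of reach, so 3 is the shipped default and
deeper combinations appear as inconclusive cuts.

## Outcome classification

Response output transitions are mapped to labels (survival, apoptosis,
necroptosis) in a declarative JSON config, not in code. An MI with exactly
one response output gets its label; with none it is housekeeping (pure
turnover); with several, ordered resolution rules are tried (the shipped
rule labels an MI apoptosis when it both blocks MOMP and activates
caspase-3 extrinsically), and unresolved MIs are ambiguous. The summary
counts survival/apoptosis/necroptosis as "counted" and reports ambiguous
and housekeeping separately.

## In-silico knockouts

A knockout deletes synthesis transitions (input transitions, or the
translation of an NF-κB-upregulated gene). An MI survives iff its support
contains no knocked transition; a place is affected (red) iff it lies in no
surviving MI-induced subnetwork, among places covered by at least one MI
overall. The test-suite verifies on synthetic nets that this equals
physically deleting the transitions and recomputing MIs. Affected sets are
monotone under knockout union. Matrix defaults: one row per synthesis
input, columns = places outside every PI support (conserved gene loci are
excluded; places covered by no MI are diagnosed separately rather than
padding the matrix). Protein ranking reports both the fraction of MIs
destroyed and the fraction of column places affected, sorted by the former
with lexicographic tie-breaks.

## Clustering

Knockout rows are binary profiles (1 = affected) compared by Pearson
correlation distance d = 1 − r on the raw 0/1 values (a halved variant
(1 − r)/2 is available; tree topology is invariant to the rescaling).
Zero-variance profiles leave r undefined; the defined fallback is d = 0 for
identical constant vectors and d = 1 otherwise, which keeps identical-row
merges at height zero. UPGMA merges the closest pair, with size-weighted
arithmetic-mean updates and merge heights d/2; ties break on the
lexicographically smallest label pair, making runs deterministic across
platforms. The implementation is cross-checked against scipy's average
linkage in the tests, and trees export to Newick with branch lengths equal
to height differences.

## The TNFR1 reconstruction

`ptnet.tnfr1` ships a reconstruction of a published discrete model of the
TNFR1 molecular switch, rebuilt from the model's printed description (its
structural counts, conservation cycles, marking, input/output conventions
and knockout narrative), not from the original model file, which is not
redistributed. Properties stated outright in that description hold by
construction and are enforced by a manifest on every load:

- 118 places, 130 transitions, 299 edges;
- 26 housekeeping synthesis inputs plus 5 gene-dependent translations
  (the 31 knockable protein syntheses);
- exactly 5 place invariants, each the two-place conservation cycle of one
  NF-κB target gene locus (IκB, A20, XIAP, cFLIP_L, BCL-2);
- initial marking of one token on each of the five gene loci;
- coverage by transition invariants (CTI);
- a 31 × 108 knockout matrix (108 = places outside the PI supports).

The knockout behaviour reproduces the published qualitative pattern:
TNF, TNFR1 and TRADD knockouts give identical rows affecting 20 of the 21
selected pathway entities and sparing only nuclear NF-κB (basal NF-κB
turnover and translocation do not require the receptor); cIAP1/2 ≡ TRAF2;
FADD ≡ procaspase-8; IKK ≡ NEMO ≡ TAK1 ≡ LUBAC; MLKL, CYLD and cFLIP_S
knockouts each block exactly one entity; every knockout blocks something;
TNF and TNFR1 top the ranking; the SMAC-mimetic (cIAP1/2 + XIAP) and
cycloheximide (all five translations) presets behave monotonically over
their single knockouts.

Counts that *emerge* from analysis are properties of the reconstruction and
differ from the original: 124 TIs rather than 48, 280 MIs rather than 279
(at combination depth 3), 38 TIs realizable alone rather than 15, and a
classification of 142 survival / 18 apoptosis / 4 necroptosis / 108
ambiguous / 8 housekeeping rather than 120/58/35/65. The divergence has one
cause: the reconstruction resolves branch points (alternative complex-II
fates, caspase inhibition routes, mRNA handling) with more independent
route variants than the original, and TI/MI counts grow multiplicatively in
such variants. Exactly one TI is a bare synthesis→degradation turnover (of
NF-κB), matching the original's single trivial TI. Passing tests on this
model therefore validate the analysis machinery and the qualitative switch
behaviour, not a numerical reproduction of the original model's invariant
inventory — the acceptance tests that assert the original's counts document
the remaining distance.

## The synthetic generator

`ptnet.synth` plants analytically known structure: open turnover chains,
gene-expression conservation cycles (one support-2 PI each), linear
cascades (one TI with k+1 transitions for k stages), complex-formation
joins, and a provider/consumer feedback motif whose catalytic consumer is
the smallest dissected pathway (its MI set is exactly {provider} and
{provider + consumer}). Motifs compose as a disjoint union under per-motif
namespaces — this keeps the planted truth exact by simple union; the
inter-TI dependency that the Manatee analysis must resolve lives inside the
feedback motif. A single integer seed drives all randomness (motif
instantiation order, random-net topology); no global random state is
touched. Random nets are connected, bipartite, weight-1/2, with optional
read arcs. What the generator does not emulate: realistic degree
distributions, crosstalk density, or the deep multi-pathway borrowing of
real signalling models — planted-recovery tests show correctness of the
algorithms, not performance on hub-rich real topologies.

## Numerical and degenerate-input choices

- Invariant arithmetic is exact; clustering uses floating point only for
  distances and heights.
- Empty invariant lists, empty affected sets and single-leaf trees are
  legal results, not errors.
- A knockout of a transition contained in no MI affects nothing.
- Firing a disabled transition, unknown ids, non-symmetric distance
  matrices and malformed nets raise typed exceptions
  (`NotEnabledError`, `UnknownIdError`, `ValidationError`).
- Serialization: PNML (ISO 15909-2 core; read arcs in a `toolspecific`
  element) and a species/reaction SBML dialect (stoichiometries = weights,
  `initialAmount` = marking); same-named layout-copy places merge on read,
  with a strict mode that rejects conflicting annotations.

## Known limitations

- MI enumeration beyond the combination-depth budget is reported as
  inconclusive rather than computed; on hub-rich nets the full MI set is
  exponential.
- The optional "downstream-only" knockout filter (restricting affected
  places to those reachable from the knocked transition) is not
  implemented; the shipped semantics is the global MI-coverage rule.
- Reachability graphs, model checking, and timed/stochastic/continuous net
  classes are out of scope.
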