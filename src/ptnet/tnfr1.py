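"""Reconstruction of a TNFR1 signal-transduction P/T net.

This module encodes a discrete place/transition model of the molecular
switch between cell survival (NF-kB pathway), apoptosis and necroptosis
downstream of tumor necrosis factor receptor 1.  It is a *synthetic
reconstruction* assembled from the published description of the model —
its structural counts (118 places, 130 transitions, 299 edges), its five
gene-expression conservation cycles, its 26 housekeeping protein
syntheses, the initial marking of one token on each of the five
NF-kB-target gene places, and the narrative of which knockouts block
which complexes — not a transcription of the original file, which is not
redistributed here.  Counts that emerge from analysis (numbers of
transition and Manatee invariants, classification fractions) are
properties of this reconstruction.

Model logic, briefly: TNF ligates TNFR1; TRADD and RIP1 nucleate complex
I, stabilised by TRAF2-recruited cIAP1/2 which decorates RIP1 with K63
ubiquitin chains; LUBAC adds M1 chains.  K63 chains recruit TAB2:TAK1,
M1 chains recruit IKK:NEMO; TAK1 activates IKK, which phosphorylates
IkB inside the NF-kB:IkB complex, freeing NF-kB to enter the nucleus and
transcribe IkB, A20, XIAP, cFLIP_L and BCL-2 (the five conserved gene
loci).  A20 disassembles ubiquitinated complex I; CYLD deubiquitinates
it, releasing TRADD:RIP1 that seeds the cytosolic death complexes: IIa
(TRADD:FADD:procaspase-8) and IIb (RIP1:FADD:procaspase-8), sources of
active caspase-8.  cFLIP_L tempers caspase-8 (cleaving RIP1), cFLIP_S
blocks it and channels complex IIb into the necrosome (RIP1:RIP3), which
phosphorylates MLKL for membrane permeabilisation.  Caspase-8 cleaves
BID; tBID activates BAX for MOMP, cytochrome-c/SMAC release, apoptosome
assembly and caspase-9/-3 activation, checked by BCL-2 and XIAP and
de-checked by SMAC.  The net is open: housekeeping proteins enter by
synthesis input transitions and leave through degradation, dissociation
or the three response outputs (Survival, Apoptosis, Necroptosis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .net import PetriNet, ValidationError

__all__ = [
    "ModelManifest",
    "IntegrityError",
    "build_tnfr1",
    "load_tnfr1",
    "load_manifest",
    "load_submatrix_columns",
    "load_outcome_rules",
    "validate_model",
    "SUBMATRIX_COLUMNS",
    "KNOCKOUT_PRESETS",
]


class IntegrityError(ValidationError):
    """The loaded model contradicts its manifest."""


# housekeeping proteins: synthesised by input transitions, 26 of them
_HOUSEKEEPING = [
    "TNF", "TNFR1", "TRADD", "RIP1", "TRAF2", "cIAP1_2", "LUBAC", "CYLD",
    "TAB2", "TAK1", "IKK", "NEMO", "NF-kB", "FADD", "ProCASP8", "cFLIP_S",
    "ProCASP3", "ProCASP9", "BAX", "BID", "APAF1", "SMAC_mito", "CytC_mito",
    "RIP3", "MLKL", "Ub",
]

# NF-kB target genes: conserved loci, translation is the knockable synthesis
_TARGET_GENES = ["IkB", "A20", "XIAP", "cFLIP_L", "BCL-2"]

# (name, consumes, produces); transition ids T1.. are assigned in order.
# Weights are 1 throughout (stoichiometry beyond 1:1 is not resolved at
# this abstraction level).
_REACTIONS: list[tuple[str, list[str], list[str]]] = [
    # --- complex I assembly and ubiquitin signalling
    ("TNF binds TNFR1", ["TNF", "TNFR1"], ["TNF:TNFR1"]),
    ("TRADD recruitment", ["TNF:TNFR1", "TRADD"], ["TNF:TNFR1:TRADD"]),
    ("RIP1 recruitment", ["TNF:TNFR1:TRADD", "RIP1"], ["CI_core"]),
    ("TRAF2/cIAP1/2 recruitment", ["CI_core", "TRAF2", "cIAP1_2"], ["CI"]),
    ("K63 ubiquitination of RIP1", ["CI", "Ub"], ["CI_K63"]),
    ("TAB2:TAK1 complex formation", ["TAB2", "TAK1"], ["TAB2:TAK1"]),
    ("TAB2:TAK1 binds K63 chains", ["CI_K63", "TAB2:TAK1"], ["CI_K63:TAK1"]),
    ("TAK1 activation and release", ["CI_K63:TAK1"], ["CI_K63", "TAK1a"]),
    ("LUBAC recruitment", ["CI_K63", "LUBAC"], ["CI_K63:LUBAC"]),
    ("M1 ubiquitination", ["CI_K63:LUBAC", "Ub"], ["CI_Ub"]),
    ("IKK:NEMO complex formation", ["IKK", "NEMO"], ["IKK:NEMO"]),
    ("NEMO binds M1 chains", ["CI_Ub", "IKK:NEMO"], ["CI_Ub:IKK"]),
    ("TAK1a joins IKK at complex I", ["CI_Ub:IKK", "TAK1a"], ["CI_Ub:IKK:TAK1"]),
    ("IKK activation", ["CI_Ub:IKK:TAK1"], ["CI_Ub", "IKKa"]),
    ("A20 binds ubiquitinated CI", ["CI_K63", "A20"], ["CI:A20"]),
    ("A20 deubiquitinates CI", ["CI:A20"], ["CI_deUb", "A20_Ub"]),
    ("CYLD binds ubiquitinated CI", ["CI_K63", "CYLD"], ["CI:CYLD"]),
    ("CYLD deubiquitinates CI", ["CI:CYLD"], ["CI_dest"]),
    ("complex I destabilisation", ["CI_dest"], ["TRADD:RIP1"]),
    ("unubiquitinated CI decay", ["CI_core"], ["TRADD:RIP1"]),
    ("TRADD dissociation from receptor", ["TNF:TNFR1:TRADD"], ["TRADD_c"]),
    ("TRADD:RIP1 separation", ["TRADD:RIP1"], ["TRADD_c", "RIP1_du"]),
    # --- NF-kB / IkB module
    ("NF-kB nuclear translocation", ["NF-kB"], ["NF-kB_n"]),
    ("IkB binds NF-kB", ["NF-kB", "IkB"], ["NF-kB:IkB"]),
    ("IkB nuclear import", ["IkB"], ["IkB_n"]),
    ("IkB-mediated NF-kB export", ["IkB_n", "NF-kB_n"], ["NF-kB:IkB"]),
    ("IKKa binds NF-kB:IkB", ["NF-kB:IkB", "IKKa"], ["NF-kB:IkB:IKK"]),
    ("IkB phosphorylation", ["NF-kB:IkB:IKK"], ["NF-kB:IkB_p"]),
    ("phospho-IkB release", ["NF-kB:IkB_p"], ["NF-kB", "IkB_p"]),
    # --- complex II formation and caspase-8
    ("complex IIa assembly", ["TRADD_c", "FADD", "ProCASP8"], ["CIIa"]),
    ("complex IIb assembly", ["RIP1_du", "FADD", "ProCASP8"], ["CIIb"]),
    ("CASP8 processing at CIIa", ["CIIa"], ["CASP8_p43"]),
    ("CASP8 processing at CIIb", ["CIIb"], ["CASP8_p43"]),
    ("CASP8 maturation", ["CASP8_p43", "ProCASP8"], ["CASP8"]),
    ("cFLIP_L binds CIIa", ["CIIa", "cFLIP_L"], ["CIIa:cFLIPL"]),
    ("CIIa:cFLIP_L disassembly", ["CIIa:cFLIPL"], ["TRADD_c"]),
    ("cFLIP_L binds CIIb", ["CIIb", "cFLIP_L"], ["CIIb:cFLIPL"]),
    ("partial CASP8 cleaves RIP1", ["CIIb:cFLIPL"], ["RIP1_cl", "cFLIP_L_sp"]),
    ("cFLIP_S binds CIIb", ["CIIb", "cFLIP_S"], ["CIIb:cFLIPs"]),
    ("necrosome seeding from blocked CIIb", ["CIIb:cFLIPs", "RIP3", "RIP1_du"],
     ["RIP1:RIP3"]),
    # --- extrinsic caspase-3 activation
    ("CASP8 binds procaspase-3", ["CASP8", "ProCASP3"], ["CASP8:C3"]),
    ("extrinsic CASP3 activation", ["CASP8:C3"], ["CASP3"]),
    ("XIAP inhibits CASP3", ["XIAP", "CASP3"], ["XIAP:CASP3"]),
    # --- BID / MOMP
    ("CASP8 binds BID", ["CASP8", "BID"], ["CASP8:BID"]),
    ("BID cleavage", ["CASP8:BID"], ["tBID"]),
    ("tBID binds BAX", ["tBID", "BAX"], ["tBID:BAX"]),
    ("BAX activation", ["tBID:BAX"], ["BAX_a"]),
    ("BCL-2 sequesters active BAX", ["BCL-2", "BAX_a"], ["BCL-2:BAX"]),
    ("BCL-2 sequesters tBID", ["BCL-2", "tBID"], ["BCL-2:tBID"]),
    ("BAX oligomerisation", ["BAX_a", "BAX"], ["BAX_olig"]),
    ("MOMP pore formation", ["BAX_olig", "BAX_a"], ["Pore"]),
    ("cytochrome c engages pore", ["Pore", "CytC_mito"], ["Pore:CytC"]),
    ("cytochrome c release", ["Pore:CytC"], ["CytC_c"]),
    ("SMAC engages pore", ["Pore", "SMAC_mito"], ["Pore:SMAC"]),
    ("SMAC release", ["Pore:SMAC"], ["Pore", "SMAC_c"]),
    # --- apoptosome, caspase-9, IAP antagonism
    ("APAF1 binds cytochrome c", ["APAF1", "CytC_c"], ["APAF1:CytC"]),
    ("apoptosome assembly", ["APAF1:CytC", "APAF1", "CytC_c", "ProCASP9"],
     ["Apoptosome"]),
    ("CASP9 activation", ["Apoptosome"], ["CASP9"]),
    ("CASP9 binds procaspase-3", ["CASP9", "ProCASP3"], ["CASP9:C3"]),
    ("intrinsic CASP3 activation", ["CASP9:C3"], ["CASP3"]),
    ("XIAP inhibits CASP9", ["XIAP", "CASP9"], ["XIAP:CASP9"]),
    ("SMAC neutralises XIAP", ["SMAC_c", "XIAP"], ["SMAC:XIAP"]),
    ("XIAP ubiquitination", ["SMAC:XIAP", "Ub"], ["XIAP_Ub", "SMAC_sp"]),
    # --- necroptosis
    ("necrosome assembly", ["RIP1_du", "RIP3"], ["RIP1:RIP3"]),
    ("RIP3 autophosphorylation", ["RIP1:RIP3", "RIP3"], ["RIP1:RIP3_p"]),
    ("MLKL recruitment", ["RIP1:RIP3_p", "MLKL"], ["RIP1:RIP3:MLKL"]),
    ("MLKL phosphorylation", ["RIP1:RIP3:MLKL"], ["MLKL_p", "Necrosome_sp"]),
    ("MLKL oligomerisation", ["MLKL_p", "MLKL"], ["MLKL_olig"]),
    ("MLKL membrane translocation", ["MLKL_olig"], ["MLKL_PM"]),
]

# output transitions: degradation, dissociation, and the three responses
_OUTPUTS: list[tuple[str, str, list[str]]] = [
    ("Diss_CI_A20", "A20-inactivated CI disassembly", ["CI_deUb", "A20_Ub"]),
    ("Deg_TRADD_c", "cytosolic TRADD degradation", ["TRADD_c"]),
    ("Deg_NF-kB", "NF-kB degradation", ["NF-kB"]),
    ("Survival", "survival response (NF-kB program)", ["NF-kB_n"]),
    ("Deg_IkB_p", "proteasomal phospho-IkB degradation", ["IkB_p"]),
    ("Deg_RIP1_cl", "cleaved RIP1 / cFLIP_L:CASP8 debris degradation",
     ["RIP1_cl", "cFLIP_L_sp"]),
    ("Apoptosis", "apoptosis execution", ["CASP3"]),
    ("Deg_CI_Ub", "internalisation of ubiquitinated complex I", ["CI_Ub"]),
    ("Diss_XIAP_CASP3", "XIAP:CASP3 turnover", ["XIAP:CASP3"]),
    ("Diss_BCL2_BAX", "BCL-2:BAX turnover", ["BCL-2:BAX"]),
    ("Diss_BCL2_tBID", "BCL-2:tBID turnover", ["BCL-2:tBID"]),
    ("Diss_XIAP_CASP9", "XIAP:CASP9 turnover", ["XIAP:CASP9"]),
    ("Deg_XIAP_Ub", "ubiquitinated XIAP / SMAC degradation",
     ["XIAP_Ub", "SMAC_sp"]),
    ("Deg_Necrosome", "necrosome turnover", ["RIP1:RIP3_p", "RIP1:RIP3"]),
    ("Necroptosis", "necroptosis execution",
     ["MLKL_PM", "Necrosome_sp", "RIP1:RIP3_p"]),
]

def _load_data(fname: str) -> dict:
    ref = resources.files("ptnet").joinpath("data", fname)
    with ref.open() as fh:
        return json.load(fh)


def load_submatrix_columns() -> list[str]:
    """The 21-entity column set of the knockout submatrix view (data file)."""
    return list(_load_data("submatrix_columns.json")["columns"])


def load_outcome_rules():
    """Shipped outcome-classification rules for the model (data file)."""
    from .manatee import OutcomeRules

    data = _load_data("outcome_rules.json")
    return OutcomeRules(
        response_outputs=data["response_outputs"],
        resolution_rules=data.get("resolution_rules", []),
    )


# convenience constant mirroring the shipped data file
SUBMATRIX_COLUMNS = load_submatrix_columns()

# drug-mimicking multiple knockouts
KNOCKOUT_PRESETS: dict[str, list[str]] = {
    # IAP antagonist: removes cIAP1/2 and XIAP
    "smac_mimetic": ["Syn_cIAP1_2", "Tl_XIAP"],
    # translation block of the five NF-kB-upregulated genes
    "cycloheximide": ["Tl_IkB", "Tl_A20", "Tl_XIAP", "Tl_cFLIP_L", "Tl_BCL-2"],
}


def build_tnfr1() -> PetriNet:
    """Construct the reconstruction net programmatically."""
    net = PetriNet(name="TNFR1")
    places: set[str] = set()

    def ensure_place(pid: str):
        if pid not in places:
            ann = "gene" if pid.endswith("_g") else None
            net.add_place(pid, name=pid, annotation=ann)
            places.add(pid)

    for prot in _HOUSEKEEPING:
        ensure_place(prot)
        net.add_transition(f"Syn_{prot}", f"synthesis of {prot}")
        net.add_arc(f"Syn_{prot}", prot)

    # gene-expression modules: conserved locus, transcription, translation
    for g in _TARGET_GENES:
        locus, bound = f"{g}_g", f"NF-kB:{g}_g"
        mrna_n, mrna, prot = f"{g}_mRNA_n", f"{g}_mRNA", g
        for pid in (locus, bound, mrna_n, mrna, prot):
            ensure_place(pid)
        net.initial_marking[locus] = 1
        tb, tr, tex, tl = (f"Tb_{g}", f"Tt_{g}", f"Tex_{g}", f"Tl_{g}")
        net.add_transition(tb, f"NF-kB binds {g} gene")
        net.add_transition(tr, f"transcription of {g}")
        net.add_transition(tex, f"{g} mRNA export")
        net.add_transition(tl, f"translation of {g}")
        for src, tgt in [
            ("NF-kB_n", tb), (locus, tb), (tb, bound),
            (bound, tr), (tr, "NF-kB_n"), (tr, locus), (tr, mrna_n),
            (mrna_n, tex), (tex, mrna),
            (mrna, tl), (tl, prot),
        ]:
            if src in net.transitions or tgt in net.transitions:
                # one endpoint is a transition; the other is a place
                pass
            ensure_place(src if tgt in net.transitions else tgt)
            net.add_arc(src, tgt)

    for i, (name, cons, prods) in enumerate(_REACTIONS, start=1):
        tid = f"T{i}"
        for pid in cons + prods:
            ensure_place(pid)
        net.add_transition(tid, name)
        for pid in cons:
            net.add_arc(pid, tid)
        for pid in prods:
            net.add_arc(tid, pid)

    for tid, name, cons in _OUTPUTS:
        net.add_transition(tid, name)
        for pid in cons:
            ensure_place(pid)
            net.add_arc(pid, tid)

    net.validate()
    return net


@dataclass
class ModelManifest:
    """Expected structure of the model, cross-checked on every load."""

    n_places: int = 118
    n_transitions: int = 130
    n_edges: int = 299
    marked_places: tuple[str, ...] = tuple(f"{g}_g" for g in _TARGET_GENES)
    n_synthesis_inputs: int = 26
    n_knockout_syntheses: int = 31  # housekeeping syntheses + translations
    response_outputs: dict[str, str] = field(
        default_factory=lambda: {
            "Survival": "survival",
            "Apoptosis": "apoptosis",
            "Necroptosis": "necroptosis",
        }
    )
    pi_supports: tuple[frozenset[str], ...] = tuple(
        frozenset({f"{g}_g", f"NF-kB:{g}_g"}) for g in _TARGET_GENES
    )

    def synthesis_transitions(self, net: PetriNet) -> list[str]:
        """The 31 protein-synthesis transitions: housekeeping inputs plus
        the five translations of NF-kB-upregulated genes."""
        return [f"Syn_{p}" for p in _HOUSEKEEPING] + [
            f"Tl_{g}" for g in _TARGET_GENES
        ]

    def knockout_experiment_names(self) -> dict[str, str]:
        """protein label -> knocked transition id"""
        names = {p: f"Syn_{p}" for p in _HOUSEKEEPING}
        names.update({g: f"Tl_{g}" for g in _TARGET_GENES})
        return names


def load_manifest() -> ModelManifest:
    return ModelManifest()


def load_tnfr1() -> tuple[PetriNet, ModelManifest]:
    """Build the net and verify it against the manifest."""
    net = build_tnfr1()
    manifest = load_manifest()
    _check_counts(net, manifest)
    return net, manifest


def _check_counts(net: PetriNet, manifest: ModelManifest) -> None:
    checks = {
        "places": (len(net.places), manifest.n_places),
        "transitions": (len(net.transitions), manifest.n_transitions),
        "edges": (len(net.arcs), manifest.n_edges),
        "synthesis inputs": (
            len(net.input_transitions()), manifest.n_synthesis_inputs
        ),
        "initial tokens": (
            net.initial_marking.total(), len(manifest.marked_places)
        ),
    }
    for what, (got, want) in checks.items():
        if got != want:
            raise IntegrityError(f"{what}: expected {want}, found {got}")
    for pid in manifest.marked_places:
        if net.initial_marking[pid] != 1:
            raise IntegrityError(f"expected one token on {pid}")


def validate_model(
    net: PetriNet,
    manifest: ModelManifest,
    tis=None,
    pis=None,
) -> dict:
    """Structural diagnostics; never raises, lists failures instead."""
    report: dict = {"failures": [], "checks": {}}

    def check(name: str, ok: bool, detail=""):
        report["checks"][name] = bool(ok)
        if not ok:
            report["failures"].append(f"{name}: {detail}")

    try:
        net.validate()
        check("bipartite", True)
    except ValidationError as exc:
        check("bipartite", False, str(exc))
    try:
        _check_counts(net, manifest)
        check("counts", True)
    except IntegrityError as exc:
        check("counts", False, str(exc))
    for tid, _ in manifest.response_outputs.items():
        check(
            f"response output {tid}",
            tid in net.transitions and net.transition_kind(tid) == "output",
            "missing or not an output transition",
        )
    if pis is not None:
        got = sorted(sorted(pi.support) for pi in pis)
        want = sorted(sorted(s) for s in manifest.pi_supports)
        check("PI supports", got == want, f"got {got}")
    if tis is not None:
        covered = set()
        for ti in tis:
            covered |= ti.support
        check(
            "CTI",
            covered == set(net.transition_ids),
            f"uncovered: {sorted(set(net.transition_ids) - covered)}",
        )
    report["ok"] = not report["failures"]
    return report
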