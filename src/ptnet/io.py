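"""Reading and writing nets: PNML core model, SBML species/reaction dialect.

PNML follows the ISO/IEC 15909-2 core model (place, transition, arc with
inscription weights and initialMarking).  Read arcs are not part of the
core model and are carried in a ``toolspecific`` element.

The SBML dialect maps species to places (``initialAmount`` = marking) and
reactions to transitions (stoichiometries = arc weights); reactions without
reactants are synthesis inputs, without products degradation/response
outputs.  This is the convention qualitative Petri-net tools use when
exporting P/T nets to SBML, and the reader autodetects it (plain
species/reaction structure, integer amounts, irreversible reactions).

Logical places — layout copies of one entity appearing at several positions
of a drawing — may occur in exported files as same-named flagged species;
readers merge them into a single place, in strict mode refusing copies with
conflicting annotations.
"""

from __future__ import annotations

import csv
from pathlib import Path

from lxml import etree

from .net import Marking, PetriNet, ValidationError

__all__ = [
    "read_pnml",
    "write_pnml",
    "read_sbml",
    "write_sbml",
    "incidence_to_csv",
    "merge_logical_places",
]

_PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"
_SBML_NS = "http://www.sbml.org/sbml/level2/version4"


def _text(parent, tag: str) -> str | None:
    el = parent.find(f"{{*}}{tag}/{{*}}text")
    if el is None:
        el = parent.find(f"{tag}/text")
    return el.text if el is not None else None


# -- PNML ------------------------------------------------------------------


def read_pnml(path, merge_logical: bool = True, strict: bool = False) -> PetriNet:
    tree = etree.parse(str(path))
    root = tree.getroot()
    net_el = root.find("{*}net")
    if net_el is None:
        raise ValidationError("no <net> element in PNML file")
    net = PetriNet(name=net_el.get("id", "net"))
    pages = net_el.findall("{*}page") or [net_el]
    logical: list[tuple[str, str]] = []  # (id, name) of flagged copies
    read_pairs: set[tuple[str, str]] = set()
    for page in pages:
        for pel in page.findall("{*}place"):
            pid = pel.get("id")
            name = _text(pel, "name")
            marking = _text(pel, "initialMarking")
            ts = pel.find("{*}toolspecific[@tool='ptnet']")
            annotation = ts.get("annotation") if ts is not None else None
            is_copy = ts is not None and ts.get("logicalCopy") == "true"
            net.add_place(pid, name, annotation, tokens=int(marking or 0))
            if is_copy:
                logical.append((pid, name or pid))
        for tel in page.findall("{*}transition"):
            net.add_transition(tel.get("id"), _text(tel, "name"))
        for ael in page.findall("{*}arc"):
            w = int(_text(ael, "inscription") or 1)
            ts = ael.find("{*}toolspecific[@tool='ptnet']")
            src, tgt = ael.get("source"), ael.get("target")
            if ts is not None and ts.get("readArc") == "true":
                pair = (src, tgt) if src in net.places else (tgt, src)
                if pair not in read_pairs:
                    read_pairs.add(pair)
                    net.add_read_arc(pair[0], pair[1], w)
            else:
                net.add_arc(src, tgt, w)
    if merge_logical and logical:
        net = merge_logical_places(net, logical, strict=strict)
    net.validate()
    return net


def write_pnml(net: PetriNet, path) -> None:
    root = etree.Element("pnml", nsmap={None: _PNML_NS})
    net_el = etree.SubElement(root, "net", id=net.name, type=f"{_PNML_NS}/ptnet")
    page = etree.SubElement(net_el, "page", id="page0")

    def _with_text(parent, tag, value):
        el = etree.SubElement(parent, tag)
        etree.SubElement(el, "text").text = str(value)

    for pid in net.place_ids:
        p = net.places[pid]
        pel = etree.SubElement(page, "place", id=pid)
        _with_text(pel, "name", p.label)
        if net.initial_marking[pid]:
            _with_text(pel, "initialMarking", net.initial_marking[pid])
        if p.annotation:
            etree.SubElement(
                pel, "toolspecific", tool="ptnet", version="1",
                annotation=p.annotation,
            )
    for tid in net.transition_ids:
        tel = etree.SubElement(page, "transition", id=tid)
        _with_text(tel, "name", net.transitions[tid].label)
    seen_read: set[frozenset] = set()
    for i, a in enumerate(net.arcs):
        if a.read_arc:
            key = frozenset((a.source, a.target))
            if key in seen_read:
                continue
            seen_read.add(key)
        ael = etree.SubElement(
            page, "arc", id=f"a{i}", source=a.source, target=a.target
        )
        if a.weight != 1:
            _with_text(ael, "inscription", a.weight)
        if a.read_arc:
            etree.SubElement(
                ael, "toolspecific", tool="ptnet", version="1", readArc="true"
            )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# -- SBML dialect ----------------------------------------------------------


def read_sbml(path, merge_logical: bool = True, strict: bool = False) -> PetriNet:
    """Read a species/reaction SBML export of a P/T net.

    Stoichiometries become arc weights; ``initialAmount`` becomes the
    initial marking.  Species flagged as layout copies (a notes/annotation
    containing ``logical``) of the same name are merged.
    """
    tree = etree.parse(str(path))
    model = tree.getroot().find("{*}model")
    if model is None:
        raise ValidationError("no <model> element in SBML file")
    net = PetriNet(name=model.get("id", model.get("name", "net")))
    logical: list[tuple[str, str]] = []
    for sp in model.findall(".//{*}listOfSpecies/{*}species"):
        sid = sp.get("id")
        name = sp.get("name") or sid
        amount = sp.get("initialAmount")
        tokens = int(float(amount)) if amount not in (None, "") else 0
        notes = etree.tostring(sp, method="text", encoding="unicode").lower()
        net.add_place(sid, name, tokens=tokens)
        if "logical" in (sp.get("metaid") or "").lower() or "logicalcopy" in notes:
            logical.append((sid, name))
    for rx in model.findall(".//{*}listOfReactions/{*}reaction"):
        rid = rx.get("id")
        net.add_transition(rid, rx.get("name") or rid)
        for sr in rx.findall("{*}listOfReactants/{*}speciesReference"):
            w = int(float(sr.get("stoichiometry", "1")))
            net.add_arc(sr.get("species"), rid, w)
        for sr in rx.findall("{*}listOfProducts/{*}speciesReference"):
            w = int(float(sr.get("stoichiometry", "1")))
            net.add_arc(rid, sr.get("species"), w)
    if merge_logical and logical:
        net = merge_logical_places(net, logical, strict=strict)
    net.validate()
    return net


def write_sbml(net: PetriNet, path) -> None:
    root = etree.Element("sbml", nsmap={None: _SBML_NS}, level="2", version="4")
    model = etree.SubElement(root, "model", id=net.name.replace(" ", "_"))
    comps = etree.SubElement(model, "listOfCompartments")
    etree.SubElement(comps, "compartment", id="default", size="1")
    los = etree.SubElement(model, "listOfSpecies")
    for pid in net.place_ids:
        etree.SubElement(
            los, "species", id=pid, name=net.places[pid].label,
            compartment="default",
            initialAmount=str(net.initial_marking[pid]),
            hasOnlySubstanceUnits="true",
        )
    lor = etree.SubElement(model, "listOfReactions")
    for tid in net.transition_ids:
        rx = etree.SubElement(
            lor, "reaction", id=tid, name=net.transitions[tid].label,
            reversible="false",
        )
        pre = net.pre(tid)
        post = net.post(tid)
        if pre:
            lr = etree.SubElement(rx, "listOfReactants")
            for pid, w in sorted(pre.items()):
                etree.SubElement(
                    lr, "speciesReference", species=pid, stoichiometry=str(w)
                )
        if post:
            lp = etree.SubElement(rx, "listOfProducts")
            for pid, w in sorted(post.items()):
                etree.SubElement(
                    lp, "speciesReference", species=pid, stoichiometry=str(w)
                )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def merge_logical_places(
    net: PetriNet, logical: list[tuple[str, str]], strict: bool = False
) -> PetriNet:
    """Merge layout-only place copies into the first place of each name."""
    by_name: dict[str, str] = {}
    for pid in net.place_ids:
        name = net.places[pid].label
        by_name.setdefault(name, pid)
    remap: dict[str, str] = {}
    for pid, name in logical:
        canon = by_name[name]
        if canon != pid:
            if strict:
                a, b = net.places[pid].annotation, net.places[canon].annotation
                if a is not None and b is not None and a != b:
                    raise ValidationError(
                        f"logical copies of {name!r} carry conflicting "
                        f"annotations {a!r} vs {b!r}"
                    )
            remap[pid] = canon
    if not remap:
        return net
    merged = PetriNet(net.name)
    for pid in net.place_ids:
        if pid in remap:
            continue
        p = net.places[pid]
        merged.add_place(pid, p.name, p.annotation)
    for tid in net.transition_ids:
        merged.add_transition(tid, net.transitions[tid].name)
    for a in net.arcs:
        src = remap.get(a.source, a.source)
        tgt = remap.get(a.target, a.target)
        merged.arcs.append(type(a)(src, tgt, a.weight, a.read_arc))
    m = Marking()
    for pid, c in net.initial_marking.items():
        tgt = remap.get(pid, pid)
        m[tgt] = m[tgt] + c
    merged.initial_marking = m
    return merged


def incidence_to_csv(net: PetriNet, path) -> None:
    """Incidence matrix with a header row/column of ids."""
    C = net.incidence_matrix()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + net.transition_ids)
        for i, pid in enumerate(net.place_ids):
            w.writerow([pid] + [int(x) for x in C[i]])
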