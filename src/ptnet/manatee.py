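"""Manatee invariants: realizable combinations of transition invariants.

A transition invariant (TI) guarantees ``C x = 0`` but not that any firing
sequence with those counts exists from the initial marking: many TIs of a
signalling net are *dissected* pathways that borrow tokens produced by
other TIs (e.g. a feedback loop that needs the transcription factor another
pathway activates).  A Manatee invariant (MI) is a minimal positive integer
combination of TIs whose summed Parikh vector IS realizable from the
initial marking — a complete pathway from receptor activation to cellular
response.  Each MI carries a witness firing sequence proving realizability.

The search is a breadth-first walk over TI sets: every single TI seeds a
combination; a stuck combination branches on the TIs able to produce the
places its dependency chain is missing.  For every TI the minimal
realizable combinations containing it are kept (a complete pathway may
legitimately contain a smaller self-sufficient one), deduplicated by their
summed Parikh vector; combination size, coefficients and search effort are
capped, and every budget cut is reported explicitly as inconclusive, never
silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .net import Marking, PetriNet
from .invariants import PlaceInvariant, TransitionInvariant

__all__ = [
    "ManateeInvariant",
    "ManateeResult",
    "OutcomeRules",
    "manatee_invariants",
    "classify_ti",
    "classify_mi",
    "classification_summary",
    "mis_to_json",
]


@dataclass
class ManateeInvariant:
    """A minimal realizable TI combination.

    ``ti_coefficients`` maps TI list indices to positive multiplicities;
    ``parikh`` is the summed transition-count vector; ``witness`` a firing
    sequence realizing it from the initial marking.
    """

    ti_coefficients: dict[int, int]
    parikh: dict[str, int]
    witness: list[str]
    is_pure: bool | None = None
    outcome_label: str | None = None

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.parikh)

    @property
    def is_singleton(self) -> bool:
        return len(self.ti_coefficients) == 1 and 1 in set(
            self.ti_coefficients.values()
        )


@dataclass
class ManateeResult:
    """MIs plus the combinations whose realizability stayed undecided."""

    mis: list[ManateeInvariant]
    inconclusive: list[dict[int, int]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.mis)

    def __len__(self) -> int:
        return len(self.mis)


def _combo_parikh(
    combo: Mapping[int, int], tis: Sequence[TransitionInvariant]
) -> dict[str, int]:
    out: dict[str, int] = {}
    for idx, mult in combo.items():
        for t, c in tis[idx].coefficients:
            out[t] = out.get(t, 0) + mult * c
    return out


def _saturate(net: PetriNet, support: set[str], m0: Marking) -> set[str]:
    """Transitions of ``support`` that can eventually fire at least once.

    A transition can fire eventually if every pre-place holds initial
    tokens or has an in-support producer that can itself fire eventually.
    Sound for proving *unfireability*: in any realizable sequence the
    first firing of each transition draws on the initial marking or on
    earlier (hence saturation-fireable) producers.
    """
    producers: dict[str, set[str]] = {}
    for t in support:
        for p in net.post(t):
            producers.setdefault(p, set()).add(t)
    fireable: set[str] = set()
    changed = True
    while changed:
        changed = False
        for t in support - fireable:
            ok = True
            for p in net.pre(t):
                if m0[p] > 0 or (producers.get(p, set()) & fireable):
                    continue
                ok = False
                break
            if ok:
                fireable.add(t)
                changed = True
    return fireable


def _missing_places(net: PetriNet, parikh: Mapping[str, int], m0: Marking) -> set[str]:
    """Places whose tokens block the combination, by eventual-firing saturation.

    A transition of the support can eventually fire if every pre-place has
    initial tokens or an in-support producer that can eventually fire.  In
    any realizable sequence the first firing of each transition draws its
    tokens from the initial marking or from transitions fired earlier, so a
    transition left out by the saturation can never fire: a non-empty
    result *proves* the combination unrealizable, and its places are the
    unproducible requirements another TI must supply.  The converse fails
    (saturation ignores consumption ordering), so an empty result still
    needs the explicit search.
    """
    support = set(parikh)
    producers: dict[str, set[str]] = {}
    for t in support:
        for p in net.post(t):
            producers.setdefault(p, set()).add(t)
    fireable = _saturate(net, support, m0)
    missing: set[str] = set()
    for t in support - fireable:
        for p in net.pre(t):
            if m0[p] == 0 and not (producers.get(p, set()) & fireable):
                missing.add(p)
    return missing


def manatee_invariants(
    net: PetriNet,
    tis: Sequence[TransitionInvariant],
    m0: Marking | None = None,
    max_coefficient: int = 3,
    max_combination: int = 3,
    node_budget: int = 200_000,
    max_states: int = 2_000_000,
    pis: Sequence[PlaceInvariant] | None = None,
) -> ManateeResult:
    """Enumerate Manatee invariants: for every TI, the minimal (by TI-set
    inclusion) realizable combinations containing it, deduplicated by
    Parikh vector across TIs.

    A combination containing a dissected TI may strictly contain another,
    smaller realizable combination (a complete pathway routinely includes
    the transcription-factor turnover flow, which is an MI of its own);
    minimality is therefore judged only against realizable combinations
    that share the anchor TI.

    ``max_combination`` caps the number of distinct TIs per combination,
    ``max_coefficient``
    the multiplicity a single TI may take when a weight->1 net needs
    parallel runs, ``node_budget`` bounds each witness search and
    ``max_states`` the overall exploration; every cut is recorded in
    ``inconclusive``, never silently dropped.
    """
    m0 = m0 if m0 is not None else net.initial_marking
    pi_places: set[str] = set()
    if pis:
        for pi in pis:
            pi_places |= pi.support

    n = len(tis)
    t_ids = net.transition_ids
    t_index = {t: k for k, t in enumerate(t_ids)}
    p_ids = net.place_ids
    p_index = {p: k for k, p in enumerate(p_ids)}

    # bitmask encodings: transitions and places as integer bit positions
    pre_masks = [0] * len(t_ids)
    post_masks = [0] * len(t_ids)
    pre_lists: list[list[int]] = []
    for k, t in enumerate(t_ids):
        pre = net.pre(t)
        post = net.post(t)
        for p in pre:
            pre_masks[k] |= 1 << p_index[p]
        for p in post:
            post_masks[k] |= 1 << p_index[p]
        pre_lists.append(sorted(p_index[p] for p in pre))
    m0_mask = 0
    for p, c in m0.items():
        if c > 0 and p in p_index:
            m0_mask |= 1 << p_index[p]

    ti_bits: list[frozenset[int]] = [
        frozenset(t_index[t] for t in ti.support) for ti in tis
    ]
    # providers[place bit] = TI indices containing a producer of the place
    providers: dict[int, set[int]] = {}
    for j, bits in enumerate(ti_bits):
        for k in bits:
            m = post_masks[k]
            while m:
                low = m & -m
                providers.setdefault(low.bit_length() - 1, set()).add(j)
                m ^= low

    post_lists: list[list[int]] = []
    for k in range(len(t_ids)):
        bits = []
        m = post_masks[k]
        while m:
            low = m & -m
            bits.append(low.bit_length() - 1)
            m ^= low
        post_lists.append(bits)
    consumers_of_place: dict[int, list[int]] = {}
    for k in range(len(t_ids)):
        for pb in pre_lists[k]:
            consumers_of_place.setdefault(pb, []).append(k)
    m0_places = {
        p_index[p] for p, c in m0.items() if c > 0 and p in p_index
    }

    def saturate_bits(support: frozenset[int]) -> set[int]:
        # worklist fixpoint: track per-transition count of unavailable
        # pre-places; a newly available place decrements its consumers
        avail = set(m0_places)
        need: dict[int, int] = {}
        stack: list[int] = []
        for k in support:
            n = sum(1 for pb in pre_lists[k] if pb not in avail)
            need[k] = n
            if n == 0:
                stack.append(k)
        fireable: set[int] = set()
        disc_order: list[int] = []
        while stack:
            k = stack.pop()
            if k in fireable:
                continue
            fireable.add(k)
            disc_order.append(k)
            for pb in post_lists[k]:
                if pb not in avail:
                    avail.add(pb)
                    for c in consumers_of_place.get(pb, ()):
                        if c in need and c not in fireable:
                            need[c] -= 1
                            if need[c] == 0:
                                stack.append(c)
        return fireable, disc_order

    # global place-bit -> producing transition indices (for chain walking)
    prod_trans: dict[int, set[int]] = {}
    for k in range(len(t_ids)):
        m = post_masks[k]
        while m:
            low = m & -m
            prod_trans.setdefault(low.bit_length() - 1, set()).add(k)
            m ^= low

    inconclusive: list[dict[int, int]] = []
    inconclusive_seen: set[frozenset[int]] = set()
    state_cache: dict[frozenset[int], tuple] = {}
    sat_cache: dict[frozenset[int], tuple[set[int], list[int]]] = {}
    states_used = 0
    budget_hit = False

    def evaluate(combo_set: frozenset[int]) -> tuple:
        """-> ("realized", combo, parikh, witness) | ("stuck", candidates)"""
        nonlocal states_used, budget_hit
        states_used += 1
        if states_used > max_states:
            budget_hit = True
        cached = state_cache.get(combo_set)
        if cached is not None:
            return cached
        support: frozenset[int] = frozenset().union(
            *(ti_bits[j] for j in combo_set)
        )
        cached_sat = sat_cache.get(support)
        if cached_sat is None:
            cached_sat = saturate_bits(support)
            sat_cache[support] = cached_sat
        fireable, disc_order = cached_sat
        stuck = support - fireable
        if not stuck:
            hint = [t_ids[k] for k in disc_order]
            combo = {j: 1 for j in combo_set}
            parikh = _combo_parikh(combo, tis)
            res = net.realize_parikh(
                parikh, m0, node_budget=node_budget, order_hint=hint
            )
            if res.status != "realized" and len(combo_set) == 1:
                # counting deadlock: a single TI may need parallel runs
                for mult in range(2, max_coefficient + 1):
                    combo = {j: mult for j in combo_set}
                    parikh = _combo_parikh(combo, tis)
                    res = net.realize_parikh(
                        parikh, m0, node_budget=node_budget, order_hint=hint
                    )
                    if res.status == "realized":
                        break
            if res.status == "realized":
                out = ("realized", combo, parikh, res.sequence or [])
            elif res.status == "inconclusive":
                inconclusive.append(dict(combo))
                out = ("stuck", frozenset())
            else:
                # ordering deadlock: offer providers of every empty pre-place
                cands: set[int] = set()
                for k in support:
                    for pb in pre_lists[k]:
                        if not (m0_mask >> pb) & 1:
                            cands |= providers.get(pb, set())
                out = ("stuck", frozenset(cands - combo_set))
            state_cache[combo_set] = out
            return out
        # branch along one dependency chain of the stuck support: at each
        # stuck transition pick one unavailable pre-place (AND node) and
        # collect its external providers (OR node), following in-support
        # stuck producers until a dead end or a borrowing cycle closes
        avail_fire = 0
        for k in fireable:
            avail_fire |= post_masks[k]
        cands = set()
        visited: set[int] = set()
        cur = min(stuck)
        while cur not in visited:
            visited.add(cur)
            blocked = [
                pb for pb in pre_lists[cur]
                if not (m0_mask >> pb) & 1 and not (avail_fire >> pb) & 1
            ]
            if not blocked:
                break
            pb = blocked[0]
            cands |= providers.get(pb, set())
            inner = sorted((prod_trans.get(pb, set()) & stuck) - visited)
            if not inner:
                break
            cur = inner[0]
        out = ("stuck", frozenset(cands - combo_set))
        state_cache[combo_set] = out
        return out

    # single global breadth-first walk over TI sets: every set is
    # evaluated once; stuck sets branch on their chain candidates.  A set
    # on the path from an anchor to one of its minimal completions is
    # never realizable before the completion (otherwise the completion
    # would not be minimal for that anchor), so branching only from stuck
    # sets loses nothing.
    realized_list: list[tuple[frozenset[int], dict, dict, list]] = []
    seen: set[frozenset[int]] = set()
    frontier: list[frozenset[int]] = []
    for j in range(n):
        s = frozenset({j})
        seen.add(s)
        frontier.append(s)
    while frontier and not budget_hit:
        nxt: list[frozenset[int]] = []
        for cs in frontier:
            if budget_hit:
                break
            state = evaluate(cs)
            if state[0] == "realized":
                realized_list.append((cs, state[1], state[2], state[3]))
                continue
            if len(cs) >= max_combination:
                if state[1] and cs not in inconclusive_seen:
                    inconclusive_seen.add(cs)
                    inconclusive.append({j: 1 for j in sorted(cs)})
                continue
            for j in sorted(state[1]):
                s = cs | {j}
                if s not in seen:
                    seen.add(s)
                    nxt.append(s)
        frontier = nxt

    # collect minimal-per-anchor combinations, dedupe by Parikh vector
    mis: list[ManateeInvariant] = []
    seen_parikh: set[tuple] = set()
    by_anchor: dict[int, list[int]] = {}
    for idx, (cs, _, _, _) in enumerate(realized_list):
        for a in cs:
            by_anchor.setdefault(a, []).append(idx)
    keep: set[int] = set()
    for anchor, idxs in by_anchor.items():
        sets = [realized_list[i][0] for i in idxs]
        for i, cs in zip(idxs, sets):
            if not any(other < cs for other in sets):
                keep.add(i)
    for i in sorted(keep):
        cs, combo, parikh, wit = realized_list[i]
        pk = tuple(sorted(parikh.items()))
        if pk in seen_parikh:
            continue
        seen_parikh.add(pk)
        mi = ManateeInvariant(dict(combo), parikh, wit)
        if pis is not None:
            mi.is_pure = not (net.induced_places(parikh) & pi_places)
        mis.append(mi)
    mis.sort(key=lambda m: (sum(m.ti_coefficients.values()),
                            sorted(m.ti_coefficients.items())))
    return ManateeResult(mis, inconclusive)


# -- classification --------------------------------------------------------


def classify_ti(
    net: PetriNet,
    ti: TransitionInvariant,
    mis: Iterable[ManateeInvariant] | ManateeResult,
    ti_index: int | None = None,
    tis: Sequence[TransitionInvariant] | None = None,
) -> str:
    """``complete`` if the TI alone is realizable (a singleton MI),
    ``trivial`` if additionally it is a bare synthesis->degradation turnover
    (one input, one output, at most one place in between), else
    ``dissected`` — an incomplete pathway that depends on other TIs."""
    singleton_supports = set()
    for mi in mis:
        if mi.is_singleton:
            if tis is not None:
                idx = next(iter(mi.ti_coefficients))
                singleton_supports.add(tis[idx].support)
            else:
                singleton_supports.add(mi.support)
    complete = ti.support in singleton_supports
    if not complete:
        return "dissected"
    inputs = [t for t in ti.support if net.transition_kind(t) == "input"]
    outputs = [t for t in ti.support if net.transition_kind(t) == "output"]
    if len(inputs) == 1 and len(outputs) == 1:
        if len(net.induced_places(ti.support)) <= 1:
            return "trivial"
    return "complete"


@dataclass
class OutcomeRules:
    """Mapping of response output transitions to labels plus resolution rules.

    ``response_outputs`` maps output transition ids to a response label.
    For MIs containing several response outputs, ``resolution_rules`` are
    tried in order: a rule fires when the MI contains every transition in
    ``requires_transitions`` and every label in ``requires_labels``;
    unresolved multi-response MIs are ``ambiguous``.  MIs without any
    response output are ``housekeeping``.
    """

    response_outputs: dict[str, str]
    resolution_rules: list[dict] = field(default_factory=list)

    @classmethod
    def from_json(cls, path) -> "OutcomeRules":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            response_outputs=data["response_outputs"],
            resolution_rules=data.get("resolution_rules", []),
        )

    def validate(self, net: PetriNet) -> None:
        for t in self.response_outputs:
            if t not in net.transitions:
                raise KeyError(f"rule references unknown transition {t!r}")
        for rule in self.resolution_rules:
            for t in rule.get("requires_transitions", []):
                if t not in net.transitions:
                    raise KeyError(f"rule references unknown transition {t!r}")


def classify_mi(mi: ManateeInvariant, rules: OutcomeRules) -> str:
    """Assign a cell-response label to an MI from its output transitions."""
    present = {
        t: rules.response_outputs[t]
        for t in mi.support
        if t in rules.response_outputs
    }
    labels = set(present.values())
    if not labels:
        return "housekeeping"
    if len(labels) == 1:
        return labels.pop()
    for rule in rules.resolution_rules:
        need_t = set(rule.get("requires_transitions", []))
        need_l = set(rule.get("requires_labels", []))
        if need_t <= mi.support and need_l <= labels:
            return rule["label"]
    return "ambiguous"


def classification_summary(
    mis: Iterable[ManateeInvariant], rules: OutcomeRules
) -> dict[str, int]:
    """Label counts; ``counted`` sums the uniquely resolved responses
    (housekeeping and ambiguous are the neglected remainder)."""
    counts = {
        "survival": 0,
        "apoptosis": 0,
        "necroptosis": 0,
        "ambiguous": 0,
        "housekeeping": 0,
    }
    for mi in mis:
        label = classify_mi(mi, rules)
        mi.outcome_label = label
        counts[label] = counts.get(label, 0) + 1
    counts["counted"] = (
        counts["survival"] + counts["apoptosis"] + counts["necroptosis"]
    )
    counts["total"] = sum(
        counts[k]
        for k in ("survival", "apoptosis", "necroptosis", "ambiguous", "housekeeping")
    )
    return counts


def mis_to_json(result: ManateeResult, path) -> None:
    data = {
        "manatee_invariants": [
            {
                "index": i + 1,
                "ti_coefficients": {str(k + 1): v for k, v in mi.ti_coefficients.items()},
                "parikh": mi.parikh,
                "witness": mi.witness,
                "is_pure": mi.is_pure,
                "outcome_label": mi.outcome_label,
            }
            for i, mi in enumerate(result.mis)
        ],
        # budget-cut combinations can number in the hundreds of thousands;
        # the full list stays on the result object, the export keeps the
        # count and a sample
        "n_inconclusive_combinations": len(result.inconclusive),
        "inconclusive_sample": [
            {str(k + 1): v for k, v in c.items()}
            for c in result.inconclusive[:100]
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
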