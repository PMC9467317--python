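"""Discrete place/transition nets with token-firing semantics.

A P/T net is the quintuple ``N = (P, T, F, W, m0)``: places ``P`` (passive
entities — proteins, genes, complexes), transitions ``T`` (reactions),
weighted flow relation ``F``/``W`` and an initial marking ``m0`` assigning
non-negative token counts to places.  Tokens move by *firing* enabled
transitions: a transition is enabled when every pre-place holds at least the
arc weight; firing removes those tokens and produces tokens on post-places
in the same step.

Read arcs (bidirectional test arcs) are supported: the tested place is
required for enabling but its token count is unchanged by firing.  They are
stored explicitly as a flagged pair of opposite arcs and are *excluded* from
the incidence matrix, which is only defined for pure nets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Place",
    "Transition",
    "Arc",
    "Marking",
    "PetriNet",
    "PetriNetError",
    "UnknownIdError",
    "NotEnabledError",
    "ValidationError",
    "ParikhResult",
]


class PetriNetError(Exception):
    """Base class for net-related errors."""


class UnknownIdError(PetriNetError, KeyError):
    """A referenced place or transition id does not exist in the net."""


class NotEnabledError(PetriNetError):
    """A transition was fired in a marking where it is not enabled."""


class ValidationError(PetriNetError):
    """The net violates a structural invariant (bipartiteness, ids, weights)."""


@dataclass(frozen=True)
class Place:
    id: str
    name: str | None = None
    annotation: str | None = None
    is_logical_copy: bool = False

    @property
    def label(self) -> str:
        return self.name if self.name is not None else self.id


@dataclass(frozen=True)
class Transition:
    id: str
    name: str | None = None

    @property
    def label(self) -> str:
        return self.name if self.name is not None else self.id


@dataclass(frozen=True)
class Arc:
    """Directed weighted edge between a place and a transition.

    ``read_arc`` flags one half of a bidirectional test-arc pair; the two
    halves always carry equal weight.
    """

    source: str
    target: str
    weight: int = 1
    read_arc: bool = False


class Marking(dict):
    """Token-count vector over places, ``place id -> count >= 0``.

    Missing places count as zero, so sparse construction is fine.
    """

    def __init__(self, counts: Mapping[str, int] | None = None):
        super().__init__()
        if counts:
            for k, v in counts.items():
                if v < 0:
                    raise ValidationError(f"negative token count for {k!r}")
                if v:
                    self[k] = int(v)

    def __missing__(self, key: str) -> int:
        return 0

    def copy(self) -> "Marking":
        m = Marking()
        dict.update(m, self)
        return m

    def as_tuple(self, order: Sequence[str]) -> tuple[int, ...]:
        return tuple(self[p] for p in order)

    def total(self) -> int:
        return sum(self.values())


@dataclass
class ParikhResult:
    """Outcome of a firing-sequence search for a Parikh vector.

    ``status`` is ``"realized"`` (with a witness ``sequence``),
    ``"unrealizable"`` (exhaustive search proved no ordering works) or
    ``"inconclusive"`` (the node budget ran out — never silently conflated
    with a proof).
    """

    status: str
    sequence: list[str] | None = None
    nodes_explored: int = 0

    @property
    def realized(self) -> bool:
        return self.status == "realized"


class PetriNet:
    """A place/transition net with an initial marking.

    Places, transitions and arcs are kept in insertion order; all matrix
    and vector indexing uses the lexicographic order of ids so that every
    downstream result is reproducible regardless of construction order.
    """

    def __init__(self, name: str = "net"):
        self.name = name
        self._places: dict[str, Place] = {}
        self._transitions: dict[str, Transition] = {}
        self.arcs: list[Arc] = []
        self.initial_marking: Marking = Marking()

    # -- construction -----------------------------------------------------

    def add_place(
        self,
        pid: str,
        name: str | None = None,
        annotation: str | None = None,
        tokens: int = 0,
    ) -> Place:
        if pid in self._places or pid in self._transitions:
            raise ValidationError(f"duplicate id {pid!r}")
        p = Place(pid, name, annotation)
        self._places[pid] = p
        if tokens:
            self.initial_marking[pid] = tokens
        return p

    def add_transition(self, tid: str, name: str | None = None) -> Transition:
        if tid in self._places or tid in self._transitions:
            raise ValidationError(f"duplicate id {tid!r}")
        t = Transition(tid, name)
        self._transitions[tid] = t
        return t

    def add_arc(self, source: str, target: str, weight: int = 1) -> Arc:
        self._check_arc(source, target, weight)
        a = Arc(source, target, weight)
        self.arcs.append(a)
        return a

    def add_read_arc(self, place: str, transition: str, weight: int = 1) -> None:
        """Add a bidirectional test arc between ``place`` and ``transition``."""
        self._check_arc(place, transition, weight)
        self.arcs.append(Arc(place, transition, weight, read_arc=True))
        self.arcs.append(Arc(transition, place, weight, read_arc=True))

    def _check_arc(self, source: str, target: str, weight: int) -> None:
        if weight < 1:
            raise ValidationError(f"arc weight must be >= 1, got {weight}")
        s_place = source in self._places
        t_place = target in self._places
        if source not in self._places and source not in self._transitions:
            raise UnknownIdError(source)
        if target not in self._places and target not in self._transitions:
            raise UnknownIdError(target)
        if s_place == t_place:
            raise ValidationError(
                f"arc {source!r}->{target!r} violates bipartiteness"
            )

    # -- accessors --------------------------------------------------------

    @property
    def places(self) -> dict[str, Place]:
        return self._places

    @property
    def transitions(self) -> dict[str, Transition]:
        return self._transitions

    @property
    def place_ids(self) -> list[str]:
        """Place ids in canonical (lexicographic) order."""
        return sorted(self._places)

    @property
    def transition_ids(self) -> list[str]:
        """Transition ids in canonical (lexicographic) order."""
        return sorted(self._transitions)

    def __contains__(self, vid: str) -> bool:
        return vid in self._places or vid in self._transitions

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PetriNet {self.name!r}: |P|={len(self._places)} "
            f"|T|={len(self._transitions)} |F|={len(self.arcs)}>"
        )

    def pre(self, tid: str) -> dict[str, int]:
        """Pre-places of a transition with consumption weights.

        Read arcs count: the tested place must carry the weight for the
        transition to be enabled.
        """
        self._require_transition(tid)
        out: dict[str, int] = {}
        for a in self.arcs:
            if a.target == tid:
                out[a.source] = out.get(a.source, 0) + a.weight
        return out

    def post(self, tid: str) -> dict[str, int]:
        self._require_transition(tid)
        out: dict[str, int] = {}
        for a in self.arcs:
            if a.source == tid:
                out[a.target] = out.get(a.target, 0) + a.weight
        return out

    def place_pre(self, pid: str) -> dict[str, int]:
        """Transitions producing onto a place (with weights)."""
        self._require_place(pid)
        out: dict[str, int] = {}
        for a in self.arcs:
            if a.target == pid:
                out[a.source] = out.get(a.source, 0) + a.weight
        return out

    def place_post(self, pid: str) -> dict[str, int]:
        self._require_place(pid)
        out: dict[str, int] = {}
        for a in self.arcs:
            if a.source == pid:
                out[a.target] = out.get(a.target, 0) + a.weight
        return out

    def transition_kind(self, tid: str) -> str:
        """``input`` (no incoming arcs: synthesis), ``output`` (no outgoing:
        degradation / response), else ``internal``."""
        if not self.pre(tid):
            return "input"
        if not self.post(tid):
            return "output"
        return "internal"

    def input_transitions(self) -> list[str]:
        return [t for t in self.transition_ids if self.transition_kind(t) == "input"]

    def output_transitions(self) -> list[str]:
        return [t for t in self.transition_ids if self.transition_kind(t) == "output"]

    def _require_transition(self, tid: str) -> None:
        if tid not in self._transitions:
            raise UnknownIdError(tid)

    def _require_place(self, pid: str) -> None:
        if pid not in self._places:
            raise UnknownIdError(pid)

    # -- incidence matrix -------------------------------------------------

    def incidence_matrix(self) -> np.ndarray:
        """Integer |P| x |T| matrix C, rows/columns in canonical id order.

        ``C[p, t] = W(t, p) - W(p, t)``: tokens produced minus consumed on
        place ``p`` per firing of ``t``.  Read-arc pairs contribute 0 and
        are skipped, so C describes the pure skeleton of the net.
        """
        prow = {p: i for i, p in enumerate(self.place_ids)}
        tcol = {t: j for j, t in enumerate(self.transition_ids)}
        C = np.zeros((len(prow), len(tcol)), dtype=np.int64)
        for a in self.arcs:
            if a.read_arc:
                continue
            if a.source in prow:  # place -> transition: consumption
                C[prow[a.source], tcol[a.target]] -= a.weight
            else:  # transition -> place: production
                C[prow[a.target], tcol[a.source]] += a.weight
        return C

    # -- semantics --------------------------------------------------------

    def is_enabled(self, m: Marking, tid: str) -> bool:
        self._require_transition(tid)
        return all(m[p] >= w for p, w in self.pre(tid).items())

    def enabled_transitions(self, m: Marking) -> list[str]:
        return [t for t in self.transition_ids if self.is_enabled(m, t)]

    def fire(self, m: Marking, tid: str) -> Marking:
        """Fire ``tid`` at ``m``; returns the successor marking.

        Read arcs test but do not move tokens: the paired opposite arcs
        cancel, so the tested place keeps its count.
        """
        if not self.is_enabled(m, tid):
            raise NotEnabledError(f"{tid!r} is not enabled")
        m2 = m.copy()
        for p, w in self.pre(tid).items():
            m2[p] = m2[p] - w
        for p, w in self.post(tid).items():
            m2[p] = m2[p] + w
        for p in [p for p, c in m2.items() if c == 0]:
            del m2[p]
        return m2

    def realize_parikh(
        self,
        counts: Mapping[str, int],
        m0: Marking | None = None,
        node_budget: int = 1_000_000,
        order_hint: Sequence[str] | None = None,
    ) -> ParikhResult:
        """Search for a firing sequence with the given per-transition counts.

        Depth-first backtracking over orderings, memoising failed
        (remaining-counts, marking) states.  Greedy firing can deadlock on
        orders another order completes, hence the exhaustive search.  A
        budget overrun returns ``inconclusive``, never a silent failure.

        ``order_hint`` sets the preference order in which the search tries
        transitions; a dependency-respecting order (producers before their
        consumers) usually yields a witness with little backtracking.
        """
        for t in counts:
            self._require_transition(t)
        m = (m0 if m0 is not None else self.initial_marking).copy()
        if order_hint is not None:
            rank = {t: i for i, t in enumerate(order_hint)}
            order = sorted(
                (t for t in self.transition_ids if counts.get(t, 0) > 0),
                key=lambda t: (rank.get(t, len(rank)), t),
            )
        else:
            order = [t for t in self.transition_ids if counts.get(t, 0) > 0]
        remaining = {t: int(counts[t]) for t in order}
        total = sum(remaining.values())
        if total == 0:
            return ParikhResult("realized", [])

        pre = {t: self.pre(t) for t in order}
        post = {t: self.post(t) for t in order}
        delta = {
            t: {
                p: post[t].get(p, 0) - pre[t].get(p, 0)
                for p in set(pre[t]) | set(post[t])
            }
            for t in order
        }
        relevant_places = sorted({p for t in order for p in delta[t]} |
                                 {p for t in order for p in pre[t]})

        failed: set[tuple] = set()
        seq: list[str] = []
        nodes = 0
        budget_hit = False

        def key(mk: Marking, rem: dict[str, int]) -> tuple:
            return (
                tuple(rem[t] for t in order),
                tuple(mk[p] for p in relevant_places),
            )

        def dfs(mk: Marking, rem: dict[str, int], left: int) -> bool:
            nonlocal nodes, budget_hit
            if left == 0:
                return True
            k = key(mk, rem)
            if k in failed:
                return False
            nodes += 1
            if nodes > node_budget:
                budget_hit = True
                return False
            for t in order:
                if rem[t] == 0:
                    continue
                if any(mk[p] < w for p, w in pre[t].items()):
                    continue
                mk2 = mk.copy()
                for p, d in delta[t].items():
                    nv = mk2[p] + d
                    if nv:
                        mk2[p] = nv
                    elif p in mk2:
                        del mk2[p]
                rem[t] -= 1
                seq.append(t)
                if dfs(mk2, rem, left - 1):
                    return True
                seq.pop()
                rem[t] += 1
                if budget_hit:
                    return False
            failed.add(k)
            return False

        ok = dfs(m, remaining, total)
        if ok:
            return ParikhResult("realized", list(seq), nodes)
        if budget_hit:
            return ParikhResult("inconclusive", None, nodes)
        return ParikhResult("unrealizable", None, nodes)

    # -- subnetworks ------------------------------------------------------

    def induced_subnetwork(self, transition_support: Iterable[str]) -> "PetriNet":
        """Subnet formed by the given transitions, all adjacent places, and
        every arc between those vertices."""
        support = set(transition_support)
        for t in support:
            self._require_transition(t)
        sub = PetriNet(name=f"{self.name}|{len(support)}t")
        places: set[str] = set()
        for a in self.arcs:
            if a.source in support:
                places.add(a.target)
            elif a.target in support:
                places.add(a.source)
        for pid in sorted(places):
            p = self._places[pid]
            sub._places[pid] = p
            if self.initial_marking[pid]:
                sub.initial_marking[pid] = self.initial_marking[pid]
        for tid in sorted(support):
            sub._transitions[tid] = self._transitions[tid]
        for a in self.arcs:
            if (a.source in support and a.target in places) or (
                a.target in support and a.source in places
            ):
                sub.arcs.append(a)
        return sub

    def induced_places(self, transition_support: Iterable[str]) -> set[str]:
        """Places adjacent to any transition in the support."""
        support = set(transition_support)
        places: set[str] = set()
        for a in self.arcs:
            if a.source in support:
                places.add(a.target)
            elif a.target in support:
                places.add(a.source)
        return places

    # -- misc -------------------------------------------------------------

    def validate(self) -> None:
        """Re-check structural invariants; raises ValidationError."""
        for a in self.arcs:
            s_place = a.source in self._places
            t_place = a.target in self._places
            if a.source not in self or a.target not in self:
                raise ValidationError(f"dangling arc {a.source!r}->{a.target!r}")
            if s_place == t_place:
                raise ValidationError(
                    f"arc {a.source!r}->{a.target!r} violates bipartiteness"
                )
            if a.weight < 1:
                raise ValidationError("non-positive arc weight")
        for pid in self.initial_marking:
            if pid not in self._places:
                raise ValidationError(f"marking on unknown place {pid!r}")

    def copy(self) -> "PetriNet":
        net = PetriNet(self.name)
        net._places = dict(self._places)
        net._transitions = dict(self._transitions)
        net.arcs = list(self.arcs)
        net.initial_marking = self.initial_marking.copy()
        return net

    def without_transitions(self, tids: Iterable[str]) -> "PetriNet":
        """Structural deletion of transitions (and their arcs)."""
        drop = set(tids)
        for t in drop:
            self._require_transition(t)
        net = PetriNet(self.name + "-ko")
        net._places = dict(self._places)
        net._transitions = {
            k: v for k, v in self._transitions.items() if k not in drop
        }
        net.arcs = [
            a for a in self.arcs if a.source not in drop and a.target not in drop
        ]
        net.initial_marking = self.initial_marking.copy()
        return net
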