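"""Minimal semi-positive place and transition invariants.

A transition invariant (TI) is a non-negative integer Parikh vector ``x``
with ``C x = 0``: firing every transition of its support ``x[t]`` times
returns any marking to itself — a steady-state pathway.  A place invariant
(PI) is a non-negative integer vector ``y`` with ``y C = 0``: the weighted
token sum ``y . m`` is conserved along every firing sequence — a substance
conservation law.  We enumerate the *minimal* ones: gcd of the positive
coefficients is 1 and no other invariant's support is a proper subset.

The enumeration is the classical Farkas / Fourier–Motzkin column
elimination on ``[A | I]`` keeping only non-negative combinations, with
support-minimality pruning after every elimination step to control the
intermediate blow-up.  All arithmetic is exact (Python integers); no
floating point is involved anywhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .net import Marking, PetriNet

__all__ = [
    "Invariant",
    "TransitionInvariant",
    "PlaceInvariant",
    "CoverageReport",
    "minimal_semipositive_invariants",
    "transition_invariants",
    "place_invariants",
    "coverage",
    "brute_force_invariants",
    "invariants_to_json",
    "invariants_to_tsv",
    "invariants_from_json",
]


@dataclass(frozen=True)
class Invariant:
    """A gcd-normalised minimal semi-positive invariant vector.

    ``coefficients`` maps ids (transition ids for TIs, place ids for PIs)
    with positive coefficient to their value; ``support`` is its key set.
    """

    coefficients: tuple[tuple[str, int], ...]

    @property
    def as_dict(self) -> dict[str, int]:
        return dict(self.coefficients)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(k for k, _ in self.coefficients)

    def vector(self, order: Sequence[str]) -> np.ndarray:
        d = self.as_dict
        return np.array([d.get(k, 0) for k in order], dtype=np.int64)

    def __getitem__(self, key: str) -> int:
        return self.as_dict.get(key, 0)

    @classmethod
    def from_mapping(cls, coeffs: dict[str, int]) -> "Invariant":
        items = tuple(sorted((k, int(v)) for k, v in coeffs.items() if v > 0))
        return cls(items)


class TransitionInvariant(Invariant):
    pass


class PlaceInvariant(Invariant):
    pass


@dataclass
class CoverageReport:
    """Which transitions/places lie in at least one invariant support.

    A net is CTI (covered by TIs) iff every transition is in some TI's
    support; CPI analogously for places.  CTI is the structural consistency
    criterion: a transition in no TI can never fire at steady state.
    """

    covered_transitions: set[str] = field(default_factory=set)
    covered_places: set[str] = field(default_factory=set)
    uncovered_transitions: list[str] = field(default_factory=list)
    uncovered_places: list[str] = field(default_factory=list)

    @property
    def is_CTI(self) -> bool:
        return not self.uncovered_transitions

    @property
    def is_CPI(self) -> bool:
        return not self.uncovered_places


def _gcd_normalise(vec: list[int]) -> list[int]:
    g = 0
    for v in vec:
        g = math.gcd(g, v)
    if g > 1:
        return [v // g for v in vec]
    return list(vec)


def _prune_non_minimal(rows: list[tuple[list[int], list[int]]]) -> list[tuple[list[int], list[int]]]:
    """Drop rows whose invariant-part support strictly contains another's.

    Among rows with identical support, keep only vectors no other row
    divides (componentwise multiple).
    """
    supports = [frozenset(i for i, v in enumerate(inv) if v) for _, inv in rows]
    keep = [True] * len(rows)
    for i in range(len(rows)):
        if not keep[i]:
            continue
        for j in range(len(rows)):
            if i == j or not keep[j]:
                continue
            if supports[j] < supports[i]:
                keep[i] = False
                break
            if supports[j] == supports[i] and j < i and rows[j][1] == rows[i][1]:
                keep[i] = False
                break
        else:
            continue
    return [r for r, k in zip(rows, keep) if k]


def minimal_semipositive_invariants(A: np.ndarray) -> list[dict[int, int]]:
    """All minimal semi-positive integer solutions ``x >= 0`` of ``A x = 0``.

    ``A`` has one column per unknown.  Returns coefficient dicts keyed by
    column index.  Farkas elimination: maintain rows ``[constraint-part |
    identity-part]`` starting from ``[A^T | I]``; eliminate constraint
    columns one at a time, combining rows of opposite sign with exact
    integer multipliers, pruning non-minimal supports after each step.
    """
    A = np.asarray(A, dtype=object)
    if A.ndim != 2:
        raise ValueError("A must be a matrix")
    n_con, n_var = A.shape
    # rows: (constraint residual, candidate invariant vector)
    rows: list[tuple[list[int], list[int]]] = []
    for j in range(n_var):
        con = [int(A[i, j]) for i in range(n_con)]
        inv = [0] * n_var
        inv[j] = 1
        rows.append((con, inv))

    # eliminate constraints in ascending density order to limit blow-up
    order = sorted(
        range(n_con), key=lambda i: sum(1 for j in range(n_var) if A[i, j] != 0)
    )
    remaining = list(range(n_con))
    for ci in order:
        pos = [r for r in rows if r[0][ci] > 0]
        neg = [r for r in rows if r[0][ci] < 0]
        zero = [r for r in rows if r[0][ci] == 0]
        new_rows = list(zero)
        for cp, ip in pos:
            for cn, iN in neg:
                a, b = cp[ci], -cn[ci]
                g = math.gcd(a, b)
                ma, mb = b // g, a // g  # ma*cp + mb*cn cancels column ci
                con = [ma * x + mb * y for x, y in zip(cp, cn)]
                inv = [ma * x + mb * y for x, y in zip(ip, iN)]
                # con = A @ inv holds per row, so the inv gcd divides con too;
                # divide both to keep the pair consistent and entries small
                g2 = 0
                for v in inv:
                    g2 = math.gcd(g2, v)
                if g2 > 1:
                    inv = [v // g2 for v in inv]
                    con = [v // g2 for v in con]
                new_rows.append((con, inv))
        rows = _prune_non_minimal(new_rows)

    out: list[dict[int, int]] = []
    seen: set[tuple] = set()
    for con, inv in rows:
        if any(con):
            continue
        vec = _gcd_normalise(inv)
        key = tuple(vec)
        if key in seen:
            continue
        seen.add(key)
        out.append({j: v for j, v in enumerate(vec) if v})
    # final minimality pass over the full solution set
    out = _filter_minimal_support(out)
    return out


def _filter_minimal_support(sols: list[dict[int, int]]) -> list[dict[int, int]]:
    keep: list[dict[int, int]] = []
    supports = [frozenset(s) for s in sols]
    for i, s in enumerate(sols):
        minimal = True
        for j, other in enumerate(sols):
            if i == j:
                continue
            if supports[j] < supports[i]:
                minimal = False
                break
            if supports[j] == supports[i] and j < i:
                # equal support: keep both only if neither divides the other
                q = None
                divides = True
                for k in supports[i]:
                    if s[k] % other[k]:
                        divides = False
                        break
                    r = s[k] // other[k]
                    if q is None:
                        q = r
                    elif q != r:
                        divides = False
                        break
                if divides:
                    minimal = False
                    break
        if minimal:
            keep.append(s)
    return keep


def _canonical_sort(invs: list[Invariant]) -> list[Invariant]:
    return sorted(invs, key=lambda v: (len(v.support), sorted(v.support), v.coefficients))


def transition_invariants(net: PetriNet) -> list[TransitionInvariant]:
    """All minimal semi-positive TIs of the net (exact arithmetic).

    The numbering produced by the canonical sort (support size, then ids)
    is stable across runs but tool-specific.
    """
    C = net.incidence_matrix()  # |P| x |T|; solve C x = 0
    tids = net.transition_ids
    sols = minimal_semipositive_invariants(C)
    invs = [
        TransitionInvariant.from_mapping({tids[j]: v for j, v in s.items()})
        for s in sols
    ]
    return _canonical_sort(invs)  # type: ignore[return-value]


def place_invariants(net: PetriNet) -> list[PlaceInvariant]:
    """All minimal semi-positive PIs of the net: ``y C = 0``."""
    C = net.incidence_matrix()
    pids = net.place_ids
    sols = minimal_semipositive_invariants(C.T)
    invs = [
        PlaceInvariant.from_mapping({pids[j]: v for j, v in s.items()}) for s in sols
    ]
    return _canonical_sort(invs)  # type: ignore[return-value]


def coverage(
    net: PetriNet,
    tis: Iterable[TransitionInvariant],
    pis: Iterable[PlaceInvariant],
) -> CoverageReport:
    ct: set[str] = set()
    for ti in tis:
        ct |= ti.support
    cp: set[str] = set()
    for pi in pis:
        cp |= pi.support
    return CoverageReport(
        covered_transitions=ct,
        covered_places=cp,
        uncovered_transitions=[t for t in net.transition_ids if t not in ct],
        uncovered_places=[p for p in net.place_ids if p not in cp],
    )


def verify_invariant(C: np.ndarray, vec: np.ndarray, kind: str = "ti") -> bool:
    """Exact check that ``C x = 0`` (TI) or ``y C = 0`` (PI)."""
    Cobj = C.astype(object)
    if kind == "ti":
        return not np.any(Cobj @ vec.astype(object))
    return not np.any(vec.astype(object) @ Cobj)


def brute_force_invariants(
    A: np.ndarray, max_coeff: int = 4
) -> list[dict[int, int]]:
    """Bounded exhaustive enumeration oracle for tiny systems.

    Enumerates every vector with entries in ``0..max_coeff`` solving
    ``A x = 0``, then reduces to minimal-support gcd-1 representatives.
    Exponential — only for nets with <= ~7 unknowns in tests.
    """
    A = np.asarray(A, dtype=object)
    n_var = A.shape[1]
    sols: list[dict[int, int]] = []
    for combo in product(range(max_coeff + 1), repeat=n_var):
        if not any(combo):
            continue
        if any(sum(int(A[i, j]) * combo[j] for j in range(n_var)) for i in range(A.shape[0])):
            continue
        vec = _gcd_normalise(list(combo))
        d = {j: v for j, v in enumerate(vec) if v}
        if d not in sols:
            sols.append(d)
    return _filter_minimal_support(sols)


# -- import/export --------------------------------------------------------


def invariants_to_json(invs: Sequence[Invariant], path) -> None:
    data = [
        {"index": i + 1, "coefficients": inv.as_dict, "support": sorted(inv.support)}
        for i, inv in enumerate(invs)
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def invariants_to_tsv(invs: Sequence[Invariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("index\tsupport_size\tcoefficients\n")
        for i, inv in enumerate(invs):
            coeffs = ",".join(f"{k}:{v}" for k, v in inv.coefficients)
            fh.write(f"{i + 1}\t{len(inv.support)}\t{coeffs}\n")


def invariants_from_json(path, kind: str = "ti") -> list[Invariant]:
    """Import externally computed invariants for cross-checking."""
    cls = TransitionInvariant if kind == "ti" else PlaceInvariant
    with open(path) as fh:
        data = json.load(fh)
    return [cls.from_mapping(rec["coefficients"]) for rec in data]
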