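"""MI-based in-silico knockout analysis.

A knockout deletes synthesis (input) transitions.  An MI *survives* a
knockout iff its Parikh support contains none of the knocked transitions;
a place is *affected* (red) iff it lies in no surviving MI-induced
subnetwork, among the places covered by at least one MI overall.  This is
exactly the structural consequence of deleting the transitions: every
pathway through them disappears, and species reachable only through those
pathways can no longer be formed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .invariants import PlaceInvariant
from .manatee import ManateeInvariant
from .net import PetriNet, UnknownIdError

__all__ = [
    "KnockoutExperiment",
    "KnockoutMatrix",
    "ProteinRanking",
    "knockout_affected",
    "knockout_matrix",
    "rank_proteins",
    "multiple_knockout_preset",
    "matrix_to_csv",
    "ranking_to_tsv",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class KnockoutExperiment:
    """A named deletion of one or more synthesis transitions."""

    name: str
    knocked_transitions: frozenset[str]

    @classmethod
    def single(cls, transition: str, name: str | None = None) -> "KnockoutExperiment":
        return cls(name or transition, frozenset({transition}))

    def validate(self, net: PetriNet, inputs_only: bool = True) -> None:
        for t in self.knocked_transitions:
            if t not in net.transitions:
                raise UnknownIdError(t)
            if inputs_only and net.transition_kind(t) == "internal" and net.pre(t):
                # synthesis semantics: input transitions, or translation
                # transitions consuming only an mRNA — anything else needs
                # inputs_only=False
                pres = net.pre(t)
                if not all(p.lower().endswith("mrna") for p in pres):
                    raise ConfigurationError(
                        f"{t!r} is not a synthesis transition; pass "
                        "inputs_only=False to knock out arbitrary transitions"
                    )


@dataclass
class KnockoutMatrix:
    rows: list[KnockoutExperiment]
    columns: list[str]
    affected: list[list[bool]]  # rows x columns, True = affected (red)
    uncovered_places: list[str] = field(default_factory=list)

    def row(self, name: str) -> list[bool]:
        for exp, vals in zip(self.rows, self.affected):
            if exp.name == name:
                return vals
        raise KeyError(name)

    def affected_places(self, name: str) -> set[str]:
        return {c for c, v in zip(self.columns, self.row(name)) if v}

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.columns))


def _mi_survives(mi: ManateeInvariant, knocked: frozenset[str]) -> bool:
    return not (mi.support & knocked)


def knockout_affected(
    net: PetriNet,
    mis: Sequence[ManateeInvariant],
    experiment: KnockoutExperiment,
    columns: Iterable[str] | None = None,
    inputs_only: bool = True,
) -> set[str]:
    """Places affected by the experiment (restricted to ``columns`` if given).

    Only places inside at least one MI-induced subnetwork are eligible:
    a place never covered by any MI is structurally dead, not knocked out.
    """
    experiment.validate(net, inputs_only=inputs_only)
    covered: set[str] = set()
    surviving: set[str] = set()
    for mi in mis:
        places = net.induced_places(mi.support)
        covered |= places
        if _mi_survives(mi, experiment.knocked_transitions):
            surviving |= places
    affected = covered - surviving
    if columns is not None:
        affected &= set(columns)
    return affected


def knockout_matrix(
    net: PetriNet,
    mis: Sequence[ManateeInvariant],
    experiments: Sequence[KnockoutExperiment] | None = None,
    columns: Sequence[str] | None = None,
    pis: Sequence[PlaceInvariant] | None = None,
    inputs_only: bool = True,
) -> KnockoutMatrix:
    """Row-wise knockouts over a column set of places.

    Defaults: one single-knockout row per synthesis input transition;
    columns are all places except PI-support places (conserved gene places
    are never producible or blockable) and except places no MI covers,
    which are reported in ``uncovered_places`` instead of padding the
    matrix with trivially red columns.
    """
    if experiments is None:
        experiments = [
            KnockoutExperiment.single(t) for t in net.input_transitions()
        ]
    if not experiments:
        raise ConfigurationError("no knockout experiments given")

    covered: set[str] = set()
    for mi in mis:
        covered |= net.induced_places(mi.support)

    if columns is None:
        pi_places: set[str] = set()
        for pi in pis or []:
            pi_places |= pi.support
        cols = [p for p in net.place_ids if p not in pi_places]
    else:
        cols = list(columns)
    uncovered = [p for p in cols if p not in covered]
    cols = [p for p in cols if p in covered]

    matrix: list[list[bool]] = []
    for exp in experiments:
        aff = knockout_affected(net, mis, exp, columns=cols, inputs_only=inputs_only)
        matrix.append([c in aff for c in cols])
    return KnockoutMatrix(list(experiments), cols, matrix, uncovered)


@dataclass
class ProteinRanking:
    """Per-experiment affected fractions, sorted descending.

    ``mi_fraction``: share of MIs containing a knocked transition (the
    pathways the knockout destroys).  ``place_fraction``: share of matrix
    columns affected.  The primary sort key is configurable; ties break
    lexicographically by experiment name.
    """

    entries: list[tuple[str, float, float]]  # (name, mi_fraction, place_fraction)

    def top(self, n: int = 5) -> list[str]:
        return [e[0] for e in self.entries[:n]]

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            name: {"mi_fraction": mf, "place_fraction": pf}
            for name, mf, pf in self.entries
        }


def rank_proteins(
    matrix: KnockoutMatrix,
    mis: Sequence[ManateeInvariant],
    key: str = "mi_fraction",
) -> ProteinRanking:
    if key not in ("mi_fraction", "place_fraction"):
        raise ConfigurationError(f"unknown ranking key {key!r}")
    n_mi = len(mis)
    n_col = len(matrix.columns)
    entries: list[tuple[str, float, float]] = []
    for exp, row in zip(matrix.rows, matrix.affected):
        hit = sum(
            1 for mi in mis if not _mi_survives(mi, exp.knocked_transitions)
        )
        mf = hit / n_mi if n_mi else 0.0
        pf = sum(row) / n_col if n_col else 0.0
        entries.append((exp.name, mf, pf))
    idx = 1 if key == "mi_fraction" else 2
    entries.sort(key=lambda e: (-e[idx], e[0]))
    return ProteinRanking(entries)


def multiple_knockout_preset(
    name: str, presets: Mapping[str, Iterable[str]]
) -> KnockoutExperiment:
    """Look up a named multi-knockout (e.g. a drug-mimicking combination)."""
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    return KnockoutExperiment(name, frozenset(presets[name]))


def matrix_to_csv(matrix: KnockoutMatrix, path, long_format: bool = False) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if long_format:
            w.writerow(["experiment", "place", "affected"])
            for exp, row in zip(matrix.rows, matrix.affected):
                for col, v in zip(matrix.columns, row):
                    w.writerow([exp.name, col, int(v)])
        else:
            w.writerow(["experiment"] + matrix.columns)
            for exp, row in zip(matrix.rows, matrix.affected):
                w.writerow([exp.name] + [int(v) for v in row])


def ranking_to_tsv(ranking: ProteinRanking, path) -> None:
    with open(path, "w") as fh:
        fh.write("experiment\tmi_fraction\tplace_fraction\n")
        for name, mf, pf in ranking.entries:
            fh.write(f"{name}\t{mf:.6f}\t{pf:.6f}\n")
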