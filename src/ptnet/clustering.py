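"""UPGMA clustering of knockout profiles under Pearson-correlation distance.

Each knockout experiment is represented by the binary vector of places its
knockout blocks; proteins whose knockouts block the same species cluster
together.  Distance is ``d = 1 - r`` (Pearson), so identical non-constant
profiles sit at 0 and perfectly anti-correlated ones at 2; UPGMA
(average linkage with size-weighted means) produces an ultrametric tree.

The implementation is deliberately explicit rather than delegated: the
tie-breaking (lexicographically smallest label pair among equal minimal
distances) and the zero-variance fallback are part of the contract and are
cross-checked against scipy's average linkage in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .net import ValidationError

__all__ = [
    "KnockoutProfile",
    "ClusterNode",
    "pearson_distance",
    "distance_matrix",
    "distance_matrix_to_tsv",
    "upgma",
    "tree_labels",
    "to_newick",
]


@dataclass(frozen=True)
class KnockoutProfile:
    label: str
    vector: tuple[int, ...]


def pearson_distance(
    a: Sequence[int] | KnockoutProfile,
    b: Sequence[int] | KnockoutProfile,
    halved: bool = False,
) -> float:
    """``1 - r`` (or ``(1 - r)/2`` with ``halved=True``) on raw 0/1 vectors.

    Zero-variance vectors leave r undefined; the defined fallback is
    d = 0 for two identical constant vectors and d = 1 otherwise, which
    keeps identical-row merges at height zero.  Tree topology is invariant
    to the monotone rescaling ``halved`` applies.
    """
    va = a.vector if isinstance(a, KnockoutProfile) else tuple(a)
    vb = b.vector if isinstance(b, KnockoutProfile) else tuple(b)
    if len(va) != len(vb) or len(va) < 2:
        raise ValidationError("profiles must share one length >= 2")
    xa = np.asarray(va, dtype=float)
    xb = np.asarray(vb, dtype=float)
    sa = xa.std()
    sb = xb.std()
    if sa == 0.0 or sb == 0.0:
        d = 0.0 if va == vb else 1.0
    else:
        r = float(np.corrcoef(xa, xb)[0, 1])
        d = 1.0 - r
    return d / 2.0 if halved else d


def distance_matrix(
    profiles: Sequence[KnockoutProfile], halved: bool = False
) -> np.ndarray:
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pearson_distance(profiles[i], profiles[j], halved)
    return D


@dataclass
class ClusterNode:
    """Rooted binary tree; leaves carry labels, internal nodes merge heights."""

    height: float = 0.0
    label: str | None = None
    children: tuple["ClusterNode", "ClusterNode"] | None = None
    annotation: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def internal_nodes(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return []
        return [self] + [n for c in self.children for n in c.internal_nodes()]

    def merge_heights(self) -> list[float]:
        return [n.height for n in self.internal_nodes()]

    def find_merge(self, labels: set[str]) -> "ClusterNode | None":
        """Smallest clade containing all the labels."""
        if not labels <= set(self.leaf_labels()):
            return None
        node = self
        while not node.is_leaf:
            nxt = None
            for c in node.children:
                if labels <= set(c.leaf_labels()):
                    nxt = c
                    break
            if nxt is None:
                return node
            node = nxt
        return node


def upgma(distances: np.ndarray, labels: Sequence[str]) -> ClusterNode:
    """Unweighted pair-group average clustering with d/2 merge heights.

    Iteratively merges the closest pair; the distance of the merged cluster
    to any other is the cluster-size-weighted arithmetic mean.  Ties break
    on the lexicographically smallest (min label, max label) pair so runs
    are deterministic across platforms.
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValidationError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix must be symmetric, zero diagonal")
    if n == 0:
        raise ValidationError("no profiles to cluster")

    clusters: dict[int, ClusterNode] = {
        i: ClusterNode(0.0, labels[i]) for i in range(n)
    }
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    # representative label for deterministic tie-breaking
    rep: dict[int, str] = {i: labels[i] for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for pair, d in dist.items():
            i, j = sorted(pair)
            tiekey = tuple(sorted((rep[i], rep[j])))
            cand = (d, tiekey, i, j)
            if best is None or cand < best:
                best = cand
        d, _, i, j = best
        node = ClusterNode(d / 2.0, None, (clusters[i], clusters[j]))
        clusters[next_id] = node
        sizes[next_id] = sizes[i] + sizes[j]
        rep[next_id] = min(rep[i], rep[j])
        active -= {i, j}
        for k in active:
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        del dist[frozenset((i, j))]
        active.add(next_id)
        next_id += 1
    return clusters[next_id - 1]


def tree_labels(tree: ClusterNode, annotation: Mapping[str, str]) -> ClusterNode:
    """Propagate leaf annotations: an internal node inherits a label when
    every descendant leaf shares it; mixed clades stay unlabeled."""
    for leaf in tree.leaves():
        if leaf.label in annotation:
            leaf.annotation = annotation[leaf.label]

    def visit(node: ClusterNode) -> set[str | None]:
        if node.is_leaf:
            return {node.annotation}
        seen = set()
        for c in node.children:
            seen |= visit(c)
        if len(seen) == 1 and None not in seen:
            node.annotation = next(iter(seen))
        return seen

    visit(tree)
    return tree


def _escape(label: str) -> str:
    if any(ch in label for ch in " :;,()'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: ClusterNode) -> str:
    """Newick with branch lengths equal to height differences."""

    def fmt(node: ClusterNode, parent_height: float) -> str:
        blen = parent_height - node.height
        if node.is_leaf:
            return f"{_escape(node.label)}:{blen:.6g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        tag = _escape(node.annotation) if node.annotation else ""
        return f"({inner}){tag}:{blen:.6g}"

    if tree.is_leaf:
        return f"{_escape(tree.label)};"
    inner = ",".join(fmt(c, tree.height) for c in tree.children)
    tag = _escape(tree.annotation) if tree.annotation else ""
    return f"({inner}){tag};"


def distance_matrix_to_tsv(
    D: np.ndarray, labels: Sequence[str], path
) -> None:
    """Square distance matrix with a header row/column of labels."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for i, lbl in enumerate(labels):
            fh.write(lbl + "\t" + "\t".join(f"{v:.6g}" for v in D[i]) + "\n")
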