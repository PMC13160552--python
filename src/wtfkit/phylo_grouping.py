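"""Distance-based trees and tree-shape statistics for family grouping.

Neighbor joining over p / JC69 / K2P distances stands in for likelihood
tree inference at desk scale: downstream stages only consume the grouping
structure.  Group assignment takes user-supplied anchor genes and labels
every leaf inside an anchor clade; ladder-likeness is quantified by the
normalized Colless imbalance (1 = caterpillar, 0 = fully balanced).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .recombination import AlignmentMatrix

JC_SATURATION_CAP = 5.0

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclasses.dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    model: str
    saturated: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


def distance_matrix(aln: AlignmentMatrix, model: str = "p-distance"
                    ) -> DistanceMatrix:
    """Pairwise-deletion distances under p-distance, JC69 or K2P.

    JC69: d = -(3/4) ln(1 - (4/3) p); saturated pairs (p >= 0.75) are capped
    at JC_SATURATION_CAP and flagged.  K2P uses transition (P) and
    transversion (Q) fractions: d = -(1/2) ln((1-2P-Q) sqrt(1-2Q)).
    """
    if model not in ("p-distance", "JC69", "K2P"):
        raise ValueError(f"unknown distance model {model!r}")
    n = aln.n_taxa
    mat = np.zeros((n, n))
    saturated = []
    chars = aln.matrix
    valid = np.isin(chars, list("ACGT"))
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            sites = int(mask.sum())
            if sites == 0:
                mat[i, j] = mat[j, i] = 0.0
                continue
            a, b = chars[i][mask], chars[j][mask]
            diff = a != b
            p = float(diff.mean())
            if model == "p-distance":
                d = p
            elif model == "JC69":
                if p >= 0.75:
                    d = JC_SATURATION_CAP
                    saturated.append((aln.taxa[i], aln.taxa[j]))
                else:
                    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            else:  # K2P
                ts = np.array([
                    (x in _PURINES) == (y in _PURINES)
                    for x, y in zip(a[diff], b[diff])])
                P = float(ts.sum()) / sites
                Q = p - P
                arg1, arg2 = 1.0 - 2 * P - Q, 1.0 - 2 * Q
                if arg1 <= 0 or arg2 <= 0:
                    d = JC_SATURATION_CAP
                    saturated.append((aln.taxa[i], aln.taxa[j]))
                else:
                    d = -0.5 * math.log(arg1 * math.sqrt(arg2))
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(aln.taxa), mat, model, saturated)


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Canonical NJ with Q-matrix joins.

    Ties in Q are broken by the lexicographically smallest taxon-label pair;
    negative branch-length estimates are clamped to 0 (annotated on the
    edge).  Returns an unrooted dendropy tree.
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = list(d.taxa)
    # smallest label reachable in each subtree, for deterministic tie-breaks
    rep = list(labels)
    sub = [_quote(t) for t in labels]
    mat = d.matrix.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        return x if x > 0.0 else 0.0  # negative NJ estimates clamped

    def join(i: int, j: int, li: float, lj: float) -> str:
        pi = f"{sub[i]}:{clamp(li):.10g}"
        pj = f"{sub[j]}:{clamp(lj):.10g}"
        return f"({pi},{pj})"

    while len(active) > 3:
        r = len(active)
        rows = mat[np.ix_(active, active)]
        totals = rows.sum(axis=1)
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                q = (r - 2) * rows[ai, aj] - totals[ai] - totals[aj]
                key = (q, *sorted((rep[active[ai]], rep[active[aj]])))
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = mat[i, j]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2.0 * (r - 2))
        lj = dij - li
        new_sub = join(i, j, li, lj)
        # reuse slot i for the merged node
        for ak in range(r):
            k = active[ak]
            if k in (i, j):
                continue
            mat[i, k] = mat[k, i] = 0.5 * (mat[i, k] + mat[j, k] - dij)
        sub[i] = new_sub
        rep[i] = min(rep[i], rep[j])
        active.remove(j)
    i, j, k = active
    li = 0.5 * (mat[i, j] + mat[i, k] - mat[j, k])
    lj = 0.5 * (mat[i, j] + mat[j, k] - mat[i, k])
    lk = 0.5 * (mat[i, k] + mat[j, k] - mat[i, j])
    def clamp2(x: float) -> float:
        return x if x > 0.0 else 0.0

    newick = (f"({sub[i]}:{clamp2(li):.10g},{sub[j]}:{clamp2(lj):.10g},"
              f"{sub[k]}:{clamp2(lk):.10g});")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _rooted(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    if not t.is_rooted:
        t.reroot_at_midpoint(update_bipartitions=True)
        t.is_rooted = True
    return t


def assign_groups(tree: dendropy.Tree,
                  anchors: Mapping[str, Sequence[str]]) -> dict[str, str | None]:
    """Assign every leaf to the group whose anchor clade contains it.

    Each group's clade is the smallest clade containing all its anchors
    (MRCA on the midpoint-rooted tree).  Leaves in several anchor clades go
    to the smallest enclosing clade (warning emitted); leaves outside all
    anchor clades map to None.  Raises KeyError for anchors absent from the
    tree.
    """
    t = _rooted(tree)
    leaf_names = {lf.taxon.label for lf in t.leaf_node_iter()}
    clades: dict[str, set[str]] = {}
    for group, anchor_ids in anchors.items():
        missing = [a for a in anchor_ids if a not in leaf_names]
        if missing:
            raise KeyError(f"anchor gene(s) {missing} not in tree (group {group})")
        mrca = t.mrca(taxon_labels=list(anchor_ids))
        clades[group] = {lf.taxon.label for lf in mrca.leaf_iter()}
    assignment: dict[str, str | None] = {}
    for leaf in sorted(leaf_names):
        holding = [(len(m), g) for g, m in clades.items() if leaf in m]
        if not holding:
            assignment[leaf] = None
        else:
            if len(holding) > 1:
                warnings.warn(
                    f"leaf {leaf} inside nested anchor clades; "
                    "smallest enclosing clade wins")
            assignment[leaf] = min(holding)[1]
    return assignment


def ladder_index(tree: dendropy.Tree) -> float:
    """Normalized Colless imbalance of the (midpoint-rooted) tree.

    Colless = sum over internal binary nodes of |n_left - n_right|,
    divided by the caterpillar maximum (n-1)(n-2)/2.  Defined as 0 for
    fewer than 3 leaves.
    """
    t = _rooted(tree)
    n = len(t.leaf_nodes())
    if n < 3:
        return 0.0
    colless = 0
    for node in t.postorder_node_iter():
        if node.is_leaf():
            node._nleaves = 1
            continue
        kids = node.child_nodes()
        node._nleaves = sum(k._nleaves for k in kids)
        if len(kids) == 2:
            colless += abs(kids[0]._nleaves - kids[1]._nleaves)
        elif len(kids) > 2:
            # polytomies scored over the two largest subtrees
            sizes = sorted((k._nleaves for k in kids), reverse=True)
            colless += abs(sizes[0] - sizes[1])
    return colless / ((n - 1) * (n - 2) / 2.0)
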