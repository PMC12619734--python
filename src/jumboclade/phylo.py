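"""Distance-based marker-gene trees and clade (monophyly) tests.

Distances are p-distances (1 - fractional identity) from pairwise local
alignments; trees are built with standard Saitou-Nei neighbor joining,
which is exact on additive matrices. This is a deliberately lightweight
stand-in for MSA + maximum-likelihood inference: the clade-membership
questions it answers (is a set of taxa monophyletic?) survive the
substitution, branch-support values do not and are not offered.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from . import homology

logger = logging.getLogger(__name__)


def marker_distance_matrix(members: Mapping[str, str]) -> DistanceMatrix:
    """All-pairs p-distance matrix from one marker protein per taxon.

    p-distance = 1 - pct_identity/100 from the optimal local alignment;
    pairs with no positive-scoring alignment get distance 1.
    """
    taxa = sorted(members)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxa")
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = homology.align_local(members[taxa[i]], members[taxa[j]])
            d = 1.0 - aln.pct_identity / 100.0 if aln is not None else 1.0
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=taxa)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Deterministic: ties in the Q matrix break by the lexicographically
    smallest taxon-name pair. Negative branch lengths are clamped to zero
    and the clamped deficit is logged. Exact on additive matrices.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=t) for t in ids]
    names: list[str] = list(ids)  # lexicographic tie-break keys
    deficit = 0.0

    def _clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        totals = d.sum(axis=1)
        q = (n - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = [(tuple(sorted((names[i], names[j]))), i, j)
                for i, j in zip(*np.nonzero(np.isclose(q, qmin)))
                if i < j]
        _, i, j = min(cand)
        li = _clamp(0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (n - 2)))
        lj = _clamp(d[i, j] - (0.5 * d[i, j] + (totals[i] - totals[j])
                               / (2 * (n - 2))))
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_next = np.empty((len(keep) + 1, len(keep) + 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d_next[-1, -1] = 0.0
        d = d_next
        new_name = min(names[i], names[j])
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [new_name]

    # final three nodes join at an unrooted trifurcation
    (a, b, c) = (0, 1, 2)
    la = _clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = _clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = _clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
    root = TreeNode(children=list(nodes))
    if deficit > 0:
        logger.info("neighbor joining clamped negative branch lengths "
                    "totalling %.6g", deficit)
    return root


def is_monophyletic(tree: TreeNode, taxa: set[str] | Sequence[str]) -> bool:
    """Bipartition test on an unrooted tree.

    True iff some edge splits exactly `taxa` from the remaining leaves.
    Trivial splits (a single taxon, or all taxa) are monophyletic.
    """
    taxa = frozenset(taxa)
    leaves = frozenset(t.name for t in tree.tips())
    unknown = taxa - leaves
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)!r}")
    if not taxa:
        raise ValueError("empty taxon set")
    if len(taxa) in (1, len(leaves)):
        return True
    complement = leaves - taxa
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if below == taxa or below == complement:
            return True
    return False
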