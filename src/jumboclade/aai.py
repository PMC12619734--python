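"""Whole-genome relatedness by average amino acid identity (AAI).

AAI between two genomes is the unweighted mean percent identity over the
reciprocal best hits (RBH) between their proteomes, after score, coverage
and identity filters. A pair with fewer than `min_pairs` RBHs is flagged
`insufficient` rather than reported, which keeps one-gene artifacts out of
the matrix. The accompanying dendrogram is average-linkage (UPGMA)
clustering on distance 100 - AAI: a presentation ordering for the heatmap,
not a phylogeny.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from . import homology
from .records import GeneRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_PAIRS = 10


@dataclass(frozen=True)
class AAIPairResult:
    genome_a: str
    genome_b: str
    aai: float | None
    n_rbh: int
    status: str  # "ok" | "insufficient"


@dataclass
class AAIMatrix:
    genome_ids: list[str]
    values: np.ndarray  # percent, NaN where insufficient
    n_rbh: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.n_rbh = np.asarray(self.n_rbh, dtype=int)

    def get(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return self.values[i, j]


def _proteome(genes: Sequence[GeneRecord]) -> dict[str, str]:
    return {g.gene_id: g.protein for g in genes}


def _result_from_rbh(rbh, genome_a, genome_b, min_pairs) -> AAIPairResult:
    if len(rbh) < min_pairs:
        return AAIPairResult(genome_a, genome_b, None, len(rbh), "insufficient")
    aai = float(np.mean([aln.pct_identity for _, _, aln in rbh]))
    return AAIPairResult(genome_a, genome_b, aai, len(rbh), "ok")


def compute_aai_pair(
    a: Sequence[GeneRecord] | Mapping[str, str],
    b: Sequence[GeneRecord] | Mapping[str, str],
    genome_a: str = "a",
    genome_b: str = "b",
    min_score: float = homology.DEFAULT_MIN_SCORE,
    min_cov: float = homology.DEFAULT_MIN_COV,
    min_id: float = homology.DEFAULT_MIN_ID,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    prefilter_k: int = homology.DEFAULT_PREFILTER_K,
) -> AAIPairResult:
    """AAI between two proteomes: mean RBH percent identity."""
    pa = a if isinstance(a, Mapping) else _proteome(a)
    pb = b if isinstance(b, Mapping) else _proteome(b)
    if not pa or not pb:
        raise ValueError("both proteomes must be non-empty")
    rbh = homology.reciprocal_best_hits(
        pa, pb, min_score=min_score, min_cov=min_cov, min_id=min_id,
        prefilter_k=prefilter_k)
    return _result_from_rbh(rbh, genome_a, genome_b, min_pairs)


def compute_aai_matrix(
    proteomes: Mapping[str, Sequence[GeneRecord]] | Mapping[str, Mapping[str, str]],
    min_pairs: int = DEFAULT_MIN_PAIRS,
    keep_pairs: bool = False,
    **kwargs,
) -> AAIMatrix | tuple[AAIMatrix, dict]:
    """All-pairs AAI over a set of genomes (each unordered pair once).

    With keep_pairs=True also returns {(genome_a, genome_b): rbh list} so
    downstream stages (orthogroup inference) can reuse the same search.
    """
    ids = sorted(proteomes)
    if len(ids) < 2:
        raise ValueError("AAI matrix needs at least 2 genomes")
    prots = {
        g: (p if isinstance(p, Mapping) else _proteome(p))
        for g, p in proteomes.items()
    }
    n = len(ids)
    values = np.full((n, n), np.nan)
    n_rbh = np.zeros((n, n), dtype=int)
    np.fill_diagonal(values, 100.0)
    pairs: dict[tuple[str, str], list] = {}
    for i, j in itertools.combinations(range(n), 2):
        rbh = homology.reciprocal_best_hits(prots[ids[i]], prots[ids[j]],
                                            **kwargs)
        if keep_pairs:
            pairs[(ids[i], ids[j])] = rbh
        res = _result_from_rbh(rbh, ids[i], ids[j], min_pairs)
        if res.status == "ok":
            values[i, j] = values[j, i] = res.aai
        n_rbh[i, j] = n_rbh[j, i] = res.n_rbh
    mat = AAIMatrix(ids, values, n_rbh)
    return (mat, pairs) if keep_pairs else mat


def aai_dendrogram(matrix: AAIMatrix) -> TreeNode:
    """Average-linkage (UPGMA) dendrogram on distance 100 - AAI.

    Genomes involved in any `insufficient` pair are excluded with a
    warning; a single remaining genome yields a single-leaf tree.
    """
    ids = list(matrix.genome_ids)
    vals = matrix.values.copy()
    # drop genomes with undefined pairs, worst offenders first
    while True:
        nan_counts = np.isnan(vals).sum(axis=1)
        if nan_counts.max(initial=0) == 0:
            break
        drop = int(np.argmax(nan_counts))
        logger.warning(
            "excluding genome %s from dendrogram: %d undefined AAI pairs",
            ids[drop], int(nan_counts[drop]))
        ids.pop(drop)
        vals = np.delete(np.delete(vals, drop, axis=0), drop, axis=1)
    if not ids:
        raise ValueError("no genomes left with defined AAI values")
    if len(ids) == 1:
        return TreeNode(name=ids[0])
    dist = 100.0 - vals
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.average(squareform(dist, checks=False))
    return _linkage_to_tree(linkage, ids)


def _linkage_to_tree(linkage: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Convert a scipy linkage matrix to an ultrametric TreeNode."""
    n = len(ids)
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=ids[i]), 0.0) for i in range(n)
    }
    for k, (left, right, height, _) in enumerate(linkage):
        lnode, lh = nodes.pop(int(left))
        rnode, rh = nodes.pop(int(right))
        h = float(height) / 2.0  # UPGMA node height = half the merge distance
        lnode.length = h - lh
        rnode.length = h - rh
        nodes[n + k] = (TreeNode(children=[lnode, rnode]), h)
    (root, _), = nodes.values()
    return root
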