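"""Orthogroup inference, occurrence deduplication, core/pan-genome analysis.

Orthogroups are connected components of the cross-genome reciprocal-best-
hit graph, augmented with within-genome best hits above the same filters
(a documented simplification of full OrthoFinder-style clustering; the
report header states the substitution). Core-genome membership is decided
by *occurrence*: a gene family present several times in one genome still
counts once, and near-identical genomes (AAI >= dedup_aai) collapse into a
single occurrence unit before fractions are taken — e.g. 28 genomes with
one triplet of essentially identical sequences are counted out of 26.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import homology
from .aai import AAIMatrix
from .records import GeneRecord

logger = logging.getLogger(__name__)

DEFAULT_DEDUP_AAI = 99.0
DEFAULT_CORE_CUTOFF = 0.80
DEFAULT_N_PERM = 100


@dataclass(frozen=True)
class Orthogroup:
    og_id: str
    members: tuple[tuple[str, str], ...]  # (genome_id, gene_id)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OccurrenceMatrix:
    """Orthogroup x occurrence-unit presence (0/1) table."""

    table: pd.DataFrame  # index og_id, columns unit ids, values 0/1
    unit_map: dict[str, str]  # genome_id -> unit_id

    @property
    def n_units(self) -> int:
        return self.table.shape[1]


@dataclass
class PangenomeSummary:
    n_units: int
    core_strict: list[str]
    core_soft: list[str]
    pan: list[str]
    cutoff: float
    rarefaction: pd.DataFrame


def infer_orthogroups(
    proteomes: Mapping[str, Sequence[GeneRecord]],
    min_score: float = homology.DEFAULT_MIN_SCORE,
    min_cov: float = homology.DEFAULT_MIN_COV,
    min_id: float = homology.DEFAULT_MIN_ID,
    prefilter_k: int = homology.DEFAULT_PREFILTER_K,
    rbh_pairs: Mapping[tuple[str, str], list] | None = None,
) -> list[Orthogroup]:
    """Partition all proteins into orthogroups.

    Edges: cross-genome RBH pairs plus, within each genome, mutual best
    paralog pairs that score at least as high as either copy's best
    cross-genome ortholog (recent, post-divergence duplications). All edges
    pass the same score/coverage/identity filters. Components are ranked by
    descending member count (ties by smallest member id) and named
    OG0000000, OG0000001, ...
    """
    genome_ids = sorted(proteomes)
    if len(genome_ids) < 2:
        logger.warning("orthogroup inference on < 2 genomes: singletons only")
    graph = nx.Graph()
    gene_owner: dict[str, str] = {}
    seqs: dict[str, dict[str, str]] = {}
    for gid in genome_ids:
        seqs[gid] = {g.gene_id: g.protein for g in proteomes[gid]}
        for gene_id in seqs[gid]:
            if gene_id in gene_owner:
                raise ValueError(f"gene id {gene_id!r} occurs in two genomes")
            gene_owner[gene_id] = gid
            graph.add_node(gene_id)
    # cross-genome RBH edges; remember each gene's best ortholog score.
    # rbh_pairs, when given (e.g. from the AAI stage under the same
    # filters), substitutes for recomputing the all-vs-all search.
    best_cross: dict[str, float] = {}
    for ga, gb in itertools.combinations(genome_ids, 2):
        if rbh_pairs is not None:
            rbh = rbh_pairs.get((ga, gb), rbh_pairs.get((gb, ga), []))
        else:
            rbh = homology.reciprocal_best_hits(
                seqs[ga], seqs[gb], min_score=min_score, min_cov=min_cov,
                min_id=min_id, prefilter_k=prefilter_k)
        for a_id, b_id, aln in rbh:
            graph.add_edge(a_id, b_id)
            best_cross[a_id] = max(best_cross.get(a_id, 0.0), aln.score)
            best_cross[b_id] = max(best_cross.get(b_id, 0.0), aln.score)
    # within-genome paralog edges: a pair joins one orthogroup only when the
    # copies are at least as similar to each other as to their closest
    # cross-genome orthologs (post-divergence duplication); otherwise the
    # duplication predates the clade ancestor and the copies belong to
    # different orthogroups
    for gid in genome_ids:
        prot = seqs[gid]
        if len(prot) < 2:
            continue
        for a_id, b_id, score in _within_genome_best_hits(
                prot, min_score, min_cov, min_id, prefilter_k):
            if (score >= best_cross.get(a_id, 0.0)
                    and score >= best_cross.get(b_id, 0.0)):
                graph.add_edge(a_id, b_id)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    return [
        Orthogroup(
            og_id=f"OG{rank:07d}",
            members=tuple((gene_owner[g], g) for g in comp),
        )
        for rank, comp in enumerate(comps)
    ]


def _within_genome_best_hits(prot: Mapping[str, str], min_score, min_cov,
                             min_id, prefilter_k):
    """Mutual best-hit paralog pairs within one genome, filtered.

    Requiring reciprocity mirrors the cross-genome edge rule and keeps
    one-sided chance hits (every gene has *some* best same-genome match)
    from bridging unrelated families. Scores are symmetric, so only the
    upper triangle is aligned.
    """
    ids = sorted(prot)
    seqs = [prot[i] for i in ids]
    n = len(ids)
    smat = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        smat[i, i + 1:] = homology.sw_scores(seqs[i], seqs[i + 1:])
    smat = np.maximum(smat, smat.T)
    np.fill_diagonal(smat, -1)
    best = smat.max(axis=1)
    out = []
    for i in range(n):
        if best[i] < min_score:
            continue
        j = int(np.flatnonzero(smat[i] == best[i])[0])  # smallest id on ties
        if j < i or smat[j].max() != smat[i, j]:
            continue  # keep mutual pairs once (i < j)
        aln = homology.align_local(seqs[i], seqs[j])
        if aln is None:
            continue
        if (aln.pct_identity >= min_id and aln.q_cov >= min_cov
                and aln.s_cov >= min_cov):
            out.append((ids[i], ids[j], float(aln.score)))
    return out


def dedup_occurrence_units(
    genome_ids: Sequence[str],
    aai: AAIMatrix,
    dedup_aai: float = DEFAULT_DEDUP_AAI,
) -> dict[str, str]:
    """Collapse near-identical genomes into occurrence units.

    Units are connected components of the graph linking genome pairs with
    AAI >= dedup_aai; a unit is named after its lexicographically smallest
    member. Genomes with undefined (insufficient) AAI to everything form
    their own units.
    """
    graph = nx.Graph()
    graph.add_nodes_from(genome_ids)
    idx = {g: i for i, g in enumerate(aai.genome_ids)}
    for ga, gb in itertools.combinations(genome_ids, 2):
        if ga not in idx or gb not in idx:
            raise ValueError(f"AAI matrix does not cover {ga!r}/{gb!r}")
        val = aai.values[idx[ga], idx[gb]]
        if np.isnan(val):
            logger.warning("AAI undefined for pair (%s, %s); not merged", ga, gb)
            continue
        if val >= dedup_aai:
            graph.add_edge(ga, gb)
    unit_map: dict[str, str] = {}
    for comp in nx.connected_components(graph):
        unit_id = min(comp)
        for g in comp:
            unit_map[g] = unit_id
    return unit_map


def occurrence_matrix(
    orthogroups: Sequence[Orthogroup],
    unit_map: Mapping[str, str],
) -> OccurrenceMatrix:
    """Presence (0/1) of each orthogroup in each occurrence unit.

    Presence is by occurrence, never by member count: multiple genes of
    one genome in the same orthogroup contribute a single 1.
    """
    units = sorted(set(unit_map.values()))
    ogs = [og.og_id for og in orthogroups]
    mat = pd.DataFrame(0, index=ogs, columns=units, dtype=int)
    for og in orthogroups:
        for genome_id in og.genomes:
            mat.loc[og.og_id, unit_map[genome_id]] = 1
    return OccurrenceMatrix(mat, dict(unit_map))


def core_genome(
    occ: OccurrenceMatrix,
    cutoff: float = DEFAULT_CORE_CUTOFF,
) -> tuple[list[str], list[str]]:
    """(soft core at >= cutoff fraction of units, strict core in all units)."""
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    frac = occ.table.sum(axis=1) / occ.n_units
    soft = sorted(occ.table.index[frac >= cutoff])
    strict = sorted(occ.table.index[occ.table.sum(axis=1) == occ.n_units])
    return soft, strict


def rarefaction(
    occ: OccurrenceMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Pan- and strict-core-size accumulation over random unit orderings.

    Returns one row per step (units added so far) with mean and sd of the
    cumulative pan size and cumulative strict-core size across n_perm
    permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pres = occ.table.to_numpy(dtype=bool)  # og x unit
    n_units = pres.shape[1]
    pan = np.zeros((n_perm, n_units), dtype=int)
    core = np.zeros((n_perm, n_units), dtype=int)
    for p in range(n_perm):
        order = rng.permutation(n_units)
        seen_any = np.zeros(pres.shape[0], dtype=bool)
        seen_all = np.ones(pres.shape[0], dtype=bool)
        for step, u in enumerate(order):
            seen_any |= pres[:, u]
            seen_all &= pres[:, u]
            pan[p, step] = int(seen_any.sum())
            core[p, step] = int(seen_all.sum())
    return pd.DataFrame({
        "n_units": np.arange(1, n_units + 1),
        "pan_mean": pan.mean(axis=0),
        "pan_sd": pan.std(axis=0, ddof=0),
        "core_mean": core.mean(axis=0),
        "core_sd": core.std(axis=0, ddof=0),
    })


def shared_og_counts(occ: OccurrenceMatrix) -> pd.DataFrame:
    """UpSet-style intersection sizes: orthogroups exactly in each unit set.

    Counts over all rows sum to the pan-genome size (the patterns
    partition the orthogroups). Sorted by descending count.
    """
    units = list(occ.table.columns)
    patterns: dict[tuple[str, ...], int] = {}
    arr = occ.table.to_numpy(dtype=bool)
    for row in arr:
        key = tuple(u for u, present in zip(units, row) if present)
        patterns[key] = patterns.get(key, 0) + 1
    rows = [
        {"units": ",".join(key), "n_units": len(key), "n_ogs": count}
        for key, count in patterns.items()
    ]
    df = pd.DataFrame(rows, columns=["units", "n_units", "n_ogs"])
    return df.sort_values(["n_ogs", "units"], ascending=[False, True],
                          ignore_index=True)


def summarize(
    occ: OccurrenceMatrix,
    cutoff: float = DEFAULT_CORE_CUTOFF,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> PangenomeSummary:
    soft, strict = core_genome(occ, cutoff)
    return PangenomeSummary(
        n_units=occ.n_units,
        core_strict=strict,
        core_soft=soft,
        pan=list(occ.table.index),
        cutoff=cutoff,
        rarefaction=rarefaction(occ, n_perm=n_perm, seed=seed),
    )


def write_og_membership_tsv(orthogroups: Sequence[Orthogroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("og_id\tgenome_id\tgene_id\n")
        for og in orthogroups:
            for genome_id, gene_id in og.members:
                fh.write(f"{og.og_id}\t{genome_id}\t{gene_id}\n")


def read_og_membership_tsv(path) -> list[Orthogroup]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for og_id, grp in df.groupby("og_id", sort=True):
        members = tuple(sorted(zip(grp["genome_id"], grp["gene_id"]),
                               key=lambda m: m[1]))
        out.append(Orthogroup(og_id=og_id, members=members))
    out.sort(key=lambda og: og.og_id)
    return out
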