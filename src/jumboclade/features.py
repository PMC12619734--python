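"""Genome-level screens: length gate, direct terminal repeats, synteny.

A direct terminal repeat (DTR) -- the same sequence at both ends of a
linear contig -- is the standard evidence that a phage contig is a
complete genome. Synteny links are each gene's best protein match in a
partner genome; links chained into runs monotone in both gene orders form
synteny blocks, with descending runs labelled as inversions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import GeneRecord, GenomeRecord, HitRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_BP = 200_000
DEFAULT_MIN_DTR_LEN = 21
DEFAULT_MAX_GAP_GENES = 3
DEFAULT_MIN_BLOCK_LINKS = 3


@dataclass(frozen=True)
class DTRResult:
    genome_id: str
    repeat_len: int
    repeat_seq: str
    complete: bool
    low_complexity_flag: bool


@dataclass(frozen=True)
class SyntenyLink:
    gene_a: str
    gene_b: str
    a_index: int
    b_index: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    pct_identity: float


@dataclass(frozen=True)
class SyntenyBlock:
    genome_a: str
    genome_b: str
    links: tuple[SyntenyLink, ...]
    orientation: str  # "forward" | "inverted"
    a_span: tuple[int, int]
    b_span: tuple[int, int]


def length_gate(genomes: Iterable[GenomeRecord],
                min_bp: int = DEFAULT_MIN_BP) -> list[GenomeRecord]:
    """Keep contigs strictly longer than min_bp; log every reject."""
    kept = []
    for g in genomes:
        if g.length_bp > min_bp:
            kept.append(g)
        else:
            logger.info("length gate: rejected %s (%d bp <= %d)",
                        g.genome_id, g.length_bp, min_bp)
    return kept


def detect_dtr(genome: GenomeRecord | str,
               min_dtr_len: int = DEFAULT_MIN_DTR_LEN,
               max_mismatch: int = 0) -> DTRResult:
    """Longest terminal repeat: largest L <= floor(n/2) with prefix ~ suffix.

    Exact when max_mismatch is 0; otherwise up to max_mismatch Hamming
    mismatches are tolerated. The repeat is flagged low-complexity when it
    is a single-nucleotide run, or has <= 2 distinct bases over >= 20 bp.
    """
    if isinstance(genome, GenomeRecord):
        gid, seq = genome.genome_id, genome.sequence
    else:
        gid, seq = "", genome
    n = len(seq)
    if n < 2 * min_dtr_len:
        logger.warning("genome %s too short (%d bp) for DTR search", gid, n)
        return DTRResult(gid, 0, "", False, False)
    repeat_len = 0
    if max_mismatch == 0:
        for length in range(n // 2, 0, -1):
            if seq[:length] == seq[-length:]:
                repeat_len = length
                break
    else:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for length in range(n // 2, 0, -1):
            if int((arr[:length] != arr[-length:]).sum()) <= max_mismatch:
                repeat_len = length
                break
    repeat_seq = seq[:repeat_len]
    distinct = len(set(repeat_seq)) if repeat_seq else 0
    low_complexity = bool(repeat_seq) and (
        distinct == 1 or (distinct <= 2 and repeat_len >= 20))
    return DTRResult(gid, repeat_len, repeat_seq,
                     complete=repeat_len >= min_dtr_len,
                     low_complexity_flag=low_complexity)


def synteny_links(genes_a: Sequence[GeneRecord],
                  genes_b: Sequence[GeneRecord],
                  hits: Sequence[HitRecord]) -> list[SyntenyLink]:
    """One link per gene of genome A with a best hit in genome B.

    genes_a / genes_b must be in genomic order; links carry gene-order
    indices and bp positions on both genomes.
    """
    a_index = {g.gene_id: i for i, g in enumerate(genes_a)}
    b_index = {g.gene_id: i for i, g in enumerate(genes_b)}
    a_by_id = {g.gene_id: g for g in genes_a}
    b_by_id = {g.gene_id: g for g in genes_b}
    links = []
    for h in hits:
        if h.query_id not in a_index or h.subject_id not in b_index:
            continue
        ga, gb = a_by_id[h.query_id], b_by_id[h.subject_id]
        links.append(SyntenyLink(
            gene_a=ga.gene_id, gene_b=gb.gene_id,
            a_index=a_index[ga.gene_id], b_index=b_index[gb.gene_id],
            a_start=ga.start, a_end=ga.end,
            b_start=gb.start, b_end=gb.end,
            pct_identity=h.alignment.pct_identity,
        ))
    links.sort(key=lambda l: l.a_index)
    return links


def chain_blocks(links: Sequence[SyntenyLink],
                 genome_a: str = "a", genome_b: str = "b",
                 max_gap_genes: int = DEFAULT_MAX_GAP_GENES,
                 min_block_links: int = DEFAULT_MIN_BLOCK_LINKS,
                 ) -> list[SyntenyBlock]:
    """Chain links into maximal monotone runs; descending-in-B runs are
    inverted blocks.

    A step between consecutive links (in genome-A order) is valid when it
    skips at most max_gap_genes genes on both genomes and moves strictly
    in genome B. Blocks are maximal runs of same-direction valid steps.
    Adjacent runs of opposite direction share one junction link; the
    inverted run claims it (the junction gene of an inversion belongs to
    the inverted segment), keeping blocks link-disjoint. Runs shorter than
    min_block_links are discarded.
    """
    ordered = sorted(links, key=lambda l: (l.a_index, l.b_index))
    if not ordered:
        return []

    def _step_sign(prev: SyntenyLink, nxt: SyntenyLink) -> int:
        a_gap = nxt.a_index - prev.a_index - 1
        b_step = nxt.b_index - prev.b_index
        if b_step == 0:
            return 0
        if a_gap <= max_gap_genes and abs(b_step) - 1 <= max_gap_genes:
            return 1 if b_step > 0 else -1
        return 0

    signs = [_step_sign(a, b) for a, b in zip(ordered, ordered[1:])]
    # maximal runs of equal non-zero step sign; run over steps k..j covers
    # links k..j+1
    runs: list[tuple[int, int, int]] = []
    k = 0
    while k < len(signs):
        s = signs[k]
        if s == 0:
            k += 1
            continue
        j = k
        while j + 1 < len(signs) and signs[j + 1] == s:
            j += 1
        runs.append((s, k, j + 1))
        k = j + 1

    claimed = [False] * len(ordered)
    raw: list[tuple[int, list[SyntenyLink]]] = []
    for sign, lo, hi in ([r for r in runs if r[0] < 0]
                         + [r for r in runs if r[0] > 0]):
        members = [i for i in range(lo, hi + 1) if not claimed[i]]
        for i in members:
            claimed[i] = True
        if len(members) >= min_block_links:
            raw.append((sign, [ordered[i] for i in members]))

    blocks = []
    for sign, chain in sorted(raw, key=lambda t: t[1][0].a_index):
        blocks.append(SyntenyBlock(
            genome_a=genome_a, genome_b=genome_b,
            links=tuple(chain),
            orientation="inverted" if sign < 0 else "forward",
            a_span=(min(l.a_start for l in chain), max(l.a_end for l in chain)),
            b_span=(min(l.b_start for l in chain), max(l.b_end for l in chain)),
        ))
    return blocks


def write_dtr_tsv(results: Sequence[DTRResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\trepeat_len\tcomplete\tlow_complexity\n")
        for r in results:
            fh.write(f"{r.genome_id}\t{r.repeat_len}\t{r.complete}\t"
                     f"{r.low_complexity_flag}\n")


def write_blocks_tsv(blocks: Sequence[SyntenyBlock], path) -> None:
    """Comparison-track shape: spans, identity, orientation per block."""
    with open(path, "w") as fh:
        fh.write("genome_a\tgenome_b\ta_start\ta_end\tb_start\tb_end\t"
                 "n_links\tmean_identity\torientation\n")
        for b in blocks:
            mean_id = float(np.mean([l.pct_identity for l in b.links]))
            fh.write(f"{b.genome_a}\t{b.genome_b}\t{b.a_span[0]}\t{b.a_span[1]}"
                     f"\t{b.b_span[0]}\t{b.b_span[1]}\t{len(b.links)}\t"
                     f"{mean_id:.2f}\t{b.orientation}\n")
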