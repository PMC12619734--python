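"""Readers and writers for every on-disk format the pipeline touches.

Formats: nucleotide / amino-acid FASTA, GFF3 (CDS rows only) or a 6-column
TSV gene table, labelled square matrices as TSV, Newick trees, and JSON
reports. Parsing is strict: records that violate an invariant raise, and
rejected inputs are never dropped silently.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from .records import GeneRecord, GenomeRecord

logger = logging.getLogger(__name__)

FASTA_WRAP = 80


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genomes(paths: Sequence[str | os.PathLike]) -> list[GenomeRecord]:
    """Read nucleotide FASTA files into validated GenomeRecords.

    Lowercase input is normalised to uppercase; the first whitespace-
    delimited header token becomes the genome_id (arbitrary tokens are
    accepted). Duplicate ids across all files raise.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for path in paths:
        n_before = len(records)
        try:
            parsed = list(SeqIO.parse(str(path), "fasta"))
        except ValueError as exc:
            raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
        for rec in parsed:
            gid = rec.id
            if gid in seen:
                raise ValueError(f"duplicate genome_id {gid!r} (file {path})")
            seen.add(gid)
            records.append(
                GenomeRecord(genome_id=gid, sequence=str(rec.seq).upper()).validate()
            )
        if len(records) == n_before:
            logger.warning("FASTA file %s contained no records", path)
    return records


def read_protein_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read an amino-acid FASTA into an id -> sequence mapping."""
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteins:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        proteins[rec.id] = str(rec.seq).upper().rstrip("*")
    return proteins


def _write_fasta(entries: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=FASTA_WRAP)
        writer.write_file(recs)


def write_genome_fasta(genomes: Iterable[GenomeRecord], path) -> None:
    _write_fasta(((g.genome_id, g.sequence) for g in genomes), path)


def write_protein_fasta(genes: Iterable[GeneRecord], path) -> None:
    _write_fasta(((g.gene_id, g.protein) for g in genes), path)


# ---------------------------------------------------------------------------
# Gene tables (GFF3 CDS subset, or 6-column TSV)
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _iter_gene_rows(path: str | os.PathLike):
    """Yield (genome_id, gene_id, start, end, strand) from GFF3 or TSV."""
    with open(path) as handle:
        lines = handle.read().splitlines()
    is_gff = any(line.startswith("##gff-version") for line in lines[:5])
    if not is_gff:
        first_data = next(
            (l for l in lines if l.strip() and not l.startswith("#")), None
        )
        if first_data is not None and len(first_data.split("\t")) == 9:
            is_gff = True
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if is_gff:
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != "CDS":
                continue
            attrs = _parse_gff3_attributes(fields[8])
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: CDS row lacks ID attribute")
            yield fields[0], attrs["ID"], int(fields[3]), int(fields[4]), fields[6]
        else:
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 TSV columns")
            yield fields[0], fields[1], int(fields[2]), int(fields[3]), fields[4]


def read_gene_table(
    path: str | os.PathLike,
    proteins: str | os.PathLike | Mapping[str, str],
    genome_lengths: Mapping[str, int] | None = None,
) -> list[GeneRecord]:
    """Join a gene-coordinate table to its protein FASTA.

    Accepts GFF3 (CDS features with an ID attribute) or the TSV dialect
    (genome_id, gene_id, start, end, strand, ...). Every row must join to
    exactly one protein sequence; coordinate and strand invariants are
    enforced, against genome lengths when provided.
    """
    if not isinstance(proteins, Mapping):
        proteins = read_protein_fasta(proteins)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for genome_id, gene_id, start, end, strand in _iter_gene_rows(path):
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        if gene_id not in proteins:
            raise ValueError(f"gene {gene_id!r} has no entry in the protein FASTA")
        glen = genome_lengths.get(genome_id) if genome_lengths else None
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                gene_id=gene_id,
                start=start,
                end=end,
                strand=strand,
                protein=proteins[gene_id],
            ).validate(genome_length=glen)
        )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path) -> None:
    """Write the 6-column TSV gene-table dialect."""
    with open(path, "w") as handle:
        for g in genes:
            handle.write(
                f"{g.genome_id}\t{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t.\n"
            )


def genes_by_genome(genes: Iterable[GeneRecord]) -> dict[str, list[GeneRecord]]:
    """Group genes per genome, preserving coordinate order."""
    out: dict[str, list[GeneRecord]] = {}
    for g in genes:
        out.setdefault(g.genome_id, []).append(g)
    for gid in out:
        out[gid].sort(key=lambda g: (g.start, g.end, g.gene_id))
    return out


# ---------------------------------------------------------------------------
# Matrices, trees, reports
# ---------------------------------------------------------------------------

def write_matrix_tsv(
    labels: Sequence[str], values, path, float_format: str = "%.2f"
) -> None:
    """Write a labelled square matrix as TSV (header row + label column)."""
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix must be square, got shape {values.shape}")
    if len(labels) != values.shape[0]:
        raise ValueError("label count does not match matrix dimension")
    if len(set(labels)) != len(labels):
        raise ValueError("matrix labels must be unique")
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format=float_format)


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return list(df.index), df.to_numpy(dtype=float)


def write_newick(tree, path) -> None:
    """Write a scikit-bio TreeNode as Newick."""
    tree.write(str(path), format="newick")


def read_newick(path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def write_report(summary: Mapping, path) -> None:
    """Write the machine-readable JSON report (round-trips via json)."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=_default)
        handle.write("\n")


def read_report(path) -> dict:
    with open(path) as handle:
        return json.load(handle)
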