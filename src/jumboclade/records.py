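"""Core record types shared across the pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention); any
arithmetic that needs 0-based half-open intervals converts explicitly at
the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUC_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GenomeRecord:
    """One phage contig: a single nucleotide sequence with provenance."""

    genome_id: str
    sequence: str
    environment: str = ""

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def validate(self) -> "GenomeRecord":
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.genome_id!r}: empty sequence")
        bad = set(self.sequence) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.genome_id!r}: non-ACGTN characters {sorted(bad)!r}"
            )
        return self


@dataclass(frozen=True)
class GeneRecord:
    """A called gene: genomic location plus its amino-acid product."""

    genome_id: str
    gene_id: str
    start: int  # 1-based
    end: int  # 1-based, inclusive
    strand: str  # '+' or '-'
    protein: str

    def validate(self, genome_length: int | None = None) -> "GeneRecord":
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}"
            )
        if genome_length is not None and self.end > genome_length:
            raise ValueError(
                f"gene {self.gene_id!r}: end {self.end} beyond genome "
                f"length {genome_length}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if len(self.protein) < 1:
            raise ValueError(f"gene {self.gene_id!r}: empty protein")
        bad = set(self.protein) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: non-standard residues {sorted(bad)!r}"
            )
        return self


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one local protein alignment.

    pct_identity uses aligned columns *including* gap columns as the
    denominator; q_cov / s_cov are the fractions of the query / subject
    sequence covered by the local alignment.
    """

    score: float
    pct_identity: float
    aln_len: int
    q_cov: float
    s_cov: float


@dataclass(frozen=True)
class HitRecord:
    """Best hit of one query against one subject set."""

    query_id: str
    subject_id: str
    alignment: AlignmentResult
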