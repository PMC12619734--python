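"""Synthetic phage-clade generator with full ground truth.

Emits a clade of genomes evolved from a common ancestor down a random
bifurcating tree: planted core and accessory gene families, host-derived
genes copied (with controlled divergence) from an emitted labelled
reference database, direct terminal repeats on a chosen fraction of
genomes, and planted gene-order inversions. Every emitted gene and genome
is covered by the truth tables, so each downstream stage of the pipeline
can be verified against a known answer.

The substitution model is deliberately simple: each site substitutes
independently with probability p_sub to a uniform choice among the 19
other residues. Two siblings evolved at p from one ancestor then share an
expected fractional identity of (1-p)^2 + p^2/19, which gives every
identity-based statistic a closed-form oracle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from skbio import TreeNode

from . import seqio
from .records import GeneRecord, GenomeRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {c: i for i, c in enumerate(AA)}
_CODON_TABLE = unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.forward_table.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_STOP_CODONS = sorted(_CODON_TABLE.stop_codons)
_REVCOMP = str.maketrans("ACGT", "TGCA")

ENVIRONMENTS = ["Freshwater", "Estuary", "Coastal salt marsh",
                "Marine water column", "Marine sediment"]
ENV_WEIGHTS = [0.7, 0.08, 0.07, 0.08, 0.07]

DECOY_PHYLA = ["Actinomycetota", "Bacillota", "Cyanobacteriota",
               "Verrucomicrobiota"]


@dataclass(frozen=True)
class HostImplant:
    phylum: str
    n_genes: int
    divergence: float  # per-site substitution probability vs the reference


@dataclass
class CladeSimConfig:
    """Study conditions for one simulated clade.

    Defaults give 12 genomes of roughly 100-150 kbp (fast to analyse);
    `paper_scale_config` returns a preset reaching jumbo-phage scale
    (200-307 kbp).
    """

    n_genomes: int = 12
    core_n: int = 120
    accessory_pool: int = 200
    accessory_rate: float = 0.25
    p_sub: float = 0.05
    gene_len_range: tuple[int, int] = (150, 350)  # aa
    intergenic_len_range: tuple[int, int] = (50, 200)  # bp
    n_inversions: int = 0
    inversion_len_range: tuple[int, int] = (3, 8)  # genes
    inversion_targets: tuple[int, ...] | None = None  # genome indices
    dtr_fraction: float = 0.25
    dtr_len: int = 500
    host_implants: tuple[HostImplant, ...] = (
        HostImplant("Bacteroidota", 30, 0.05),
        HostImplant("Pseudomonadota", 10, 0.05),
    )
    n_decoy_refs: int = 40
    occurrence_overrides: dict[str, tuple[int, ...]] = field(default_factory=dict)
    tree_newick: str | None = None
    seed: int = 0

    def validate(self) -> "CladeSimConfig":
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.core_n < 1:
            raise ValueError("core_n must be >= 1")
        for name in ("accessory_rate", "p_sub", "dtr_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for imp in self.host_implants:
            if not (0 <= imp.divergence <= 1):
                raise ValueError("implant divergence must be in [0, 1]")
        return self


def paper_scale_config(seed: int = 0, **overrides) -> CladeSimConfig:
    """Preset at jumbo-phage genome scale (roughly 200-307 kbp)."""
    kwargs = dict(n_genomes=28, core_n=160, accessory_pool=400,
                  accessory_rate=0.40, seed=seed)
    kwargs.update(overrides)
    return CladeSimConfig(**kwargs)


@dataclass
class TruthTables:
    tree_newick: str
    family_of_gene: dict[str, str]  # gene_id -> family
    occurrence: pd.DataFrame  # family x genome, 0/1
    host_phylum: dict[str, str]  # genome_id -> planted phylum
    dtr_len: dict[str, int]  # genome_id -> planted repeat length (0 = none)
    inversions: dict[str, list[tuple[int, int]]]  # gene-index intervals
    expected_length: dict[str, int]
    p_sub: float


@dataclass
class SimulatedClade:
    genomes: list[GenomeRecord]
    genes: dict[str, list[GeneRecord]]  # genomic order per genome
    reference: dict[str, str]
    taxonomy: dict[str, str]
    truth: TruthTables
    config: CladeSimConfig

    def proteomes(self) -> dict[str, list[GeneRecord]]:
        return self.genes


# ---------------------------------------------------------------------------
# Sequence-level primitives
# ---------------------------------------------------------------------------

def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def evolve_protein(ancestor: str, p_sub: float,
                   rng: np.random.Generator) -> str:
    """Substitute each site independently with probability p_sub, uniformly
    to one of the 19 other residues. Length is preserved."""
    if not (0 <= p_sub <= 1):
        raise ValueError("p_sub must be in [0, 1]")
    arr = np.array([_AA_IDX[c] for c in ancestor], dtype=np.int64)
    mask = rng.random(arr.size) < p_sub
    shift = rng.integers(1, 20, size=arr.size)
    arr = np.where(mask, (arr + shift) % 20, arr)
    return "".join(AA[i] for i in arr)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon per residue, plus a terminal stop codon."""
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS[aa]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(_STOP_CODONS[rng.integers(0, len(_STOP_CODONS))])
    return "".join(codons)


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def _random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def _random_tree(genome_ids: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Random bifurcating topology by sequential joins; unit branch lengths."""
    nodes = [TreeNode(name=g, length=1.0) for g in genome_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b], length=1.0))
    root = nodes[0]
    root.length = None
    return root


def _evolve_down_tree(tree: TreeNode, root_seq: str, p_sub: float,
                      rng: np.random.Generator) -> dict[str, str]:
    """One sequence per leaf, each branch applying p_sub once.

    Traversal order is deterministic (preorder over the constructed tree),
    so results are reproducible under a fixed seed.
    """
    out: dict[str, str] = {}
    stack = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in reversed(node.children):
            child_seq = evolve_protein(seq, p_sub, rng)
            if child.is_tip():
                out[child.name] = child_seq
            else:
                stack.append((child, child_seq))
    if tree.is_tip():  # single-genome degenerate case
        out[tree.name] = evolve_protein(root_seq, p_sub, rng)
    return out


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate_clade(config: CladeSimConfig,
                   out_dir: str | os.PathLike | None = None) -> SimulatedClade:
    """Generate one clade with truth tables; optionally write it to disk.

    Deterministic under a fixed seed: the same config produces
    byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genomes
    genome_ids = [f"sim{i:02d}" for i in range(n)]

    if config.tree_newick is not None:
        tree = TreeNode.read([config.tree_newick])
        tips = sorted(t.name for t in tree.tips())
        if tips != sorted(genome_ids):
            raise ValueError("tree leaves must be sim00..simNN")
    else:
        tree = _random_tree(genome_ids, rng)
    tree_newick = str(tree)

    # --- family catalogue: name -> presence per genome ------------------
    families: list[str] = []
    presence: dict[str, np.ndarray] = {}
    for i in range(config.core_n):
        fam = f"fam_core_{i:04d}"
        families.append(fam)
        presence[fam] = np.ones(n, dtype=bool)
    for i in range(config.accessory_pool):
        fam = f"fam_acc_{i:04d}"
        families.append(fam)
        presence[fam] = rng.random(n) < config.accessory_rate
    for fam, idxs in sorted(config.occurrence_overrides.items()):
        if fam in presence:
            raise ValueError(f"override clashes with family {fam!r}")
        families.append(fam)
        mask = np.zeros(n, dtype=bool)
        mask[list(idxs)] = True
        presence[fam] = mask
    implant_families: list[tuple[str, str, float]] = []  # (family, phylum, div)
    for imp in config.host_implants:
        for i in range(imp.n_genes):
            fam = f"fam_host_{imp.phylum}_{i:04d}"
            families.append(fam)
            presence[fam] = np.ones(n, dtype=bool)
            implant_families.append((fam, imp.phylum, imp.divergence))

    # ancestral gene order: one fixed shuffle of the catalogue
    order = list(rng.permutation(len(families)))
    ancestral_order = [families[k] for k in order]

    # --- evolve sequences ------------------------------------------------
    fam_len = {fam: int(rng.integers(config.gene_len_range[0],
                                     config.gene_len_range[1] + 1))
               for fam in families}
    implant_set = {fam for fam, _, _ in implant_families}
    leaf_seq: dict[str, dict[str, str]] = {}  # family -> genome -> protein
    for fam in families:
        if fam in implant_set:
            continue
        ancestor = random_protein(fam_len[fam], rng)
        leaf_seq[fam] = _evolve_down_tree(tree, ancestor, config.p_sub, rng)

    # --- labelled reference database -------------------------------------
    reference: dict[str, str] = {}
    taxonomy: dict[str, str] = {}
    for fam, phylum, divergence in implant_families:
        ref_id = f"ref_{fam}"
        reference[ref_id] = random_protein(fam_len[fam], rng)
        taxonomy[ref_id] = phylum
        leaf_seq[fam] = {
            g: evolve_protein(reference[ref_id], divergence, rng)
            for g in genome_ids
        }
    for i in range(config.n_decoy_refs):
        ref_id = f"ref_decoy_{i:04d}"
        reference[ref_id] = random_protein(
            int(rng.integers(config.gene_len_range[0],
                             config.gene_len_range[1] + 1)), rng)
        taxonomy[ref_id] = DECOY_PHYLA[i % len(DECOY_PHYLA)]

    # --- DTR / inversion assignment --------------------------------------
    n_dtr = int(round(config.dtr_fraction * n))
    dtr_genomes = set(rng.choice(n, size=n_dtr, replace=False).tolist())
    if config.inversion_targets is not None:
        inversion_genomes = set(config.inversion_targets)
    elif config.n_inversions > 0:
        inversion_genomes = set(range(1, n))
    else:
        inversion_genomes = set()

    # --- assemble genomes -------------------------------------------------
    genomes: list[GenomeRecord] = []
    genes: dict[str, list[GeneRecord]] = {}
    family_of_gene: dict[str, str] = {}
    truth_dtr: dict[str, int] = {}
    truth_inv: dict[str, list[tuple[int, int]]] = {}
    expected_length: dict[str, int] = {}
    environments = [ENVIRONMENTS[k] for k in rng.choice(
        len(ENVIRONMENTS), size=n, p=ENV_WEIGHTS)]

    for gi, gid in enumerate(genome_ids):
        fams = [f for f in ancestral_order if presence[f][gi]]
        items = [(f, leaf_seq[f][gid], "+-"[rng.integers(0, 2)]) for f in fams]
        # planted inversions: reverse a gene-order slice, flip strands
        intervals: list[tuple[int, int]] = []
        if gi in inversion_genomes and config.n_inversions > 0:
            intervals = _plant_inversions(
                len(items), config.n_inversions, config.inversion_len_range, rng)
            for lo, hi in intervals:
                seg = [(f, s, "+" if st == "-" else "-")
                       for f, s, st in items[lo:hi + 1]][::-1]
                items[lo:hi + 1] = seg
        truth_inv[gid] = intervals

        dtr_seq = _random_nt(config.dtr_len, rng) if gi in dtr_genomes else ""
        truth_dtr[gid] = len(dtr_seq)
        parts = [dtr_seq]
        pos = len(dtr_seq)
        glist: list[GeneRecord] = []
        for k, (fam, protein, strand) in enumerate(items):
            spacer = _random_nt(int(rng.integers(
                config.intergenic_len_range[0],
                config.intergenic_len_range[1] + 1)), rng)
            parts.append(spacer)
            pos += len(spacer)
            cds = reverse_translate(protein, rng)
            parts.append(cds if strand == "+" else _revcomp(cds))
            gene_id = f"{gid}_{k + 1:04d}"
            glist.append(GeneRecord(
                genome_id=gid, gene_id=gene_id,
                start=pos + 1, end=pos + len(cds), strand=strand,
                protein=protein))
            family_of_gene[gene_id] = fam
            pos += len(cds)
        tail = _random_nt(int(rng.integers(
            config.intergenic_len_range[0],
            config.intergenic_len_range[1] + 1)), rng)
        parts.append(tail)
        parts.append(dtr_seq)
        sequence = "".join(parts)
        if dtr_seq and len(sequence) < 2 * config.dtr_len:
            raise ValueError("config forces genome below 2 x dtr_len")
        expected_length[gid] = (2 * len(dtr_seq)
                                + sum(len(p) for p in parts[1:-1]))
        genomes.append(GenomeRecord(genome_id=gid, sequence=sequence,
                                    environment=environments[gi]).validate())
        genes[gid] = glist

    host_truth = _planted_hosts(config, genome_ids)
    occurrence = pd.DataFrame(
        {gid: [int(presence[f][gi]) for f in families]
         for gi, gid in enumerate(genome_ids)},
        index=families)

    truth = TruthTables(
        tree_newick=tree_newick,
        family_of_gene=family_of_gene,
        occurrence=occurrence,
        host_phylum=host_truth,
        dtr_len=truth_dtr,
        inversions=truth_inv,
        expected_length=expected_length,
        p_sub=config.p_sub,
    )
    clade = SimulatedClade(genomes=genomes, genes=genes, reference=reference,
                           taxonomy=taxonomy, truth=truth, config=config)
    if out_dir is not None:
        write_clade(clade, out_dir)
    return clade


def _plant_inversions(n_genes: int, count: int,
                      len_range: tuple[int, int],
                      rng: np.random.Generator) -> list[tuple[int, int]]:
    """Non-overlapping, non-adjacent gene-index intervals to invert."""
    intervals: list[tuple[int, int]] = []
    attempts = 0
    while len(intervals) < count and attempts < 1000:
        attempts += 1
        size = int(rng.integers(len_range[0], len_range[1] + 1))
        if size >= n_genes:
            continue
        lo = int(rng.integers(0, n_genes - size))
        hi = lo + size - 1
        # keep a 1-gene buffer so planted inversions stay distinguishable
        if all(hi < a - 1 or lo > b + 1 for a, b in intervals):
            intervals.append((lo, hi))
    if len(intervals) < count:
        raise ValueError("could not place the requested inversions")
    return sorted(intervals)


def _planted_hosts(config: CladeSimConfig,
                   genome_ids: Sequence[str]) -> dict[str, str]:
    if not config.host_implants:
        return {}
    best = sorted(config.host_implants, key=lambda i: (-i.n_genes, i.phylum))[0]
    return {g: best.phylum for g in genome_ids}


# ---------------------------------------------------------------------------
# On-disk output (exactly the formats seqio reads)
# ---------------------------------------------------------------------------

def write_clade(clade: SimulatedClade, out_dir: str | os.PathLike) -> None:
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    seqio.write_genome_fasta(clade.genomes, os.path.join(out, "genomes.fna"))
    all_genes = [g for gid in sorted(clade.genes) for g in clade.genes[gid]]
    seqio.write_protein_fasta(all_genes, os.path.join(out, "proteins.faa"))
    seqio.write_gene_table(all_genes, os.path.join(out, "genes.tsv"))
    seqio._write_fasta(sorted(clade.reference.items()),
                       os.path.join(out, "reference.faa"))
    with open(os.path.join(out, "taxonomy.tsv"), "w") as fh:
        for pid in sorted(clade.taxonomy):
            fh.write(f"{pid}\t{clade.taxonomy[pid]}\n")
    with open(os.path.join(out, "truth_tree.nwk"), "w") as fh:
        fh.write(clade.truth.tree_newick)
    with open(os.path.join(out, "truth_families.tsv"), "w") as fh:
        fh.write("gene_id\tfamily\n")
        for gene_id in sorted(clade.truth.family_of_gene):
            fh.write(f"{gene_id}\t{clade.truth.family_of_gene[gene_id]}\n")
    clade.truth.occurrence.to_csv(
        os.path.join(out, "truth_occurrence.tsv"), sep="\t")
    with open(os.path.join(out, "truth_genomes.tsv"), "w") as fh:
        fh.write("genome_id\tenvironment\thost_phylum\tdtr_len\tinversions\n")
        for g in clade.genomes:
            inv = ";".join(f"{lo}-{hi}"
                           for lo, hi in clade.truth.inversions[g.genome_id])
            fh.write(f"{g.genome_id}\t{g.environment}\t"
                     f"{clade.truth.host_phylum.get(g.genome_id, '.')}\t"
                     f"{clade.truth.dtr_len[g.genome_id]}\t{inv or '.'}\n")
    _write_config_echo(clade.config, os.path.join(out, "sim_config.txt"))


def _write_config_echo(config: CladeSimConfig, path) -> None:
    with open(path, "w") as fh:
        for key, value in sorted(asdict(config).items()):
            fh.write(f"{key} = {value!r}\n")
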