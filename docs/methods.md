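# Methods

This note documents the models, parameter choices, and numerical
conventions behind each stage of the pipeline, what the synthetic clade
generator does and does not emulate, and the known limitations.

## Homology search

All protein comparison is exact affine-gap Smith–Waterman under BLOSUM62.
A gap of length *k* costs `gap_open + k·gap_extend` with defaults 11/1
(the convention of protein database search tools). Hits are accepted on a
raw alignment score floor (`min_score`, default 50) plus identity and
coverage filters, rather than e-values: Karlin–Altschul statistics depend
on database size and composition, whereas a raw-score rule is
deterministic and portable across datasets. The trade-off is that the
floor has no probabilistic calibration; on ~250-residue random proteins,
chance local alignments reach the low 50s reasonably often but are short
(coverage well under 0.5) and low-identity, which is why downstream
consumers always combine the score floor with coverage/identity filters.

Percent identity is defined once and used everywhere: identical aligned
columns divided by all aligned columns *including* gap columns. Coverage
is the aligned span over the full sequence length, per side.

`best_hits` returns each query's single highest-scoring subject, with a
deterministic tie-break (higher percent identity, then lexicographically
smallest subject id). A shared-k-mer prefilter (k = 4) skips candidate
pairs sharing no length-4 word; it is disabled below 200 total proteins.
The prefilter is exact for any hit that contains four consecutive
identities — in practice every hit of biological interest — but a
marginal, gapped chance hit near the score floor can lack a shared 4-mer,
so prefiltered and exhaustive searches are only guaranteed to agree when
`min_score` is set above the chance-hit regime.

Reciprocal best hits (RBH) are mutual-best pairs under the same scoring.
Ties are resolved by a greedy one-to-one matching ordered by
(score, identity, id pair), which makes `rbh(A,B)` and `rbh(B,A)`
identical and bounds the pair count by `min(|A|, |B|)`.

The batch score search runs through a numba-compiled kernel (score-only,
rolling single-row DP with a query profile); tracebacks for reported hits
use scikit-bio's exact aligner. Both compute the same optimum; the test
suite asserts kernel/aligner agreement and checks both against an
independent pure-Python dynamic-programming oracle.

## AAI

AAI between two genomes is the unweighted mean percent identity over
their RBH pairs after filters (`min_cov` 0.5 per side, `min_id` 20). A
pair with fewer than `min_pairs` (default 10) RBHs is reported
`insufficient` rather than as a number, preventing one-gene artifacts.
The published AAI protocols differ in their exact search tool and
coverage cutoffs, so all filters are configuration, not constants; under
different choices reported AAI values can shift by a point or two.

Under the generator's substitution model, two siblings evolved from one
ancestor at per-site substitution probability *p* have expected fractional
identity `(1−p)² + p²/19`, which the test suite uses as a closed-form
oracle (at p = 0.2: ≈ 64.2 %). Measured AAI runs ~0.5–1 point above the
closed form because a local alignment clips a few low-scoring terminal
columns; this bias is well inside the 2-point test tolerance.

The dendrogram is average-linkage (UPGMA) clustering on `100 − AAI`. It
is a heatmap-ordering convention, not a phylogeny, and is labelled as
such. Genomes with any `insufficient` pair are dropped from the
dendrogram (worst offenders first) with a warning.

## Orthogroups and the pan-genome

Orthogroups are connected components of the cross-genome RBH graph. This
is a deliberate simplification of full graph-clustering orthology tools
(normalised scores + MCL); it is deterministic, desk-scale, and
sufficient for occurrence-based core-genome analysis, but absolute
orthogroup *counts* are not comparable across methods and are not treated
as reproduction targets. The report header states the substitution.

Within-genome paralog edges are added only for pairs that are (a) mutual
best hits inside their genome, (b) above the same score/coverage/identity
filters, and (c) at least as similar to each other as either copy is to
its best cross-genome ortholog. Condition (c) is the orthogroup
definition itself: a duplication *after* the clade ancestor leaves copies
more similar to each other than to orthologs, whereas copies from an
older duplication belong to different orthogroups. Without (c), chance
same-genome alignments near the score floor (every gene has *some* best
same-genome match) measurably bridge unrelated families on simulated
clades.

Occurrence counting: presence of an orthogroup in a genome is 0/1
regardless of member multiplicity, and near-identical genomes are
collapsed first. Deduplication is operationalised as connected components
of the graph linking genome pairs with AAI ≥ `dedup_aai` (default 99);
a unit is named after its lexicographically smallest member. Lowering the
threshold can only merge units, never split them.

Core membership uses ≥ at the cutoff (`count/units ≥ 0.80`), so an
orthogroup in 21 of 26 units (0.8077) is core while 20 of 26 (0.769) is
not. The strict core requires presence in all units. Rarefaction draws
`n_perm` (default 100) random unit orderings from the mandatory seed and
reports mean ± sd cumulative pan and strict-core sizes; within any single
ordering the pan size is non-decreasing and the core non-increasing by
construction. UpSet-style intersection counts group orthogroups by their
exact unit-presence pattern, so the counts partition the pan-genome.

## Host prediction

One vote per phage protein: the phylum of its single best reference hit
above `min_score`; proteins without hits abstain. The genome call divides
the top phylum's votes by the runner-up's and assigns the top phylum only
when the ratio strictly exceeds 1.5 ("exceeds" is read strictly). A
runner-up count of zero is an unopposed plurality: assigned, ratio
reported as infinite, and flagged. Equal top counts are a tie: flagged,
broken lexicographically for reporting, and necessarily ambiguous at any
threshold above 1. The score floor for counting a hit is configuration;
no attempt is made to exclude phage-derived reference proteins, so a
reference database contaminated with viral sequences will bias tallies.

## Genome-level screens

The length gate keeps contigs strictly longer than `min_bp`
(default 200 000 bp) and logs every reject.

DTR detection reports the largest `L ≤ floor(n/2)` with
`prefix(L) == suffix(L)` (exact; a Hamming-mismatch tolerance is
available). The completeness call requires `L ≥ min_dtr_len`
(default 21 bp, the convention of metagenomic completeness classifiers;
configuration-exposed since published thresholds vary). The `floor(n/2)`
cap avoids degenerate whole-genome "repeats"; repeats that are
single-nucleotide runs, or ≤ 2 distinct bases over ≥ 20 bp, carry a
low-complexity flag. Random sequence ends match by chance for a base or
two, so `repeat_len` is rarely 0 on real contigs — the completeness call,
not the raw length, is the decision output.

Synteny links are one per gene of genome A with a best hit in genome B,
carrying gene-order indices and bp spans. Chaining works on gene-index
gaps (not bp), which is robust to intergenic length variation: a step
between consecutive links is valid when it skips ≤ `max_gap_genes`
(default 3) genes on both sides and moves strictly in genome B. Blocks
are maximal same-direction runs of valid steps with ≥ `min_block_links`
(default 3) links; descending runs are inversions. Where an inverted run
meets a forward run they share one junction link; it is attributed to the
inverted run (the junction gene belongs to the inverted segment), which
keeps blocks link-disjoint and makes planted inversions of exactly 3
genes recoverable — with forward-first attribution the first inverted
gene would be absorbed into the flanking forward block.

## Marker trees

Distances are p-distances (`1 − identity/100`) from pairwise local
alignments; pairs with no positive-scoring alignment get distance 1. This
replaces multiple alignment + maximum likelihood deliberately: the
clade-membership question (is a taxon set monophyletic?) survives the
substitution, while branch lengths are not evolutionary distances and
bootstrap support is meaningless without alignment columns, so neither is
offered. Neighbor joining follows Saitou–Nei with two determinism rules:
Q-matrix ties break by the lexicographically smallest taxon-name pair,
and negative branch lengths are clamped to zero with the clamped deficit
logged. On additive matrices NJ is exact (tree path lengths reproduce the
input to numerical tolerance); this is asserted against hand-computed
path distances and cross-checked against scikit-bio's independent NJ.
Monophyly on the unrooted tree is a bipartition test: some edge must
split exactly the query taxa from the rest.

## Synthetic clade generator

The generator emulates the *shape* of a metagenome-derived jumbo-phage
clade: 10–30 single-contig genomes, planted core families present
everywhere, accessory families retained per genome at a fixed rate,
explicit occurrence overrides for families planted in a chosen subset of
genomes, host-implant genes copied at controlled divergence from an
emitted labelled reference database (plus unrelated decoy references),
DTRs on a chosen fraction of genomes, and per-genome gene-order
inversions with strand flips.

Protein evolution is i.i.d. per site: substitution with probability
`p_sub` per branch, uniform over the 19 alternative residues. This is
chosen *for* its analytic tractability (the closed-form sibling identity
above), not realism: there is no rate heterogeneity, no BLOSUM-biased
exchange, and no indels — so alignments of simulated homologs are
gap-free and identity oracles are exact. Nucleotide sequence is produced
by uniform synonymous reverse translation with a random stop codon;
intergenic spacers are uniform random sequence. There is no codon bias,
no recombination, no assembly noise, and no gene-calling error (the
generator emits the gene table it laid out). Consequently, passing
recovery tests demonstrates the pipeline's correctness on data matching
its assumptions; on real contigs, indels, compositional bias and
fragmented assemblies will degrade identity estimates and chaining in
ways the simulation does not measure.

Defaults: 12 genomes, 120 core families, a 200-family accessory pool at
retention 0.25, gene lengths 150–350 aa, spacers 50–200 bp, DTR 500 bp on
a quarter of genomes, host implants 30 Bacteroidota + 10 Pseudomonadota
genes at divergence 0.05 — genomes land near 100–150 kbp, small enough
for fast testing. The `paper_scale_config` preset (28 genomes, 160 core,
400-family pool at 0.40) reaches 200–307 kbp. All randomness flows from a
single mandatory seed; the same configuration yields byte-identical
output files.

## Problem sizes and numerical conventions

The test suite runs the orthogroup-recovery check on the default
12-genome clade (~2 500 genes, ~1.4 M candidate alignments; the single
heaviest check) and keeps every other check at or below a few seconds.
Floating-point conventions: AAI is reported to 2 decimals in TSV output;
NJ exactness is asserted at 1e-9; UPGMA heights are half the merge
distance so tip-to-tip dendrogram distances reproduce `100 − AAI` on
ultrametric inputs. Matrix TSVs carry labels on both axes and are
rejected if non-square or with duplicate labels. Degenerate inputs are
defined, not accidental: empty FASTA files parse to empty lists with a
warning, a sequence too short for the DTR search returns repeat length 0
with a warning, single-genome orthogroup inference yields singletons, and
an all-insufficient AAI matrix refuses to produce a dendrogram.

## Known limitations

- Raw-score thresholds are not calibrated probabilities; porting the
  pipeline to proteins much shorter or longer than the simulated range
  may warrant adjusting `min_score`.
- Orthogroup counts are method-relative (see above).
- The host-prediction reference database is user-supplied; taxonomy
  errors or viral contamination propagate directly into the tallies.
- Marker-tree branch lengths are p-distances, not substitutions per site;
  use them only for topology-level questions.
- Circular permutations and assembly-artifact terminal repeats are not
  distinguished from genuine DTRs.
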