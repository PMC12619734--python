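"""End-to-end clade characterisation: gate -> DTR -> AAI -> orthogroups ->
dedup -> core/pan -> host calls -> synteny -> marker tree, with one JSON
report tying every number to a per-stage TSV."""

from __future__ import annotations

import dataclasses
import itertools
import logging
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import aai as aai_mod
from . import features, homology, hostcall, pangenome, phylo, seqio
from .records import GeneRecord, GenomeRecord

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Every threshold the pipeline applies, echoed verbatim into the report."""

    min_bp: int = features.DEFAULT_MIN_BP
    min_dtr_len: int = features.DEFAULT_MIN_DTR_LEN
    min_score: float = homology.DEFAULT_MIN_SCORE
    min_cov: float = homology.DEFAULT_MIN_COV
    min_id: float = homology.DEFAULT_MIN_ID
    min_pairs: int = aai_mod.DEFAULT_MIN_PAIRS
    dedup_aai: float = pangenome.DEFAULT_DEDUP_AAI
    core_cutoff: float = pangenome.DEFAULT_CORE_CUTOFF
    ratio_threshold: float = hostcall.DEFAULT_RATIO_THRESHOLD
    max_gap_genes: int = features.DEFAULT_MAX_GAP_GENES
    min_block_links: int = features.DEFAULT_MIN_BLOCK_LINKS
    prefilter_k: int = homology.DEFAULT_PREFILTER_K
    n_perm: int = pangenome.DEFAULT_N_PERM
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat `key = value` document; unknown keys are errors."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, sep, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if not sep or not key:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key "
                                     f"{key!r}")
                kwargs[key] = (int(value) if fields[key] == "int"
                               else float(value))
        return cls(**kwargs)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_characterize(
    genomes: Sequence[GenomeRecord],
    genes: Sequence[GeneRecord],
    config: PipelineConfig | None = None,
    reference: Mapping[str, str] | None = None,
    taxonomy: Mapping[str, str] | None = None,
    markers: Mapping[str, str] | None = None,
    out_dir: str | os.PathLike = ".",
) -> dict:
    """Run the whole characterisation pipeline and write the report.

    `reference`/`taxonomy` enable host prediction; `markers` (taxon ->
    protein, one per genome) enables the marker NJ tree. Any stage failure
    aborts with the stage name and cause.
    """
    config = config or PipelineConfig()
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "note": ("orthogroups are connected components of the "
                 "reciprocal-best-hit graph, not OrthoFinder clusters"),
    }

    if len(genomes) < 2:
        raise PipelineError("input", ValueError("need at least 2 genomes"))

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage
                report["failed_stage"] = name
                seqio.write_report(report, os.path.join(out, "report.json"))
                raise PipelineError(name, exc) from exc
        return deco

    # -- length gate -------------------------------------------------------
    @_stage("length_gate")
    def passed():
        kept = features.length_gate(genomes, min_bp=config.min_bp)
        report["length_gate"] = {
            "n_input": len(genomes), "n_passed": len(kept),
            "rejected": sorted(g.genome_id for g in genomes if g not in kept),
        }
        return kept

    gated_ids = {g.genome_id for g in passed}
    by_genome = seqio.genes_by_genome(
        [g for g in genes if g.genome_id in gated_ids])
    missing = gated_ids - set(by_genome)
    if missing:
        raise PipelineError(
            "input", ValueError(f"no genes for genomes {sorted(missing)!r}"))
    if len(passed) < 2:
        raise PipelineError(
            "length_gate", ValueError("fewer than 2 genomes pass the gate"))

    # -- DTR completeness --------------------------------------------------
    @_stage("dtr")
    def dtr_results():
        res = [features.detect_dtr(g, min_dtr_len=config.min_dtr_len)
               for g in passed]
        features.write_dtr_tsv(res, os.path.join(out, "dtr.tsv"))
        report["dtr"] = {
            "n_complete": sum(r.complete for r in res),
            "complete": sorted(r.genome_id for r in res if r.complete),
        }
        return res

    # -- AAI ----------------------------------------------------------------
    @_stage("aai")
    def aai_result():
        mat, pairs = aai_mod.compute_aai_matrix(
            by_genome, min_score=config.min_score, min_cov=config.min_cov,
            min_id=config.min_id, min_pairs=config.min_pairs,
            prefilter_k=config.prefilter_k, keep_pairs=True)
        seqio.write_matrix_tsv(mat.genome_ids, mat.values,
                               os.path.join(out, "aai_matrix.tsv"))
        tree = aai_mod.aai_dendrogram(mat)
        seqio.write_newick(tree, os.path.join(out, "aai_dendrogram.nwk"))
        off_diag = mat.values[~np.eye(len(mat.genome_ids), dtype=bool)]
        defined = off_diag[~np.isnan(off_diag)]
        report["aai"] = {
            "n_genomes": len(mat.genome_ids),
            "min": float(defined.min()) if defined.size else None,
            "max": float(defined.max()) if defined.size else None,
            "n_insufficient_pairs": int(np.isnan(off_diag).sum() // 2),
        }
        return mat, pairs

    aai_matrix, rbh_pairs = aai_result

    # -- orthogroups, dedup, core/pan ---------------------------------------
    @_stage("orthogroups")
    def ogs():
        groups = pangenome.infer_orthogroups(
            by_genome, min_score=config.min_score, min_cov=config.min_cov,
            min_id=config.min_id, prefilter_k=config.prefilter_k,
            rbh_pairs=rbh_pairs)
        pangenome.write_og_membership_tsv(
            groups, os.path.join(out, "orthogroups.tsv"))
        report["orthogroups"] = {"n_ogs": len(groups)}
        return groups

    @_stage("pangenome")
    def pan_summary():
        unit_map = pangenome.dedup_occurrence_units(
            sorted(by_genome), aai_matrix, dedup_aai=config.dedup_aai)
        occ = pangenome.occurrence_matrix(ogs, unit_map)
        occ.table.to_csv(os.path.join(out, "occurrence_matrix.tsv"), sep="\t")
        summary = pangenome.summarize(
            occ, cutoff=config.core_cutoff, n_perm=config.n_perm,
            seed=config.seed)
        summary.rarefaction.to_csv(
            os.path.join(out, "rarefaction.tsv"), sep="\t", index=False)
        pangenome.shared_og_counts(occ).to_csv(
            os.path.join(out, "upset_intersections.tsv"), sep="\t",
            index=False)
        report["pangenome"] = {
            "n_units": summary.n_units,
            "n_core_strict": len(summary.core_strict),
            "n_core_soft": len(summary.core_soft),
            "core_cutoff": summary.cutoff,
            "n_pan": len(summary.pan),
            "unit_map": dict(sorted(unit_map.items())),
        }
        return summary

    # -- host prediction (optional) ------------------------------------------
    if reference is not None:
        if taxonomy is None:
            raise PipelineError(
                "host", ValueError("reference given without taxonomy table"))

        @_stage("host")
        def host_calls():
            calls = []
            for gid in sorted(by_genome):
                tallies = hostcall.tally_best_hit_taxa(
                    by_genome[gid], reference, taxonomy,
                    min_score=config.min_score,
                    prefilter_k=config.prefilter_k)
                calls.append(hostcall.predict_host(
                    tallies, genome_id=gid,
                    ratio_threshold=config.ratio_threshold))
            hostcall.write_host_calls_tsv(
                calls, os.path.join(out, "host_calls.tsv"))
            report["host"] = {
                c.genome_id: {"phylum": c.top_phylum, "decision": c.decision}
                for c in calls
            }
            return calls

    # -- pairwise synteny -----------------------------------------------------
    @_stage("synteny")
    def blocks():
        all_blocks = []
        for ga, gb in itertools.combinations(sorted(by_genome), 2):
            hits = homology.best_hits(
                {g.gene_id: g.protein for g in by_genome[ga]},
                {g.gene_id: g.protein for g in by_genome[gb]},
                min_score=config.min_score, prefilter_k=config.prefilter_k)
            links = features.synteny_links(by_genome[ga], by_genome[gb], hits)
            all_blocks.extend(features.chain_blocks(
                links, genome_a=ga, genome_b=gb,
                max_gap_genes=config.max_gap_genes,
                min_block_links=config.min_block_links))
        features.write_blocks_tsv(
            all_blocks, os.path.join(out, "synteny_blocks.tsv"))
        report["synteny"] = {
            "n_blocks": len(all_blocks),
            "n_inverted": sum(b.orientation == "inverted" for b in all_blocks),
        }
        return all_blocks

    # -- marker tree (optional) -----------------------------------------------
    if markers is not None:

        @_stage("tree")
        def marker_tree():
            dm = phylo.marker_distance_matrix(markers)
            tree = phylo.neighbor_joining(dm)
            seqio.write_newick(tree, os.path.join(out, "marker_tree.nwk"))
            report["tree"] = {"n_taxa": len(dm.ids)}
            return tree

    seqio.write_report(report, os.path.join(out, "report.json"))
    return report
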