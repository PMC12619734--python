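"""Homology-based host prediction.

Each phage protein casts one vote: the phylum of its single best hit in a
labelled reference protein database (no vote if it has no hit above the
score floor). The genome-level call divides the top phylum's votes by the
runner-up's; the host is assigned only when that ratio strictly exceeds
the threshold (default 1.5). An unopposed plurality (runner-up count 0)
is assigned with an infinite ratio and flagged.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import homology
from .records import GeneRecord

DEFAULT_RATIO_THRESHOLD = 1.5


@dataclass
class HostCall:
    genome_id: str
    tallies: dict[str, int]
    top_phylum: str | None
    second_phylum: str | None
    ratio: float  # inf when unopposed, nan when no hits
    decision: str  # "assigned" | "ambiguous" | "unassigned"
    tie: bool = False


def tally_best_hit_taxa(
    proteome: Sequence[GeneRecord] | Mapping[str, str],
    reference: Mapping[str, str],
    taxonomy: Mapping[str, str],
    min_score: float = homology.DEFAULT_MIN_SCORE,
    prefilter_k: int = homology.DEFAULT_PREFILTER_K,
) -> dict[str, int]:
    """Count best-hit phyla across a proteome, one vote per protein."""
    unlabelled = set(reference) - set(taxonomy)
    if unlabelled:
        raise ValueError(
            f"reference proteins without taxonomy label: {sorted(unlabelled)[:5]!r}")
    if not isinstance(proteome, Mapping):
        proteome = {g.gene_id: g.protein for g in proteome}
    hits = homology.best_hits(proteome, reference, min_score=min_score,
                              prefilter_k=prefilter_k)
    return dict(Counter(taxonomy[h.subject_id] for h in hits))


def predict_host(
    tallies: Mapping[str, int],
    genome_id: str = "",
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> HostCall:
    """Plurality/ratio decision on a phylum tally.

    Ranked by count (ties broken lexicographically and flagged). Decision
    is `assigned` iff ratio strictly exceeds the threshold, or the
    runner-up count is zero while the top count is positive.
    """
    ranked = sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))
    if not ranked or ranked[0][1] == 0:
        return HostCall(genome_id, dict(tallies), None, None,
                        float("nan"), "unassigned")
    top_phylum, top_count = ranked[0]
    if len(ranked) == 1 or ranked[1][1] == 0:
        return HostCall(genome_id, dict(tallies), top_phylum, None,
                        math.inf, "assigned")
    second_phylum, second_count = ranked[1]
    ratio = top_count / second_count
    decision = "assigned" if ratio > ratio_threshold else "ambiguous"
    return HostCall(genome_id, dict(tallies), top_phylum, second_phylum,
                    ratio, decision, tie=(top_count == second_count))


def read_taxonomy_tsv(path) -> dict[str, str]:
    """2-column TSV: protein_id <tab> phylum."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if fields[0] in out:
                raise ValueError(f"{path}:{lineno}: duplicate protein id "
                                 f"{fields[0]!r}")
            out[fields[0]] = fields[1]
    return out


def write_host_calls_tsv(calls: Sequence[HostCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\ttop_phylum\ttop_count\tsecond_phylum\t"
                 "second_count\tratio\tdecision\n")
        for c in calls:
            top_n = c.tallies.get(c.top_phylum, 0) if c.top_phylum else 0
            sec_n = c.tallies.get(c.second_phylum, 0) if c.second_phylum else 0
            ratio = ("inf" if math.isinf(c.ratio)
                     else "" if math.isnan(c.ratio) else f"{c.ratio:.3f}")
            fh.write(f"{c.genome_id}\t{c.top_phylum or '.'}\t{top_n}\t"
                     f"{c.second_phylum or '.'}\t{sec_n}\t{ratio}\t{c.decision}\n")
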