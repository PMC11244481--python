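"""QTN intersection across association models and gene windowing.

A locus becomes a QTN when a locus within the merge distance exists in
every model of at least one required set (conventionally: all single-locus
models, or all multi-locus models).  Candidate genes are every annotated
gene whose span overlaps a ±flank window around a QTN (overlap, not
containment; boundaries inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GeneModel
from .gwas_multi import Locus, merge_loci

log = logging.getLogger(__name__)


@dataclass
class QTN:
    chrom: str
    pos: int
    supporting_models: list[str]
    best_score: float


def intersect_models(
    per_model_loci: dict[str, list[Locus]],
    required_sets: list[set[str]],
    max_gap: int = 20_000,
) -> list[QTN]:
    """Loci supported (within ``max_gap``) by every model of a required set.

    The union over required sets is returned, deduplicated by the same
    <= max_gap single-linkage chaining used for locus merging; the result is
    independent of model-list and locus ordering.
    """
    known = set(per_model_loci)
    for s in required_sets:
        unknown = s - known
        if unknown:
            raise ValueError(f"unknown model tag(s) in required set: {sorted(unknown)}")

    qtns: list[QTN] = []
    for req in required_sets:
        tags = sorted(req)
        if not tags:
            continue
        base = per_model_loci[tags[0]]
        for locus in base:
            supported = all(
                any(
                    other.chrom == locus.chrom and abs(other.pos - locus.pos) <= max_gap
                    for other in per_model_loci[tag]
                )
                for tag in tags[1:]
            )
            if supported:
                qtns.append(QTN(chrom=locus.chrom, pos=locus.pos,
                                supporting_models=tags, best_score=locus.best_score))

    # deduplicate across required sets by chaining
    merged = merge_loci(qtns, max_gap=max_gap, score_attr="best_score")
    out: list[QTN] = []
    for loc in merged:
        support: list[str] = []
        for q in qtns:
            if q.chrom == loc.chrom and abs(q.pos - loc.pos) <= max_gap:
                support.extend(q.supporting_models)
        out.append(QTN(chrom=loc.chrom, pos=loc.pos,
                       supporting_models=sorted(set(support)), best_score=loc.best_score))
    out.sort(key=lambda q: (q.chrom, q.pos))
    return out


def genes_in_windows(
    qtns: list[QTN],
    gene_models: list[GeneModel],
    flank: int = 500_000,
) -> pd.DataFrame:
    """Genes overlapping [pos - flank, pos + flank] of any QTN.

    Returns a provenance table with one row per (gene, QTN) pair plus a
    deduplicated ``gene`` column usable as the candidate set; a QTN on a
    chromosome absent from the annotation is skipped with a warning.
    """
    chroms = {g.chrom for g in gene_models}
    rows = []
    for q in qtns:
        if q.chrom not in chroms:
            log.warning("QTN %s:%d on chromosome absent from annotation; skipped", q.chrom, q.pos)
            continue
        lo, hi = q.pos - flank, q.pos + flank
        for g in gene_models:
            if g.chrom == q.chrom and g.start <= hi and g.end >= lo:
                rows.append((g.id, g.chrom, g.start, g.end, f"{q.chrom}:{q.pos}"))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "qtn"])
    return df.sort_values(["gene", "qtn"]).drop_duplicates().reset_index(drop=True)


def candidate_gene_ids(window_table: pd.DataFrame) -> list[str]:
    """Deduplicated candidate gene ids from a genes_in_windows table."""
    return sorted(window_table["gene"].unique().tolist())
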