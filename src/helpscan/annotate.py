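"""Genomic annotation of candidate loci.

Covers three steps: boolean overlap flags against feature tracks (CpG
islands, CG clusters, conserved elements, repeats), strand-aware mapping
of loci to genes (promoter = 10 kb upstream of the TSS, gene body =
transcript span), and a right-tailed hypergeometric enrichment score
(-log10 p of a Fisher exact right tail).  The output report mirrors the
candidate-table layout: position in 1-based text, group means, the
case-minus-control difference, p scaled x10^-6 for display, feature
flags, locus category (PRO / PRO2 / GB), and gene identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .io_model import AnnotationTrack, GeneModel, GenomicInterval

__all__ = [
    "GeneAssignment",
    "overlap_flags",
    "map_to_genes",
    "enrichment_score",
    "build_candidate_report",
]

log = logging.getLogger(__name__)


@dataclass
class GeneAssignment:
    """Gene-mapping result for one locus.

    category: ``PRO`` (promoter), ``PRO2`` (bidirectional promoter:
    promoter of >= 2 genes on opposite strands), ``GB`` (gene body), or
    ``none``.  All matched genes are reported; GB takes precedence over
    PRO in the category when both occur.
    """

    locus: str
    category: str
    genes: list[str]
    transcripts: list[str]

    def __post_init__(self) -> None:
        if self.category not in ("PRO", "PRO2", "GB", "none"):
            raise ValueError(f"bad category {self.category!r}")
        if self.category == "none" and self.genes:
            raise ValueError("category 'none' implies an empty gene list")


def _build_trees(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap_flags(
    loci: dict[str, GenomicInterval],
    tracks: list[AnnotationTrack],
) -> pd.DataFrame:
    """Boolean overlap flag per (locus, track): >= 1 bp half-open intersection.

    Columns are track names.  Chromosomes present in the loci but absent
    from every track are allowed (flags stay False) and logged.
    """
    index = pd.Index(list(loci), name="locus")
    out = pd.DataFrame(index=index)
    track_chroms: set[str] = set()
    for track in tracks:
        trees = _build_trees(track.intervals)
        track_chroms |= set(trees)
        flags = []
        for key in index:
            iv = loci[key]
            tree = trees.get(iv.chrom)
            flags.append(bool(tree is not None and tree.overlap(iv.start, iv.end)))
        out[track.name] = flags
    if tracks:
        orphan = {loci[k].chrom for k in index} - track_chroms
        if orphan:
            log.info("chromosomes with no track intervals: %s", sorted(orphan))
    return out


def _promoter_window(gene: GeneModel, upstream_window: int) -> tuple[int, int]:
    """Strand-aware [TSS - w, TSS) window, half-open; mirrored on -.

    The TSS base itself belongs to the gene body, not the promoter.
    """
    if gene.strand == "+":
        return max(0, gene.tss - upstream_window), gene.tss
    # on '-' the upstream direction is increasing coordinates:
    # window covers (tss, tss + w] i.e. half-open [tss + 1, tss + 1 + w)
    return gene.tss + 1, gene.tss + 1 + upstream_window


def map_to_genes(
    loci: dict[str, GenomicInterval],
    genes: list[GeneModel],
    upstream_window: int = 10_000,
) -> dict[str, GeneAssignment]:
    """Assign each locus to promoters and gene bodies by position.

    A locus is PRO for a gene when it intersects the 10 kb strand-aware
    window upstream of the TSS, GB when it intersects the gene body (GB
    wins over PRO for the same gene).  Promoter hits on >= 2 genes lying
    on opposite strands make the locus a bidirectional promoter (PRO2).
    A locus matching nothing gets category ``none``.
    """
    if upstream_window <= 0:
        raise ValueError("upstream_window must be > 0")
    assignments: dict[str, GeneAssignment] = {}
    for key, iv in loci.items():
        hit_genes: list[GeneModel] = []
        roles: list[str] = []
        for g in genes:
            if g.body.chrom != iv.chrom:
                continue
            in_body = iv.start < g.body.end and g.body.start < iv.end
            ws, we = _promoter_window(g, upstream_window)
            in_prom = iv.start < we and ws < iv.end
            if in_body:
                hit_genes.append(g)
                roles.append("GB")
            elif in_prom:
                hit_genes.append(g)
                roles.append("PRO")
        if not hit_genes:
            assignments[key] = GeneAssignment(key, "none", [], [])
            continue
        if "GB" in roles:
            category = "GB"
        else:
            strands = {g.strand for g, r in zip(hit_genes, roles) if r == "PRO"}
            n_prom = sum(r == "PRO" for r in roles)
            category = "PRO2" if (n_prom >= 2 and strands == {"+", "-"}) else "PRO"
        assignments[key] = GeneAssignment(
            key, category, [g.symbol for g in hit_genes], [g.transcript for g in hit_genes]
        )
    return assignments


def enrichment_score(overlap: int, list_size: int, set_size: int, universe: int) -> float:
    """-log10 of the right-tailed Fisher exact (hypergeometric) probability.

    p = P(X >= overlap) where X ~ Hypergeometric(universe, list_size,
    set_size): the chance that a random size-``set_size`` draw from a
    universe containing ``list_size`` marked genes captures at least
    ``overlap`` of them.  Exact tail, no approximation.
    """
    if min(overlap, list_size, set_size, universe) < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(list_size, set_size):
        raise ValueError("overlap cannot exceed min(list_size, set_size)")
    if max(list_size, set_size) > universe:
        raise ValueError("list_size and set_size must not exceed universe")
    p = float(hypergeom.sf(overlap - 1, universe, list_size, set_size))
    p = min(p, 1.0)
    return -np.log10(max(p, np.finfo(float).tiny))


def build_candidate_report(
    candidates: pd.DataFrame,
    flags: pd.DataFrame,
    assignments: dict[str, GeneAssignment],
    loci: dict[str, GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Assemble the candidate-table report (one row per candidate locus).

    ``candidates`` is a LocusStats frame (index: locus key) already
    restricted to the chosen tier.  P-values are displayed scaled by 10^6.
    Rows sort ascending by p.  Every candidate must appear in ``flags``
    and ``assignments``.
    """
    rows = []
    for key, stat in candidates.iterrows():
        if key not in flags.index or key not in assignments:
            raise KeyError(f"unmatched locus ID in annotation inputs: {key!r}")
        iv = (loci or {}).get(key) or GenomicInterval.from_key(key)
        a = assignments[key]
        row = {
            "position": iv.to_key(),
            "mean_case": round(float(stat["mean_case"]), 2),
            "mean_control": round(float(stat["mean_control"]), 2),
            "difference": round(float(stat["mean_case"]) - float(stat["mean_control"]), 2),
            "p_x1e6": float(stat["p"]) * 1e6,
            "category": a.category if a.category != "none" else "",
            "genes": " ".join(a.genes),
            "transcripts": " ".join(a.transcripts),
            "p": float(stat["p"]),
        }
        for col in flags.columns:
            row[col] = "YES" if bool(flags.loc[key, col]) else "no"
        rows.append(row)
    report = pd.DataFrame(rows)
    if report.empty:
        return pd.DataFrame(
            columns=["position", "mean_case", "mean_control", "difference", "p_x1e6",
                     "category", "genes", "transcripts", "p", *flags.columns]
        )
    return report.sort_values("p", kind="stable").reset_index(drop=True)
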