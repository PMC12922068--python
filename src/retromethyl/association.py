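"""Locus-gene genomic association: intragenic overlap and flanking windows.

A retroelement locus is *intragenic* to a gene when their intervals share
at least one base (strand is recorded, never used for detection, since
antisense-embedded loci are biologically meaningful here). A gene is
*nearby* when it does not overlap but the number of bases strictly between
the two intervals is at most the window (50 kb by default). Host and
nearby link sets are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence

from intervaltree import IntervalTree

from .features import DEResult, GenomicFeature

__all__ = [
    "LocusGeneLink",
    "ChromosomeNamingError",
    "find_host_genes",
    "find_nearby_genes",
    "annotate_links",
]

DEFAULT_NEARBY_WINDOW = 50_000


class ChromosomeNamingError(ValueError):
    """Loci and genes use different chromosome naming styles."""


@dataclass(frozen=True)
class LocusGeneLink:
    locus_id: str
    gene_id: str
    relation: str  # "intragenic" | "nearby"
    distance_bp: int
    same_strand: bool
    locus_de: Optional[DEResult] = None
    gene_de: Optional[DEResult] = None


def _check_chrom_styles(loci: Sequence[GenomicFeature],
                        genes: Sequence[GenomicFeature]) -> None:
    lc = {f.chrom for f in loci}
    gc = {f.chrom for f in genes}
    if not lc or not gc:
        return
    lc_pref = {c.startswith("chr") for c in lc}
    gc_pref = {c.startswith("chr") for c in gc}
    if len(lc_pref) == 1 and len(gc_pref) == 1 and lc_pref != gc_pref and not (lc & gc):
        raise ChromosomeNamingError(
            "loci and genes use different chromosome naming styles "
            "('chr1' vs '1'); harmonize names before association"
        )


def _gene_trees(genes: Sequence[GenomicFeature]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    return trees


def find_host_genes(loci: Sequence[GenomicFeature],
                    genes: Sequence[GenomicFeature]) -> List[LocusGeneLink]:
    """Intragenic links: every (locus, gene) pair overlapping by >= 1 bp.

    A locus may link to several overlapping genes (e.g. a protein-coding
    gene on one strand and a lncRNA on the other). Output order follows
    locus input order, then gene id.
    """
    _check_chrom_styles(loci, genes)
    trees = _gene_trees(genes)
    links: List[LocusGeneLink] = []
    for locus in loci:
        tree = trees.get(locus.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(locus.start, locus.end + 1),
                      key=lambda iv: iv.data.feature_id)
        for iv in hits:
            gene = iv.data
            links.append(LocusGeneLink(
                locus_id=locus.feature_id,
                gene_id=gene.feature_id,
                relation="intragenic",
                distance_bp=0,
                same_strand=locus.strand == gene.strand,
            ))
    return links


def gap_between(a: GenomicFeature, b: GenomicFeature) -> int:
    """Bases strictly between two same-chromosome intervals (0 if they
    overlap or abut)."""
    if a.start <= b.end and b.start <= a.end:
        return 0
    if b.start > a.end:
        return b.start - a.end - 1
    return a.start - b.end - 1


def find_nearby_genes(loci: Sequence[GenomicFeature],
                      genes: Sequence[GenomicFeature],
                      window: int = DEFAULT_NEARBY_WINDOW) -> List[LocusGeneLink]:
    """Nearby links: non-overlapping pairs with gap <= window.

    The distance is the number of bases strictly between the inclusive
    intervals (abutting intervals get distance 0 but remain "nearby", not
    intragenic). Overlapping pairs are reported by :func:`find_host_genes`
    only, never duplicated here.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    _check_chrom_styles(loci, genes)
    trees = _gene_trees(genes)
    links: List[LocusGeneLink] = []
    for locus in loci:
        tree = trees.get(locus.chrom)
        if tree is None:
            continue
        # expand the query by window+1 so any gene with gap <= window is hit
        lo = max(1, locus.start - window - 1)
        hi = locus.end + window + 2
        hits = sorted(tree.overlap(lo, hi), key=lambda iv: iv.data.feature_id)
        for iv in hits:
            gene = iv.data
            if locus.overlaps(gene):
                continue
            gap = gap_between(locus, gene)
            if gap <= window:
                links.append(LocusGeneLink(
                    locus_id=locus.feature_id,
                    gene_id=gene.feature_id,
                    relation="nearby",
                    distance_bp=gap,
                    same_strand=locus.strand == gene.strand,
                ))
    return links


def annotate_links(links: Iterable[LocusGeneLink],
                   locus_de: Sequence[DEResult] = (),
                   gene_de: Sequence[DEResult] = (),
                   only_de: bool = False,
                   alpha: float = 0.05,
                   lfc_min: float = 1.0) -> List[LocusGeneLink]:
    """Join locus and gene DE records onto links.

    With ``only_de`` the report keeps only links whose gene side is
    differentially expressed (padj < alpha and |log2FC| >= lfc_min);
    links lacking a gene DE record are then dropped too.
    """
    lmap = {d.feature_id: d for d in locus_de}
    gmap = {d.feature_id: d for d in gene_de}
    out: List[LocusGeneLink] = []
    for link in links:
        ld = lmap.get(link.locus_id)
        gd = gmap.get(link.gene_id)
        if only_de:
            if gd is None or gd.padj is None:
                continue
            if not (gd.padj < alpha and abs(gd.log2fc) >= lfc_min):
                continue
        out.append(replace(link, locus_de=ld, gene_de=gd))
    return out
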