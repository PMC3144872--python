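"""Gene annotation of regions under the exon-or-flank rule.

A gene is assigned to a region when the region's interval intersects an
exon of the gene or lies within ``flank`` bp (10 kb default) of the
transcript's 5' or 3' end. The literal rule therefore excludes regions
confined to a deep intron; ``gene_body_mode`` relaxes it to the whole
span [tx_start - flank, tx_end + flank] for coarser gene-level labeling.

Multiple transcripts per symbol should be merged (union of exons,
outermost bounds) with :func:`merge_transcripts` before indexing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from intervaltree import IntervalTree

from .overlap import OverlapRegion
from .scan import Region

__all__ = [
    "GeneModel",
    "AnnotationIndex",
    "build_annotation_index",
    "annotate_region",
    "merge_transcripts",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene: outermost transcript bounds plus exon intervals (1-based closed)."""

    symbol: str
    chromosome: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple  # ((start, end), ...) sorted, non-overlapping, inside tx bounds

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.symbol}: tx_start > tx_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.symbol}: strand must be '+' or '-'")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"invalid gene model {self.symbol}: exon start > end")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(
                    f"invalid gene model {self.symbol}: exon outside transcript bounds"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"invalid gene model {self.symbol}: exons unsorted or overlapping"
                )
            prev_end = e


def merge_transcripts(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Collapse multiple transcripts per symbol to one merged model.

    Exons are unioned (overlapping/adjacent exon intervals merged) and
    transcript bounds are the outermost; the first transcript's strand is
    kept. Symbols on different chromosomes are treated as distinct genes.
    """
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    order: list[tuple[str, str]] = []
    for g in genes:
        key = (g.symbol, g.chromosome)
        if key not in by_key:
            order.append(key)
        by_key.setdefault(key, []).append(g)
    out = []
    for key in order:
        models = by_key[key]
        if len(models) == 1:
            out.append(models[0])
            continue
        exons = sorted(iv for g in models for iv in g.exons)
        merged: list[list[int]] = []
        for s, e in exons:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.append(
            GeneModel(
                symbol=models[0].symbol,
                chromosome=models[0].chromosome,
                strand=models[0].strand,
                tx_start=min(g.tx_start for g in models),
                tx_end=max(g.tx_end for g in models),
                exons=tuple((s, e) for s, e in merged),
            )
        )
    return out


class AnnotationIndex:
    """Interval index from genomic intervals to gene symbols.

    Stores, per chromosome, an interval tree over the queryable pieces of
    every gene: its exons plus both flanks (or the flanked whole gene
    body in ``gene_body_mode``). Query coordinates are 1-based closed.
    """

    def __init__(self, flank: int = 10_000, gene_body_mode: bool = False):
        if flank < 0:
            raise ValueError("flank must be >= 0")
        self.flank = flank
        self.gene_body_mode = gene_body_mode
        self._trees: dict[str, IntervalTree] = {}

    def add(self, gene: GeneModel) -> None:
        tree = self._trees.setdefault(gene.chromosome, IntervalTree())
        if self.gene_body_mode:
            pieces = [(gene.tx_start - self.flank, gene.tx_end + self.flank)]
        else:
            pieces = list(gene.exons)
            if self.flank > 0:
                pieces.append((gene.tx_start - self.flank, gene.tx_start - 1))
                pieces.append((gene.tx_end + 1, gene.tx_end + self.flank))
        for s, e in pieces:
            s = max(s, 1)  # clip at chromosome start
            if s > e:
                continue
            tree[s : e + 1] = gene.symbol  # half-open tree over closed coords

    def query(self, chromosome: str, start: int, end: int) -> frozenset:
        """Symbols of genes whose indexed pieces intersect [start, end]."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return frozenset()
        return frozenset(iv.data for iv in tree.overlap(start, end + 1))

    @property
    def chromosomes(self) -> frozenset:
        return frozenset(self._trees)


def build_annotation_index(
    genes: Iterable[GeneModel],
    flank: int = 10_000,
    gene_body_mode: bool = False,
) -> AnnotationIndex:
    """Index merged gene models for region-to-gene queries."""
    index = AnnotationIndex(flank=flank, gene_body_mode=gene_body_mode)
    for g in genes:
        index.add(g)
    return index


def annotate_region(
    region: Union[Region, OverlapRegion], index: AnnotationIndex
) -> frozenset:
    """Gene symbols assigned to a region under the exon-or-flank rule.

    A region on a chromosome absent from the index yields the empty set.
    Reports should sort the returned set for deterministic output.
    """
    genes = index.query(region.chromosome, region.start, region.end)
    if isinstance(region, OverlapRegion):
        region.genes = genes
    return genes
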