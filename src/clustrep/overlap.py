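"""Cross-sample region overlap: the replication step.

A chromosomal region is "identified in both samples" when a cluster-tagged
interval from sample A intersects one from sample B on the same chromosome
(closed intervals; a shared single base pair counts). Intersection
intervals that themselves overlap are merged into connected components,
one :class:`OverlapRegion` each. Because within-sample regions are
disjoint, the merged-component count usually equals the intersecting-pair
count; both are reported since published counts do not pin down the
convention.

Enrichment is quantified against an independence null: the genome
fraction expected to be covered by overlap if the two samples' clustered
fractions were placed independently is their product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scan import Region, chromosome_sort_key, genome_fraction

__all__ = [
    "OverlapRegion",
    "OverlapSummary",
    "overlap_regions",
    "count_overlap_pairs",
    "count_overlap_pairs_positions",
    "enrichment_ratio",
    "cross_population_genes",
    "parse_gene_field",
    "summarize_overlap",
]


@dataclass
class OverlapRegion:
    """An interval tagged by clusters in two samples (1-based, closed).

    ``source_a``/``source_b`` are the contributing within-sample Regions;
    the interval is the union of all pairwise intersections among them.
    ``genes`` is filled by the annotation stage.
    """

    chromosome: str
    start: int
    end: int
    source_a: tuple
    source_b: tuple
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("overlap region start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class OverlapSummary:
    """Counts and genome fractions for one two-sample comparison."""

    n_overlap_regions: int
    n_pairs: int
    fraction_a: float
    fraction_b: float
    fraction_overlap: float
    enrichment_ratio: float  # percent of the chance expectation


def _check_sorted_disjoint(regions: Sequence[Region], label: str) -> None:
    prev: dict[str, int] = {}
    for r in regions:
        last = prev.get(r.chromosome)
        if last is not None and r.start <= last:
            raise ValueError(f"regions in sample {label} not sorted/disjoint")
        prev[r.chromosome] = r.end


def overlap_regions(
    regions_a: Sequence[Region], regions_b: Sequence[Region]
) -> list[OverlapRegion]:
    """All merged intersections between two samples' region sets.

    Both inputs must be sorted and disjoint within sample (as produced by
    :func:`clustrep.scan.find_clusters`). Every intersecting (a, b) pair
    contributes its intersection interval; overlapping intersection
    intervals on a chromosome are merged into one OverlapRegion. Output
    is sorted by (chromosome, start).
    """
    _check_sorted_disjoint(regions_a, "A")
    _check_sorted_disjoint(regions_b, "B")

    by_chrom_a: dict[str, list[Region]] = {}
    for r in regions_a:
        by_chrom_a.setdefault(r.chromosome, []).append(r)
    by_chrom_b: dict[str, list[Region]] = {}
    for r in regions_b:
        by_chrom_b.setdefault(r.chromosome, []).append(r)

    out: list[OverlapRegion] = []
    for chrom in sorted(set(by_chrom_a) & set(by_chrom_b), key=chromosome_sort_key):
        aa, bb = by_chrom_a[chrom], by_chrom_b[chrom]
        # two-pointer sweep over sorted disjoint intervals
        pieces: list[tuple[int, int, Region, Region]] = []
        i = j = 0
        while i < len(aa) and j < len(bb):
            a, b = aa[i], bb[j]
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if lo <= hi:
                pieces.append((lo, hi, a, b))
            if a.end < b.end:
                i += 1
            else:
                j += 1
        # merge intersection intervals that overlap into components
        pieces.sort(key=lambda t: (t[0], t[1]))
        k = 0
        while k < len(pieces):
            lo, hi = pieces[k][0], pieces[k][1]
            src_a, src_b = {id(pieces[k][2]): pieces[k][2]}, {id(pieces[k][3]): pieces[k][3]}
            k += 1
            while k < len(pieces) and pieces[k][0] <= hi:
                hi = max(hi, pieces[k][1])
                src_a[id(pieces[k][2])] = pieces[k][2]
                src_b[id(pieces[k][3])] = pieces[k][3]
                k += 1
            out.append(
                OverlapRegion(
                    chromosome=chrom,
                    start=lo,
                    end=hi,
                    source_a=tuple(src_a.values()),
                    source_b=tuple(src_b.values()),
                )
            )
    return out


def count_overlap_pairs_positions(
    start_a: np.ndarray,
    end_a: np.ndarray,
    start_b: np.ndarray,
    end_b: np.ndarray,
) -> int:
    """Count intersecting (a, b) interval pairs on shared coordinates.

    Inputs are sorted, disjoint closed intervals (global coordinates are
    fine). With disjoint inputs the pair count equals the merged overlap
    region count, so this is the fast path for Monte Carlo trials.
    """
    if len(start_a) == 0 or len(start_b) == 0:
        return 0
    lo = np.searchsorted(end_b, start_a, side="left")
    hi = np.searchsorted(start_b, end_a, side="right")
    return int(np.maximum(hi - lo, 0).sum())


def count_overlap_pairs(
    regions_a: Sequence[Region], regions_b: Sequence[Region]
) -> int:
    """Number of intersecting (A-region, B-region) pairs across samples."""
    by_chrom_a: dict[str, list[Region]] = {}
    for r in regions_a:
        by_chrom_a.setdefault(r.chromosome, []).append(r)
    by_chrom_b: dict[str, list[Region]] = {}
    for r in regions_b:
        by_chrom_b.setdefault(r.chromosome, []).append(r)
    n = 0
    for chrom in set(by_chrom_a) & set(by_chrom_b):
        aa, bb = by_chrom_a[chrom], by_chrom_b[chrom]
        n += count_overlap_pairs_positions(
            np.array([r.start for r in aa]),
            np.array([r.end for r in aa]),
            np.array([r.start for r in bb]),
            np.array([r.end for r in bb]),
        )
    return n


def enrichment_ratio(
    fraction_a: float, fraction_b: float, fraction_overlap: float
) -> float:
    """Observed overlap fraction as a percent of the chance expectation.

    The expected-by-chance overlap fraction under independence is
    fraction_a * fraction_b; the ratio is 100 * observed / expected,
    so 100 means exactly the chance level.
    """
    if fraction_a <= 0 or fraction_b <= 0:
        raise ValueError("undefined ratio: zero input fraction")
    return 100.0 * fraction_overlap / (fraction_a * fraction_b)


def parse_gene_field(cell: str) -> frozenset:
    """Normalize one gene(s) table cell to a set of uppercase symbols."""
    return frozenset(
        g.strip().upper() for g in str(cell).split(",") if g.strip()
    )


def cross_population_genes(*gene_sets: Iterable[str]) -> frozenset:
    """Intersection of two or more gene-symbol sets (normalized)."""
    if len(gene_sets) < 2:
        raise ValueError("need at least two gene sets")
    norm = [frozenset(str(g).strip().upper() for g in s) for s in gene_sets]
    out = norm[0]
    for s in norm[1:]:
        out &= s
    return out


def summarize_overlap(
    regions_a: Sequence[Region],
    regions_b: Sequence[Region],
    chrom_sizes: Mapping[str, int],
) -> OverlapSummary:
    """Overlap counts, genome fractions and the enrichment ratio."""
    merged = overlap_regions(regions_a, regions_b)
    n_pairs = count_overlap_pairs(regions_a, regions_b)
    fa = genome_fraction(regions_a, chrom_sizes)
    fb = genome_fraction(regions_b, chrom_sizes)
    total = float(sum(chrom_sizes.values()))
    f_ov = sum(m.length for m in merged) / total
    ratio = enrichment_ratio(fa, fb, f_ov) if fa > 0 and fb > 0 else float("nan")
    return OverlapSummary(
        n_overlap_regions=len(merged),
        n_pairs=n_pairs,
        fraction_a=fa,
        fraction_b=fb,
        fraction_overlap=f_ov,
        enrichment_ratio=ratio,
    )
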