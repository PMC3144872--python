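"""Positional scan for clusters of nominally significant SNPs.

A cluster is a maximal run of nominally significant markers on one
chromosome in which every adjacent pair lies within ``max_gap`` base
pairs (10 kb by default), containing at least ``min_cluster_size``
members (4 by default; 3 within 25 kb is the conventional setting for
sparser ~500K arrays). The chromosomal region tagged by a cluster is the
closed interval spanned by its outermost member SNPs.

The chain is over significant markers only: intervening non-significant
markers neither join nor break a cluster. The scan is purely positional —
no linkage-disequilibrium information is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .association import SnpRecord

__all__ = [
    "ScanParams",
    "Region",
    "select_nominal",
    "find_clusters",
    "genome_fraction",
    "split_runs",
    "count_clusters_positions",
    "cluster_spans_positions",
    "normalize_chromosome",
    "chromosome_sort_key",
    "AUTOSOMES",
]

AUTOSOMES = tuple(str(i) for i in range(1, 23))


def normalize_chromosome(label: str) -> str:
    """Strip a leading 'chr' prefix and uppercase sex/mito labels."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.lower() in ("x", "y", "mt", "m") else s


def chromosome_sort_key(label: str):
    """Numeric chromosomes first in numeric order, then others lexically."""
    s = normalize_chromosome(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass(frozen=True)
class ScanParams:
    """Cluster-scan thresholds.

    alpha: nominal per-SNP significance level (strict: p < alpha).
    min_cluster_size: minimum members per cluster.
    max_gap: maximum distance in bp between adjacent cluster members.
    """

    alpha: float = 0.05
    min_cluster_size: int = 4
    max_gap: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass(frozen=True)
class Region:
    """A cluster-tagged chromosomal interval (1-based, closed).

    Boundaries coincide with the outermost member SNP positions.
    """

    chromosome: str
    start: int
    end: int
    member_snp_ids: tuple
    n_snps: int
    min_p: float
    min_p_snp_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        if self.n_snps != len(self.member_snp_ids):
            raise ValueError("n_snps does not match member list")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def select_nominal(
    snps: Sequence[SnpRecord], alpha: float = 0.05
) -> list[SnpRecord]:
    """Markers with p < alpha (strict), sorted by (chromosome, position)."""
    sig = [s for s in snps if s.p_value < alpha]
    sig.sort(key=lambda s: (chromosome_sort_key(s.chromosome), s.position))
    return sig


def split_runs(positions: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Index bounds of maximal runs with adjacent gaps <= max_gap.

    ``positions`` must be sorted ascending. Returns (start_idx, end_idx)
    arrays of inclusive indices, one entry per maximal run.
    """
    n = len(positions)
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    breaks = np.flatnonzero(np.diff(positions) > max_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [n - 1]))
    return starts, ends


def count_clusters_positions(
    positions: np.ndarray, max_gap: int, min_size: int
) -> int:
    """Number of maximal runs of size >= min_size in a sorted position array.

    Positions may be 'global' coordinates (chromosomes offset so that
    cross-chromosome gaps always exceed max_gap).
    """
    starts, ends = split_runs(positions, max_gap)
    return int(np.count_nonzero(ends - starts + 1 >= min_size))


def cluster_spans_positions(
    positions: np.ndarray, max_gap: int, min_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """(span_start, span_end) position arrays of qualifying runs."""
    starts, ends = split_runs(positions, max_gap)
    keep = ends - starts + 1 >= min_size
    return positions[starts[keep]], positions[ends[keep]]


def find_clusters(
    nominal: Sequence[SnpRecord], params: ScanParams = ScanParams()
) -> list[Region]:
    """Scan position-sorted significant SNPs for clusters, per chromosome.

    Input must already be restricted to nominally significant markers
    (all p < alpha) and sorted by (chromosome, position), as produced by
    :func:`select_nominal`. Returns disjoint Regions sorted by position.
    """
    regions: list[Region] = []
    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in nominal:
        if s.p_value >= params.alpha:
            raise ValueError(
                f"{s.snp_id}: p={s.p_value} not nominally significant at alpha={params.alpha}"
            )
        by_chrom.setdefault(s.chromosome, []).append(s)

    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        recs = by_chrom[chrom]
        pos = np.array([r.position for r in recs], dtype=np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"input not sorted on chromosome {chrom}")
        starts, ends = split_runs(pos, params.max_gap)
        for i0, i1 in zip(starts, ends):
            members = recs[i0 : i1 + 1]
            if len(members) < params.min_cluster_size:
                continue
            best = min(members, key=lambda r: r.p_value)
            regions.append(
                Region(
                    chromosome=chrom,
                    start=int(members[0].position),
                    end=int(members[-1].position),
                    member_snp_ids=tuple(r.snp_id for r in members),
                    n_snps=len(members),
                    min_p=float(best.p_value),
                    min_p_snp_id=best.snp_id,
                )
            )
    return regions


def genome_fraction(
    regions: Iterable[Region], chrom_sizes: Mapping[str, int]
) -> float:
    """Fraction of the genome covered by regions (closed-interval lengths).

    The denominator is the total length of the chromosomes in
    ``chrom_sizes``; regions must lie within their chromosome bounds.
    """
    total = float(sum(chrom_sizes.values()))
    if total <= 0:
        raise ValueError("chromosome sizes must sum to a positive length")
    covered = 0
    for r in regions:
        size = chrom_sizes.get(r.chromosome)
        if size is None:
            raise KeyError(f"chromosome {r.chromosome} missing from chrom_sizes")
        if r.end > size or r.start < 1:
            raise ValueError(
                f"region out of bounds: {r.chromosome}:{r.start}-{r.end} (size {size})"
            )
        covered += r.length
    return covered / total
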