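"""Monte Carlo pseudo-positive resampling nulls.

Two empirical null hypotheses are tested by relabeling markers rather
than permuting phenotypes:

* clustering null — the nominally significant SNPs of one sample are
  randomly arrayed over that sample's marker map. Each trial draws, from
  the full list of assayed autosomal SNPs, a "pseudo-positive" set whose
  size matches the observed significant count, then re-runs the cluster
  scan on it.
* overlap null — the chromosomal regions tagged by clusters in two
  independent samples coincide no more than chance predicts. Each trial
  draws pseudo-positives independently in both maps, clusters each, and
  counts cross-sample overlap regions.

Marker positions are never altered; only the significance labels move.
Empirical p-values use the add-one estimator (n_exceed + 1)/(n_trials + 1)
with ties counted as exceedances, so a result that no trial matches is
reported as 1/(n_trials + 1) — the conventional "p < 1/n_trials" floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .association import SnpRecord
from .scan import (
    ScanParams,
    chromosome_sort_key,
    cluster_spans_positions,
    split_runs,
)
from .overlap import count_overlap_pairs_positions

__all__ = [
    "SnpMap",
    "MonteCarloResult",
    "draw_pseudopositives",
    "mc_clustering_null",
    "mc_overlap_null",
    "empirical_p",
]


@dataclass
class SnpMap:
    """All assayed (post-QC) markers of one sample, ordered per chromosome.

    ``positions``/``ids`` map chromosome label -> sorted arrays. The map
    is the resampling population for pseudo-positive draws; ``n_positive``
    records how many markers achieved nominal significance in the real
    data, when known.
    """

    positions: dict
    ids: dict
    n_positive: Optional[int] = None

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.positions[chrom] = pos
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on chromosome {chrom}")
            if chrom in self.ids and len(self.ids[chrom]) != len(pos):
                raise ValueError(f"ids/positions length mismatch on {chrom}")
        if self.n_positive is not None and self.n_positive > self.n_total:
            raise ValueError("n_positive exceeds n_total")

    @property
    def n_total(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    @classmethod
    def from_records(
        cls, snps: Sequence[SnpRecord], n_positive: Optional[int] = None
    ) -> "SnpMap":
        by_chrom: dict[str, list[SnpRecord]] = {}
        for s in snps:
            by_chrom.setdefault(s.chromosome, []).append(s)
        positions, ids = {}, {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.position)
            positions[chrom] = np.array([r.position for r in recs], dtype=np.int64)
            ids[chrom] = np.array([r.snp_id for r in recs], dtype=object)
        return cls(positions=positions, ids=ids, n_positive=n_positive)

    def global_positions(self, max_gap: int) -> np.ndarray:
        """All positions on one axis, chromosomes offset beyond max_gap.

        Consecutive chromosomes are shifted so inter-chromosome gaps
        always exceed ``max_gap``; run-splitting on the global axis then
        matches per-chromosome splitting exactly.
        """
        chroms = sorted(self.positions, key=chromosome_sort_key)
        parts = []
        offset = 0
        for chrom in chroms:
            pos = self.positions[chrom]
            if len(pos):
                parts.append(pos + offset)
                offset += int(pos[-1]) + max_gap + 1
            else:
                offset += max_gap + 1
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(parts)


@dataclass
class MonteCarloResult:
    """Observed statistic, trial distribution and empirical p for one null."""

    null_id: str  # "clustering" or "overlap"
    observed_stat: float
    trial_stats: np.ndarray
    n_exceed: int
    empirical_p: float
    n_trials: int
    seed: int
    secondary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "null_id": self.null_id,
            "observed_stat": float(self.observed_stat),
            "n_trials": int(self.n_trials),
            "n_exceed": int(self.n_exceed),
            "empirical_p": float(self.empirical_p),
            "seed": int(self.seed),
            **{k: v for k, v in self.secondary.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def empirical_p(n_exceed: int, n_trials: int) -> float:
    """Add-one empirical p-value: (n_exceed + 1) / (n_trials + 1).

    Never returns 0: with 0 exceedances in 10,000 trials the estimate is
    1/10,001, conventionally reported as p < 0.0001.
    """
    if n_trials < 1:
        raise ValueError("no trials")
    if not (0 <= n_exceed <= n_trials):
        raise ValueError("n_exceed outside [0, n_trials]")
    return (n_exceed + 1) / (n_trials + 1)


def _trial_rng(seed: int, trial: int) -> np.random.Generator:
    # deterministic per-trial substream: results independent of execution order
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(trial))))


def draw_pseudopositives(
    snp_map: SnpMap, n_positive: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draw of n_positive marker indices, without replacement.

    Indices refer to the map's global ordering (chromosomes concatenated
    in sorted order). Returned sorted ascending.
    """
    n = snp_map.n_total
    if n_positive > n:
        raise ValueError("sample larger than population")
    if n_positive == 0:
        return np.empty(0, dtype=np.int64)
    idx = rng.choice(n, size=n_positive, replace=False)
    idx.sort()
    return idx


def _resolve_n_positive(snp_map: SnpMap, n_positive: Optional[int]) -> int:
    n = n_positive if n_positive is not None else snp_map.n_positive
    if n is None:
        raise ValueError("n_positive not given and not recorded on the SnpMap")
    return int(n)


def mc_clustering_null(
    snp_map: SnpMap,
    params: ScanParams,
    observed_stat: float,
    n_trials: int = 10_000,
    seed: int = 0,
    n_positive: Optional[int] = None,
) -> MonteCarloResult:
    """Empirical p for the within-sample clustering extent.

    ``observed_stat`` is the cluster count obtained by the scan on the
    real significant set with the same ``params``. Each trial relabels
    a random marker subset of the same size as significant and re-counts
    clusters. The mean count of clustered SNPs across trials is reported
    as a secondary statistic.
    """
    n_pos = _resolve_n_positive(snp_map, n_positive)
    gpos = snp_map.global_positions(params.max_gap)
    trial_stats = np.empty(n_trials, dtype=np.int64)
    clustered_snps = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        rng = _trial_rng(seed, t)
        idx = draw_pseudopositives(snp_map, n_pos, rng)
        sub = gpos[idx]
        starts, ends = split_runs(sub, params.max_gap)
        sizes = ends - starts + 1
        keep = sizes >= params.min_cluster_size
        trial_stats[t] = int(np.count_nonzero(keep))
        clustered_snps[t] = int(sizes[keep].sum())
    n_exceed = int(np.count_nonzero(trial_stats >= observed_stat))
    return MonteCarloResult(
        null_id="clustering",
        observed_stat=observed_stat,
        trial_stats=trial_stats,
        n_exceed=n_exceed,
        empirical_p=empirical_p(n_exceed, n_trials),
        n_trials=n_trials,
        seed=seed,
        secondary={
            "mean_trial_clustered_snps": float(clustered_snps.mean()) if n_trials else 0.0,
            "params": {
                "alpha": params.alpha,
                "min_cluster_size": params.min_cluster_size,
                "max_gap": params.max_gap,
            },
        },
    )


def mc_overlap_null(
    map_a: SnpMap,
    map_b: SnpMap,
    params: ScanParams,
    observed_stat: float,
    n_trials: int = 10_000,
    seed: int = 0,
    n_positive_a: Optional[int] = None,
    n_positive_b: Optional[int] = None,
) -> MonteCarloResult:
    """Empirical p for the extent of between-sample region overlap.

    ``observed_stat`` is the overlap-region count from the two real
    cluster sets. Pseudo-positive draws are independent between samples;
    the global coordinate axes of the two maps are aligned chromosome by
    chromosome so trial regions can be intersected directly.
    """
    n_pos_a = _resolve_n_positive(map_a, n_positive_a)
    n_pos_b = _resolve_n_positive(map_b, n_positive_b)

    # shared chromosome offsets so both maps live on one comparable axis
    chroms = sorted(
        set(map_a.positions) | set(map_b.positions), key=chromosome_sort_key
    )
    offsets = {}
    offset = 0
    for chrom in chroms:
        offsets[chrom] = offset
        hi_a = int(map_a.positions[chrom][-1]) if len(map_a.positions.get(chrom, ())) else 0
        hi_b = int(map_b.positions[chrom][-1]) if len(map_b.positions.get(chrom, ())) else 0
        offset += max(hi_a, hi_b) + params.max_gap + 1

    def _gpos(m: SnpMap) -> np.ndarray:
        parts = [
            m.positions[c] + offsets[c]
            for c in sorted(m.positions, key=chromosome_sort_key)
            if len(m.positions[c])
        ]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    gpos_a, gpos_b = _gpos(map_a), _gpos(map_b)
    trial_stats = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        rng_a = _trial_rng(seed, 2 * t)
        rng_b = _trial_rng(seed, 2 * t + 1)
        sub_a = gpos_a[draw_pseudopositives(map_a, n_pos_a, rng_a)]
        sub_b = gpos_b[draw_pseudopositives(map_b, n_pos_b, rng_b)]
        sa, ea = cluster_spans_positions(sub_a, params.max_gap, params.min_cluster_size)
        sb, eb = cluster_spans_positions(sub_b, params.max_gap, params.min_cluster_size)
        trial_stats[t] = count_overlap_pairs_positions(sa, ea, sb, eb)
    n_exceed = int(np.count_nonzero(trial_stats >= observed_stat))
    return MonteCarloResult(
        null_id="overlap",
        observed_stat=observed_stat,
        trial_stats=trial_stats,
        n_exceed=n_exceed,
        empirical_p=empirical_p(n_exceed, n_trials),
        n_trials=n_trials,
        seed=seed,
        secondary={
            "n_positive_a": n_pos_a,
            "n_positive_b": n_pos_b,
            "params": {
                "alpha": params.alpha,
                "min_cluster_size": params.min_cluster_size,
                "max_gap": params.max_gap,
            },
        },
    )
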