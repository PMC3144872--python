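"""Synthetic dual-platform GWAS datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes,
not real genomes: two genotyping platforms assay different marker maps
with a controllable shared fraction (about 1/4 of autosomal markers are
shared between the ~900K and ~1M SNP arrays the two designs use);
markers unrelated to phenotype carry Uniform(0,1) p-values; markers in
planted risk regions carry Beta(a, b) p-values with a < 1, enriching
small values with closed-form per-SNP power P(p < alpha) = alpha**a for
Beta(a, 1); pooled allele-frequency estimates get Gaussian noise with
SD 0.02, the pool-to-pool variation reported for validated pooling on
these arrays; and individual genotypes follow binomial (HWE) sampling.

Linkage disequilibrium is deliberately not modeled: planted regions are
dense runs of independently significant markers, which is what the
positional cluster scan actually consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .annotate import GeneModel
from .association import PoolFreqSet, SnpRecord
from .montecarlo import SnpMap
from .scan import chromosome_sort_key

__all__ = [
    "SimConfig",
    "TruthRegion",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_snp_maps",
    "plant_risk_regions",
    "simulate_pvalues",
    "simulate_pools",
    "simulate_genotype_counts",
    "simulate_gene_models",
    "generate_dataset",
    "records_from_map",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults give two 100,000-marker maps over ten 20-Mb chromosomes
    (mean spacing 2 kb, so clusters at the 10-kb gap rule are easy to
    form inside dense planted regions but rare among the ~5% of null
    markers that are nominally significant), a quarter of markers shared
    between platforms, and 20 planted risk regions of at least 6 markers
    per platform with Beta(0.1, 1) p-values (per-SNP power 0.74 at
    alpha = 0.05).
    """

    n_chromosomes: int = 10
    chrom_length: int = 20_000_000
    n_snps_a: int = 100_000
    n_snps_b: int = 100_000
    shared_fraction: float = 0.25
    n_risk_regions: int = 20
    snps_per_risk_region: int = 6
    risk_p_beta: tuple = (0.1, 1.0)
    max_gap: int = 10_000
    pool_noise_sd: float = 0.02
    n_pools_per_group: int = 4
    n_case: int = 1000
    n_control: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0,1]")
        if self.pool_noise_sd < 0:
            raise ValueError("pool_noise_sd must be >= 0")
        if self.risk_p_beta[0] <= 0 or self.risk_p_beta[1] <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def chrom_sizes(self) -> dict:
        return {str(i + 1): self.chrom_length for i in range(self.n_chromosomes)}


@dataclass(frozen=True)
class TruthRegion:
    """One planted risk region with its member markers per platform."""

    chromosome: str
    start: int
    end: int
    members_a: tuple
    members_b: tuple


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted risk-region coordinates, for recovery scoring."""

    regions: tuple

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class SyntheticDataset:
    """One generated two-platform dataset, ready for the pipeline."""

    config: SimConfig
    map_a: SnpMap
    map_b: SnpMap
    shared_ids: frozenset
    truth: SyntheticTruth
    records_a: list
    records_b: list


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _distinct_positions(
    rng: np.random.Generator, n: int, length: int
) -> np.ndarray:
    """n distinct uniform positions in [1, length], sorted."""
    if n > length:
        raise ValueError("density too high: requested SNPs exceed distinct positions")
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # oversample and deduplicate; collisions are rare at the densities used
    draw = n
    pos = np.unique(rng.integers(1, length + 1, size=draw))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=max(n - len(pos), 16) * 2)
        pos = np.unique(np.concatenate([pos, extra]))
    if len(pos) > n:
        keep = rng.choice(len(pos), size=n, replace=False)
        pos = np.sort(pos[keep])
    return pos.astype(np.int64)


def simulate_snp_maps(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[SnpMap, SnpMap, frozenset]:
    """Two platform marker maps with a shared subset at identical positions.

    The shared marker count is exactly
    round(shared_fraction * min(n_snps_a, n_snps_b)); shared markers get
    the same id on both maps. Returns (map_a, map_b, shared ids).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_shared = round(config.shared_fraction * min(config.n_snps_a, config.n_snps_b))
    shared_per_chrom = _split_counts(n_shared, config.n_chromosomes)
    a_per_chrom = _split_counts(config.n_snps_a, config.n_chromosomes)
    b_per_chrom = _split_counts(config.n_snps_b, config.n_chromosomes)

    pos_a: dict[str, np.ndarray] = {}
    ids_a: dict[str, np.ndarray] = {}
    pos_b: dict[str, np.ndarray] = {}
    ids_b: dict[str, np.ndarray] = {}
    shared_ids: list[str] = []

    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        n_s = shared_per_chrom[c]
        n_ao = a_per_chrom[c] - n_s
        n_bo = b_per_chrom[c] - n_s
        if n_ao < 0 or n_bo < 0:
            raise ValueError("shared_fraction too high for the per-platform counts")
        allpos = _distinct_positions(rng, n_s + n_ao + n_bo, config.chrom_length)
        perm = rng.permutation(len(allpos))
        p_shared = allpos[perm[:n_s]]
        p_aonly = allpos[perm[n_s : n_s + n_ao]]
        p_bonly = allpos[perm[n_s + n_ao :]]

        s_ids = np.array([f"s{chrom}_{p}" for p in p_shared], dtype=object)
        shared_ids.extend(s_ids.tolist())
        a_ids = np.array([f"a{chrom}_{p}" for p in p_aonly], dtype=object)
        b_ids = np.array([f"b{chrom}_{p}" for p in p_bonly], dtype=object)

        pa = np.concatenate([p_shared, p_aonly])
        ia = np.concatenate([s_ids, a_ids]) if len(pa) else np.empty(0, dtype=object)
        order = np.argsort(pa, kind="stable")
        pos_a[chrom], ids_a[chrom] = pa[order], ia[order]

        pb = np.concatenate([p_shared, p_bonly])
        ib = np.concatenate([s_ids, b_ids]) if len(pb) else np.empty(0, dtype=object)
        order = np.argsort(pb, kind="stable")
        pos_b[chrom], ids_b[chrom] = pb[order], ib[order]

    return (
        SnpMap(positions=pos_a, ids=ids_a),
        SnpMap(positions=pos_b, ids=ids_b),
        frozenset(shared_ids),
    )


def plant_risk_regions(
    map_a: SnpMap,
    map_b: SnpMap,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticTruth:
    """Choose disjoint risk regions dense on BOTH maps.

    Candidate regions are maximal runs of markers shared by the two maps
    (identical positions) in which adjacent shared markers lie within
    ``max_gap`` and the run holds at least ``snps_per_risk_region``
    markers; such a run is simultaneously a chained dense stretch on
    each platform. Runs are separated by more than ``max_gap`` by
    construction. ``n_risk_regions`` of them are drawn at random.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    k = config.snps_per_risk_region
    candidates: list[tuple[str, int, int]] = []
    for chrom in sorted(set(map_a.positions) & set(map_b.positions), key=chromosome_sort_key):
        shared = np.intersect1d(map_a.positions[chrom], map_b.positions[chrom])
        if len(shared) < k:
            continue
        breaks = np.flatnonzero(np.diff(shared) > config.max_gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(shared) - 1]))
        for i0, i1 in zip(starts, ends):
            if i1 - i0 + 1 >= k:
                candidates.append((chrom, int(shared[i0]), int(shared[i1])))
    if len(candidates) < config.n_risk_regions:
        raise ValueError(
            f"cannot place regions: only {len(candidates)} candidate dense "
            f"shared runs for {config.n_risk_regions} requested"
        )
    chosen_idx = rng.choice(len(candidates), size=config.n_risk_regions, replace=False)
    regions = []
    for i in sorted(chosen_idx.tolist()):
        chrom, start, end = candidates[i]
        in_a = (map_a.positions[chrom] >= start) & (map_a.positions[chrom] <= end)
        in_b = (map_b.positions[chrom] >= start) & (map_b.positions[chrom] <= end)
        regions.append(
            TruthRegion(
                chromosome=chrom,
                start=start,
                end=end,
                members_a=tuple(map_a.ids[chrom][in_a].tolist()),
                members_b=tuple(map_b.ids[chrom][in_b].tolist()),
            )
        )
    return SyntheticTruth(regions=tuple(regions))


def simulate_pvalues(
    snp_map: SnpMap,
    truth: Optional[SyntheticTruth],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Per-SNP p-values: Uniform(0,1) null, Beta(a,b) inside risk regions.

    Returns {chromosome: array aligned to the map's positions}. All
    p-values are independent across markers.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    a, b = config.risk_p_beta
    out: dict[str, np.ndarray] = {}
    for chrom in sorted(snp_map.positions, key=chromosome_sort_key):
        pos = snp_map.positions[chrom]
        p = rng.uniform(size=len(pos))
        if truth is not None:
            risk = np.zeros(len(pos), dtype=bool)
            for region in truth.regions:
                if region.chromosome == chrom:
                    risk |= (pos >= region.start) & (pos <= region.end)
            n_risk = int(risk.sum())
            if n_risk:
                p[risk] = rng.beta(a, b, size=n_risk)
        out[chrom] = p
    return out


def records_from_map(snp_map: SnpMap, pvalues: dict) -> list[SnpRecord]:
    """Assemble SnpRecords from a map and its simulated p-values."""
    records = []
    for chrom in sorted(snp_map.positions, key=chromosome_sort_key):
        pos = snp_map.positions[chrom]
        ids = snp_map.ids[chrom]
        pv = pvalues[chrom]
        records.extend(
            SnpRecord(chromosome=chrom, position=int(pos[i]), snp_id=str(ids[i]), p_value=float(pv[i]))
            for i in range(len(pos))
        )
    return records


def simulate_pools(
    true_freq_case: float,
    true_freq_control: float,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PoolFreqSet, PoolFreqSet]:
    """Per-pool allele-frequency estimates with Gaussian measurement noise.

    Each pool's estimate is the group's true frequency plus
    N(0, pool_noise_sd) noise, truncated to [0, 1].
    """
    if not (0.0 <= true_freq_case <= 1.0 and 0.0 <= true_freq_control <= 1.0):
        raise ValueError("true frequencies must be in [0,1]")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    k = config.n_pools_per_group
    case = np.clip(true_freq_case + rng.normal(0.0, config.pool_noise_sd, size=k), 0.0, 1.0)
    ctrl = np.clip(true_freq_control + rng.normal(0.0, config.pool_noise_sd, size=k), 0.0, 1.0)
    return (
        PoolFreqSet(group="case", estimates=tuple(case)),
        PoolFreqSet(group="control", estimates=tuple(ctrl)),
    )


def simulate_genotype_counts(
    freq_case,
    freq_control,
    n_case: int,
    n_control: int,
    rng: np.random.Generator,
):
    """2x2 allele-count tables under HWE: binomial(2n, freq) minor alleles.

    Frequencies may be scalars or arrays (one table per element).
    Returns ((case_minor, case_major), (control_minor, control_major)).
    """
    fc = np.asarray(freq_case, dtype=float)
    f0 = np.asarray(freq_control, dtype=float)
    if np.any(fc < 0) or np.any(fc > 1) or np.any(f0 < 0) or np.any(f0 > 1):
        raise ValueError("frequencies must be in [0,1]")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("subject counts must be positive")
    case_minor = rng.binomial(2 * n_case, fc)
    ctrl_minor = rng.binomial(2 * n_control, f0)
    return (
        (case_minor, 2 * n_case - case_minor),
        (ctrl_minor, 2 * n_control - ctrl_minor),
    )


def simulate_gene_models(
    config: SimConfig,
    truth: Optional[SyntheticTruth] = None,
    n_background_genes: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> list[GeneModel]:
    """Non-overlapping multi-exon genes; one covering each planted region.

    For every truth region a gene is placed whose transcript spans it
    (so annotation should recover it); background genes are scattered
    uniformly and kept disjoint by rejection. Exons are short blocks at
    the ends plus evenly spaced internal blocks, leaving long introns —
    useful for exercising the intron-only exclusion of the literal
    exon-or-flank rule.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    placed: dict[str, list[tuple[int, int]]] = {str(c + 1): [] for c in range(config.n_chromosomes)}
    genes: list[GeneModel] = []

    def _exons(tx_start: int, tx_end: int, n_exons: int) -> tuple:
        length = tx_end - tx_start + 1
        n_exons = max(2, min(n_exons, max(2, length // 2000)))
        anchors = np.linspace(tx_start, tx_end, n_exons, dtype=np.int64)
        exons = []
        for i, a0 in enumerate(anchors):
            size = int(rng.integers(150, 400))
            s = int(a0) if i < n_exons - 1 else max(tx_start, int(a0) - size)
            e = min(tx_end, s + size)
            if exons and s <= exons[-1][1]:
                continue
            exons.append((s, e))
        exons[0] = (tx_start, exons[0][1])
        exons[-1] = (exons[-1][0], tx_end)
        return tuple(exons)

    def _free(chrom: str, s: int, e: int) -> bool:
        return all(e < s0 or s > e0 for s0, e0 in placed[chrom])

    counter = 0
    if truth is not None:
        for region in truth.regions:
            # transcript spans the region exactly, so its first exon starts
            # inside the region and the literal exon rule recovers the gene
            s, e = region.start, region.end
            if not _free(region.chromosome, s, e):
                continue
            placed[region.chromosome].append((s, e))
            counter += 1
            genes.append(
                GeneModel(
                    symbol=f"RISKG{counter}",
                    chromosome=region.chromosome,
                    strand="+" if rng.random() < 0.5 else "-",
                    tx_start=s,
                    tx_end=e,
                    exons=_exons(s, e, int(rng.integers(2, 9))),
                )
            )
    attempts = 0
    n_bg = 0
    while n_bg < n_background_genes and attempts < 50 * n_background_genes:
        attempts += 1
        chrom = str(int(rng.integers(1, config.n_chromosomes + 1)))
        length = int(rng.integers(20_000, 200_000))
        s = int(rng.integers(1, max(2, config.chrom_length - length)))
        e = s + length
        if not _free(chrom, s, e):
            continue
        placed[chrom].append((s, e))
        n_bg += 1
        genes.append(
            GeneModel(
                symbol=f"BGG{chrom}_{n_bg}",
                chromosome=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                tx_start=s,
                tx_end=e,
                exons=_exons(s, e, int(rng.integers(2, 9))),
            )
        )
    return genes


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full two-platform dataset: maps, planted truth and p-values.

    All randomness flows from ``config.seed`` through independent
    substreams, so identical configs reproduce identical datasets.
    """
    root = np.random.SeedSequence(config.seed)
    ss = root.spawn(4)
    rng_maps = np.random.default_rng(ss[0])
    rng_truth = np.random.default_rng(ss[1])
    rng_pa = np.random.default_rng(ss[2])
    rng_pb = np.random.default_rng(ss[3])

    map_a, map_b, shared = simulate_snp_maps(config, rng_maps)
    if config.n_risk_regions > 0:
        truth = plant_risk_regions(map_a, map_b, config, rng_truth)
    else:
        truth = SyntheticTruth(regions=())
    pv_a = simulate_pvalues(map_a, truth, config, rng_pa)
    pv_b = simulate_pvalues(map_b, truth, config, rng_pb)
    return SyntheticDataset(
        config=config,
        map_a=map_a,
        map_b=map_b,
        shared_ids=shared,
        truth=truth,
        records_a=records_from_map(map_a, pv_a),
        records_b=records_from_map(map_b, pv_b),
    )
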