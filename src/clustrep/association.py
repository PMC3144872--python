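"""Per-SNP association tests and marker-level quality-control filters.

Two routes to a nominal per-SNP p-value are supported, matching the two
genotyping designs the pipeline handles:

* individually genotyped case/control samples → 1-df allelic Pearson
  chi-square on the 2x2 minor/major allele count table;
* multi-pool DNA pooling designs → a two-sample t-test comparing the
  per-pool minor-allele frequency estimates of case pools against
  control pools (Welch by default).

QC filtering drops markers with minor-allele frequency below a threshold
(0.01-0.02 depending on population) or missing-call rate above 5%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "PoolFreqSet",
    "AssocResult",
    "Exclusion",
    "DegenerateTableError",
    "InsufficientPoolsError",
    "chi2_allelic",
    "chi2_allelic_arrays",
    "pool_ttest",
    "welch_ttest_arrays",
    "filter_snps",
]


class DegenerateTableError(ValueError):
    """Raised for a monomorphic 2x2 allele table (a zero marginal)."""


class InsufficientPoolsError(ValueError):
    """Raised when a pool t-test is requested with fewer than 2 pools in a group."""


@dataclass(frozen=True)
class SnpRecord:
    """One marker: map position, association p-value and optional QC fields.

    Coordinates are 1-based. ``maf`` and ``missing_rate`` may be absent
    when the input is a pre-filtered public association table.
    """

    chromosome: str
    position: int
    snp_id: str
    p_value: float
    maf: Optional[float] = None
    missing_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.snp_id}: p_value {self.p_value} outside [0,1]")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0,0.5]")
        if self.missing_rate is not None and not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError(f"{self.snp_id}: missing_rate outside [0,1]")


@dataclass(frozen=True)
class PoolFreqSet:
    """Per-pool minor-allele frequency estimates for one phenotype group."""

    group: str  # "case" or "control"
    estimates: tuple

    def __post_init__(self) -> None:
        est = tuple(float(x) for x in self.estimates)
        object.__setattr__(self, "estimates", est)
        if any(not (0.0 <= x <= 1.0) for x in est):
            raise ValueError("pool frequency estimate outside [0,1]")


@dataclass(frozen=True)
class AssocResult:
    statistic: float
    df: float
    p_value: float


class Exclusion(NamedTuple):
    snp_id: str
    reason: str


def chi2_allelic_arrays(
    case_minor: np.ndarray,
    case_major: np.ndarray,
    control_minor: np.ndarray,
    control_major: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised 1-df allelic chi-square (no continuity correction).

    Uses the closed form n(ad-bc)^2 / (r1 r2 c1 c2) for the 2x2 table
    [[a, b], [c, d]] = [[case_minor, case_major], [ctl_minor, ctl_major]].
    Returns (statistic, p_value) arrays; tables with a zero marginal get NaN.
    """
    a = np.asarray(case_minor, dtype=float)
    b = np.asarray(case_major, dtype=float)
    c = np.asarray(control_minor, dtype=float)
    d = np.asarray(control_major, dtype=float)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, np.nan)
    p = stats.chi2.sf(stat, df=1)
    return stat, p


def chi2_allelic(
    case_alleles: Sequence[float], control_alleles: Sequence[float]
) -> AssocResult:
    """1-df Pearson chi-square on a 2x2 (minor, major) allele-count table.

    Parameters are (minor, major) count pairs for cases and controls.
    Raises :class:`DegenerateTableError` for a monomorphic marker.
    """
    a, b = case_alleles
    c, d = control_alleles
    if min(a, b, c, d) < 0:
        raise ValueError("allele counts must be non-negative")
    if (a + b) <= 0 or (c + d) <= 0 or (a + c) <= 0 or (b + d) <= 0:
        raise DegenerateTableError("degenerate table: zero marginal (monomorphic SNP)")
    stat, p = chi2_allelic_arrays(
        np.array([a]), np.array([b]), np.array([c]), np.array([d])
    )
    return AssocResult(statistic=float(stat[0]), df=1.0, p_value=float(p[0]))


def welch_ttest_arrays(
    x_mean, x_var, n_x, y_mean, y_var, n_y
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch two-sample t statistic, Welch-Satterthwaite df and two-sided p.

    Inputs are per-group sample means, unbiased variances and sizes
    (scalars or arrays). Zero combined variance yields stat 0, p 1.
    """
    x_mean = np.asarray(x_mean, dtype=float)
    y_mean = np.asarray(y_mean, dtype=float)
    vx = np.asarray(x_var, dtype=float) / n_x
    vy = np.asarray(y_var, dtype=float) / n_y
    se2 = vx + vy
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, (x_mean - y_mean) / np.sqrt(se2), 0.0)
        df = np.where(
            se2 > 0,
            se2**2 / (vx**2 / (n_x - 1) + vy**2 / (n_y - 1)),
            1.0,
        )
    p = np.where(se2 > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return t, df, p


def pool_ttest(
    case_pools: PoolFreqSet,
    control_pools: PoolFreqSet,
    equal_var: bool = False,
) -> AssocResult:
    """Two-sample t-test on per-pool allele-frequency estimates.

    Welch (unequal-variance) by default; ``equal_var=True`` selects the
    pooled-variance Student's t. Identical groups give stat 0, p 1.
    """
    x = np.asarray(case_pools.estimates, dtype=float)
    y = np.asarray(control_pools.estimates, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientPoolsError("insufficient pools: need >= 2 per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("degenerate variance: both groups have zero variance")
    if equal_var:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        df = float(len(x) + len(y) - 2)
        return AssocResult(statistic=float(t), df=df, p_value=float(p))
    t, df, p = welch_ttest_arrays(x.mean(), vx, len(x), y.mean(), vy, len(y))
    return AssocResult(statistic=float(t), df=float(df), p_value=float(p))


def filter_snps(
    snps: Sequence[SnpRecord],
    maf_min: float = 0.01,
    missing_max: float = 0.05,
) -> tuple[list[SnpRecord], list[Exclusion]]:
    """Apply marker QC: drop maf < maf_min or missing_rate > missing_max.

    Records lacking a QC field pass that filter by default (pre-filtered
    input tables carry p-values only); a single warning is logged when
    this happens. Returns (retained, exclusion log), input order preserved.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= missing_max <= 1.0):
        raise ValueError("missing_max must be in [0, 1]")
    retained: list[SnpRecord] = []
    excluded: list[Exclusion] = []
    n_unchecked = 0
    for rec in snps:
        reasons = []
        if rec.maf is not None and rec.maf < maf_min:
            reasons.append("maf")
        if rec.missing_rate is not None and rec.missing_rate > missing_max:
            reasons.append("missing_rate")
        if rec.maf is None and rec.missing_rate is None:
            n_unchecked += 1
        if reasons:
            excluded.append(Exclusion(rec.snp_id, "+".join(reasons)))
        else:
            retained.append(rec)
    if n_unchecked:
        logger.warning(
            "%d records lack QC fields; maf/missing filters skipped for them",
            n_unchecked,
        )
    return retained, excluded
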