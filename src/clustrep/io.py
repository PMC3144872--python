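"""Readers and writers for the pipeline's tabular formats.

Conventions: association tables are PLINK-style tab-separated files with
header columns CHR, SNP, BP, P (optional MAF, F_MISS); coordinates are
1-based closed in TSV reports and 0-based half-open in BED output; and
chromosome labels are normalized on ingest ("chr1" -> "1").
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotate import GeneModel, merge_transcripts
from .association import PoolFreqSet, SnpRecord, pool_ttest
from .overlap import OverlapRegion
from .scan import Region, chromosome_sort_key, normalize_chromosome
from .simulate import SyntheticTruth, TruthRegion

__all__ = [
    "read_assoc_table",
    "write_assoc_table",
    "read_genotype_count_table",
    "read_pool_table",
    "write_pool_table",
    "read_region_table",
    "write_region_table",
    "write_regions_bed",
    "write_overlap_table",
    "write_overlaps_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_models",
    "write_gene_models_bed12",
    "read_truth",
    "write_truth",
    "load_published_region_table",
]


class TableFormatError(ValueError):
    """Malformed input table; message carries file and line number."""


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", dtype={"CHR": str, "ch": str})


def read_assoc_table(path) -> list[SnpRecord]:
    """Read a per-SNP association table (CHR, SNP, BP, P [, MAF, F_MISS])."""
    df = _read_tsv(path)
    required = {"CHR", "SNP", "BP", "P"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    has_maf = "MAF" in df.columns
    has_miss = "F_MISS" in df.columns
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        try:
            records.append(
                SnpRecord(
                    chromosome=normalize_chromosome(getattr(row, "CHR")),
                    position=int(getattr(row, "BP")),
                    snp_id=str(getattr(row, "SNP")),
                    p_value=float(getattr(row, "P")),
                    maf=float(getattr(row, "MAF")) if has_maf and not pd.isna(getattr(row, "MAF")) else None,
                    missing_rate=float(getattr(row, "F_MISS")) if has_miss and not pd.isna(getattr(row, "F_MISS")) else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise TableFormatError(f"{path}:{line}: {exc}") from exc
    return records


def write_assoc_table(records: Sequence[SnpRecord], path) -> None:
    any_maf = any(r.maf is not None for r in records)
    any_miss = any(r.missing_rate is not None for r in records)
    cols = {
        "CHR": [r.chromosome for r in records],
        "SNP": [r.snp_id for r in records],
        "BP": [r.position for r in records],
        "P": [r.p_value for r in records],
    }
    if any_maf:
        cols["MAF"] = [r.maf for r in records]
    if any_miss:
        cols["F_MISS"] = [r.missing_rate for r in records]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_genotype_count_table(path) -> pd.DataFrame:
    """Allele-count table: CHR, SNP, BP, CASE_MINOR, CASE_MAJOR, CTRL_MINOR, CTRL_MAJOR."""
    df = _read_tsv(path)
    required = {"CHR", "SNP", "BP", "CASE_MINOR", "CASE_MAJOR", "CTRL_MINOR", "CTRL_MAJOR"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    df["CHR"] = df["CHR"].map(normalize_chromosome)
    return df


def read_pool_table(path) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Pool frequency table: CHR, SNP, BP, then CASE1..k and CTRL1..m columns.

    Returns (frame, case column names, control column names).
    """
    df = _read_tsv(path)
    case_cols = sorted(
        (c for c in df.columns if c.upper().startswith("CASE")),
        key=lambda c: int("".join(ch for ch in c if ch.isdigit()) or 0),
    )
    ctrl_cols = sorted(
        (c for c in df.columns if c.upper().startswith("CTRL")),
        key=lambda c: int("".join(ch for ch in c if ch.isdigit()) or 0),
    )
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise TableFormatError(f"{path}: need >= 2 CASE and >= 2 CTRL pool columns")
    for col in ("CHR", "SNP", "BP"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col}")
    df["CHR"] = df["CHR"].map(normalize_chromosome)
    return df, case_cols, ctrl_cols


def write_pool_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def pool_table_to_records(
    df: pd.DataFrame, case_cols: Sequence[str], ctrl_cols: Sequence[str],
    equal_var: bool = False,
) -> list[SnpRecord]:
    """Per-row pool t-tests, yielding SnpRecords with the resulting p-values."""
    records = []
    for row in df.itertuples(index=False):
        case = PoolFreqSet("case", tuple(getattr(row, c) for c in case_cols))
        ctrl = PoolFreqSet("control", tuple(getattr(row, c) for c in ctrl_cols))
        res = pool_ttest(case, ctrl, equal_var=equal_var)
        records.append(
            SnpRecord(
                chromosome=str(getattr(row, "CHR")),
                position=int(getattr(row, "BP")),
                snp_id=str(getattr(row, "SNP")),
                p_value=res.p_value,
            )
        )
    return records


_REGION_COLS = ["ch", "n_snps", "bp_start", "bp_end", "pmin_snp", "pmin", "members"]


def write_region_table(regions: Sequence[Region], path) -> None:
    """Per-sample cluster regions as TSV (1-based closed coordinates)."""
    pd.DataFrame(
        {
            "ch": [r.chromosome for r in regions],
            "n_snps": [r.n_snps for r in regions],
            "bp_start": [r.start for r in regions],
            "bp_end": [r.end for r in regions],
            "pmin_snp": [r.min_p_snp_id for r in regions],
            "pmin": [r.min_p for r in regions],
            "members": [",".join(r.member_snp_ids) for r in regions],
        }
    ).to_csv(path, sep="\t", index=False)


def read_region_table(path) -> list[Region]:
    df = _read_tsv(path)
    missing = set(_REGION_COLS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    regions = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            members = tuple(str(row.members).split(","))
            regions.append(
                Region(
                    chromosome=normalize_chromosome(row.ch),
                    start=int(row.bp_start),
                    end=int(row.bp_end),
                    member_snp_ids=members,
                    n_snps=int(row.n_snps),
                    min_p=float(row.pmin),
                    min_p_snp_id=str(row.pmin_snp),
                )
            )
        except (TypeError, ValueError) as exc:
            raise TableFormatError(f"{path}:{idx + 2}: {exc}") from exc
    return regions


def write_regions_bed(regions: Sequence[Region], path) -> None:
    """Regions as BED3+ (0-based half-open; score = -log10 min p)."""
    with open(path, "w") as fh:
        for r in regions:
            score = -math.log10(r.min_p) if r.min_p > 0 else 999.0
            fh.write(
                f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.min_p_snp_id}\t{score:.4f}\t{r.n_snps}\n"
            )


def write_overlap_table(overlaps: Sequence[OverlapRegion], path) -> None:
    """Cross-sample overlap report, one row per intersecting (A, B) pair."""
    rows = []
    for ov in overlaps:
        genes = ", ".join(sorted(ov.genes)) if ov.genes else ""
        for a in ov.source_a:
            for b in ov.source_b:
                if a.start > b.end or b.start > a.end:
                    continue
                rows.append(
                    {
                        "ch": ov.chromosome,
                        "a_n_snps": a.n_snps,
                        "a_start": a.start,
                        "a_end": a.end,
                        "a_pmin_snp": a.min_p_snp_id,
                        "a_pmin": a.min_p,
                        "b_n_snps": b.n_snps,
                        "b_start": b.start,
                        "b_end": b.end,
                        "b_pmin_snp": b.min_p_snp_id,
                        "b_pmin": b.min_p,
                        "genes": genes,
                    }
                )
    pd.DataFrame(
        rows,
        columns=[
            "ch", "a_n_snps", "a_start", "a_end", "a_pmin_snp", "a_pmin",
            "b_n_snps", "b_start", "b_end", "b_pmin_snp", "b_pmin", "genes",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_overlaps_bed(overlaps: Sequence[OverlapRegion], path) -> None:
    with open(path, "w") as fh:
        for ov in overlaps:
            name = ";".join(sorted(ov.genes)) if ov.genes else "."
            fh.write(f"{ov.chromosome}\t{ov.start - 1}\t{ov.end}\t{name}\n")


def read_chrom_sizes(path) -> dict:
    """Two-column TSV (chromosome, length) without header."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise TableFormatError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            sizes[normalize_chromosome(parts[0])] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes, key=chromosome_sort_key):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def _read_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise TableFormatError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(parts)}")
            try:
                chrom = normalize_chromosome(parts[0])
                start0, end0 = int(parts[1]), int(parts[2])
                name = parts[3]
                strand = parts[5] if parts[5] in ("+", "-") else "+"
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise TableFormatError(
                    f"{path}:{lineno}: block sizes/starts inconsistent with blockCount {n_blocks}"
                )
            exons = tuple(
                (start0 + off + 1, start0 + off + size)  # to 1-based closed
                for off, size in zip(offsets, sizes)
            )
            try:
                genes.append(
                    GeneModel(
                        symbol=name,
                        chromosome=chrom,
                        strand=strand,
                        tx_start=start0 + 1,
                        tx_end=end0,
                        exons=exons,
                    )
                )
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _read_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        symbol = (
            g.attributes.get("Name", g.attributes.get("gene_name", [g.id]))[0]
        )
        exons = sorted(
            (e.start, e.end)
            for e in db.children(g, featuretype="exon")
        )
        merged = []
        for s, e in exons:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        genes.append(
            GeneModel(
                symbol=symbol,
                chromosome=normalize_chromosome(g.seqid),
                strand=g.strand if g.strand in ("+", "-") else "+",
                tx_start=g.start,
                tx_end=g.end,
                exons=tuple(merged) if merged else ((g.start, g.end),),
            )
        )
    return genes


def read_gene_models(path, merge: bool = True) -> list[GeneModel]:
    """Gene models from BED12 or GFF3, optionally merged per symbol."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _read_gff3(path)
    else:
        genes = _read_bed12(path)
    return merge_transcripts(genes) if merge else genes


def write_gene_models_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start0 = g.tx_start - 1
            sizes = ",".join(str(e - s + 1) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, _ in g.exons)
            fh.write(
                f"{g.chromosome}\t{start0}\t{g.tx_end}\t{g.symbol}\t0\t{g.strand}"
                f"\t{start0}\t{g.tx_end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = [
        {
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "members_a": list(r.members_a),
            "members_b": list(r.members_b),
        }
        for r in truth.regions
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SyntheticTruth(
        regions=tuple(
            TruthRegion(
                chromosome=r["chromosome"],
                start=r["start"],
                end=r["end"],
                members_a=tuple(r["members_a"]),
                members_b=tuple(r["members_b"]),
            )
            for r in payload
        )
    )


def load_published_region_table(population: str) -> pd.DataFrame:
    """Bundled two-sample overlap region tables from published dual-platform
    addiction-dependence GWA comparisons.

    ``population`` is ``"european_american"`` or ``"african_american"``.
    Columns: ch, a_* (individually genotyped alcohol-dependence sample),
    b_* (pooled illegal-substance-dependence sample), genes.
    """
    valid = ("european_american", "african_american")
    if population not in valid:
        raise ValueError(f"population must be one of {valid}")
    ref = resources.files("clustrep.data") / f"regions_{population}.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype={"ch": str})
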