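"""Readers and writers for genotype tables, phenotype tables and result reports.

Genotype input is either a long-format delimited table
(``animal_id, locus, allele1, allele2``) or a minimal VCF 4.x file restricted
to biallelic SNPs with a GT field (one sample column per animal). Phenotype
input is a delimited test-day table with a documented header. Results are
written as TSV so a round-trip re-read equals the in-memory values at the
printed precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    GenotypeCall,
    Locus,
    TestDayRecord,
    ValidationError,
    check_unique_calls,
)

GENOTYPE_COLUMNS = ["animal_id", "locus", "allele1", "allele2"]
PHENOTYPE_COLUMNS = [
    "animal_id", "sire_id", "year_season", "parity", "dim",
    "milk_kg", "fat_pct", "protein_pct", "scc",
]
PHENOTYPE_OPTIONAL = ["milk305_kg", "fat305_kg", "protein305_kg"]


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, loci: Sequence[Locus]) -> list[GenotypeCall]:
    """Read genotype calls from a delimited table or a minimal VCF.

    Every call is validated against its :class:`Locus`; unknown loci, unknown
    allele codes and duplicate (animal, locus) pairs raise
    :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        calls = _read_vcf(path, loci)
    else:
        calls = _read_genotype_table(path, loci)
    check_unique_calls(calls)
    return calls


def _read_genotype_table(path: Path, loci: Sequence[Locus]) -> list[GenotypeCall]:
    by_name = {l.name: l for l in loci}
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, skipinitialspace=True)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing genotype columns {missing}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        locus = by_name.get(row.locus)
        if locus is None:
            raise ValidationError(f"{path} line {i}: unknown locus {row.locus!r}")
        call = GenotypeCall(str(row.animal_id), row.locus,
                            str(row.allele1).strip(), str(row.allele2).strip())
        try:
            call.validate(locus)
        except ValidationError as e:
            raise ValidationError(f"{path} line {i}: {e}") from None
        calls.append(call)
    return calls


def _read_vcf(path: Path, loci: Sequence[Locus]) -> list[GenotypeCall]:
    """Minimal VCF reader: biallelic SNP sites matched to loci by ID column."""
    by_name = {l.name: l for l in loci}
    calls: list[GenotypeCall] = []
    with open(path) as fh:
        samples: list[str] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if len(fields) < 10:
                raise ValidationError(f"{path} line {lineno}: no sample columns")
            _, _, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise ValidationError(f"{path} line {lineno}: multi-allelic site unsupported")
            if len(ref) != 1 or len(alt) != 1:
                raise ValidationError(f"{path} line {lineno}: not a SNP (REF={ref} ALT={alt})")
            locus = by_name.get(vid)
            if locus is None:
                raise ValidationError(f"{path} line {lineno}: unknown locus id {vid!r}")
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise ValidationError(f"{path} line {lineno}: no GT field") from None
            alleles = {0: ref, 1: alt}
            for sample, value in zip(samples, fields[9:]):
                gt = value.split(":")[gt_idx].replace("|", "/")
                if gt in (".", "./."):
                    continue  # missing genotype: animal excluded at this locus
                a, b = (alleles[int(x)] for x in gt.split("/"))
                call = GenotypeCall(sample, vid, a, b)
                call.validate(locus)
                calls.append(call)
    return calls


def write_genotypes(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(GENOTYPE_COLUMNS)
        for c in calls:
            w.writerow([c.animal_id, c.locus, c.allele1, c.allele2])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> list[TestDayRecord]:
    """Read test-day records; missing optional trait cells are allowed (NaN -> None)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing phenotype columns {missing}")
    records = []
    for i, row in df.iterrows():
        kwargs = {}
        for col in PHENOTYPE_OPTIONAL:
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        for col in ("animal_id", "sire_id", "year_season"):
            if pd.isna(row[col]):
                raise ValidationError(f"{path} row {i}: missing mandatory column {col!r}")
        try:
            rec = TestDayRecord(
                animal_id=str(row["animal_id"]),
                sire_id=str(row["sire_id"]),
                year_season=str(row["year_season"]),
                parity=int(row["parity"]),
                dim=int(row["dim"]),
                milk_kg=float(row["milk_kg"]),
                fat_pct=float(row["fat_pct"]),
                protein_pct=float(row["protein_pct"]),
                scc=float(row["scc"]),
                **kwargs,
            )
        except ValidationError as e:
            raise ValidationError(f"{path} row {i}: {e}") from None
        records.append(rec)
    return records


def write_phenotypes(records: Iterable[TestDayRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PHENOTYPE_COLUMNS + PHENOTYPE_OPTIONAL)
        for r in records:
            w.writerow([
                r.animal_id, r.sire_id, r.year_season, r.parity, r.dim,
                r.milk_kg, r.fat_pct, r.protein_pct, r.scc,
                "" if r.milk305_kg is None else r.milk305_kg,
                "" if r.fat305_kg is None else r.fat305_kg,
                "" if r.protein305_kg is None else r.protein305_kg,
            ])


def records_to_frame(records: Sequence[TestDayRecord]) -> pd.DataFrame:
    """Test-day records as a DataFrame (one row per record)."""
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(table: pd.DataFrame, path: str | Path, float_precision: int = 4) -> None:
    """Write a result table as TSV, floats rounded to a declared precision.

    Round-tripping through :func:`read_report` reproduces the values at that
    precision.
    """
    table.to_csv(path, sep="\t", index=False,
                 float_format=f"%.{float_precision}f")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_run_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=str) + "\n")
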