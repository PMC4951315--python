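"""Readers and writers for the genotype and score-model formats the pipeline touches.

Three genotype formats are supported:

* a native TSV dialect — one row per subject, columns ``subject_id``,
  ``status``, ``age``, then one column per SNP holding two-character genotype
  strings (missing = ``NN``). Human-editable; the intended fixture format.
* PLINK text ped/map pairs (phenotype 2 = case, 1 = control, 0/-9 missing).
* minimal VCF v4.x, read-only through cyvcf2: biallelic records, GT field
  only, phasing ignored. VCF carries no phenotype; attach it afterwards with
  :meth:`GenotypeTable.with_status`.

Allele orientation: files are allele-agnostic. The TSV and ped/map readers
count the lexicographically smaller of the two observed alleles unless the
file carries ``#allele`` header comments (which the writers always emit, so
write→read round-trips preserve dosages exactly). The VCF reader counts ALT.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeTable, ScoreModel, SnpModelEntry, ValidationError

__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "write_ped_map",
    "read_score_model",
    "write_score_model",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeTable:
    """Read a genotype file into a validated :class:`GenotypeTable`.

    Parameters
    ----------
    path:
        File path. For ``ped_map`` this may be the ``.ped`` file or the
        common prefix of the ``.ped``/``.map`` pair.
    format:
        One of ``tsv``, ``ped_map``, ``vcf``.
    """
    if format == "tsv":
        return _read_tsv(Path(path))
    if format == "ped_map":
        return _read_ped_map(Path(path))
    if format == "vcf":
        return _read_vcf(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------- native TSV

def _split_genotype(gt: str, rsid: str, lineno: int) -> tuple[str, str]:
    if len(gt) != 2:
        raise ParseError(
            f"line {lineno}: genotype {gt!r} for {rsid} is not two characters"
        )
    return gt[0], gt[1]


def _read_tsv(path: Path) -> GenotypeTable:
    allele_hints: dict[str, tuple[str, str]] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    linenos: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "allele" and len(parts) == 4:
                    allele_hints[parts[1]] = (parts[2], parts[3])
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"line {lineno}: {len(fields)} fields, header has {len(header)}"
                )
            rows.append(fields)
            linenos.append(lineno)
    if header is None or header[:2] != ["subject_id", "status"]:
        raise ParseError(f"{path}: expected header starting 'subject_id\\tstatus'")
    has_age = len(header) > 2 and header[2] == "age"
    first_snp = 3 if has_age else 2
    snp_ids = header[first_snp:]
    if not snp_ids:
        raise ParseError(f"{path}: no SNP columns")
    if not rows:
        raise ParseError(f"{path}: no subject rows")

    subject_ids, status, age = [], [], []
    geno = [[("N", "N")] * len(snp_ids) for _ in rows]
    na = {"", "NA", "na", ".", "nan"}
    for i, (fields, lineno) in enumerate(zip(rows, linenos)):
        subject_ids.append(fields[0])
        s = fields[1]
        if s in na:
            status.append(None)
        elif s in ("0", "1"):
            status.append(int(s))
        else:
            raise ParseError(f"line {lineno}: status {s!r} not 0/1/NA")
        if has_age:
            a = fields[2]
            age.append(math.nan if a in na else float(a))
        for j, rsid in enumerate(snp_ids):
            geno[i][j] = _split_genotype(fields[first_snp + j], rsid, lineno)

    any_status = any(s is not None for s in status)
    if any_status and any(s is None for s in status):
        raise ParseError(f"{path}: mixed present/missing status values")
    return _calls_to_table(
        subject_ids,
        snp_ids,
        geno,
        status=[int(s) for s in status] if any_status else None,
        age=age if has_age else None,
        allele_hints=allele_hints,
    )


def _calls_to_table(subject_ids, snp_ids, geno, *, status, age, allele_hints,
                    positions=None, chrom=None) -> GenotypeTable:
    """Turn per-subject allele-pair calls into a dosage table.

    ``geno[i][j]`` is a pair of single-character allele symbols; ``N``/``0``
    mark a missing half-call (both halves must be missing together).
    """
    n, m = len(subject_ids), len(snp_ids)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    counted, other = [], []
    for j, rsid in enumerate(snp_ids):
        observed: set[str] = set()
        for i in range(n):
            a, b = geno[i][j]
            miss = {a, b} & {"N", "0"}
            if miss:
                if len({a, b} - {"N", "0"}) != 0:
                    raise ParseError(
                        f"SNP {rsid}, subject {subject_ids[i]}: half-missing "
                        f"genotype {a}{b}"
                    )
                continue
            observed |= {a, b}
        if len(observed) > 2:
            raise ValidationError(
                f"SNP {rsid}: more than two alleles observed ({sorted(observed)})"
            )
        hint = allele_hints.get(rsid)
        if hint is not None:
            ca, oa = hint
            extra = observed - {ca, oa}
            if extra:
                raise ValidationError(
                    f"SNP {rsid}: allele(s) {sorted(extra)} not in declared pair "
                    f"{ca}/{oa}"
                )
        elif len(observed) == 2:
            ca, oa = sorted(observed)
        elif len(observed) == 1:
            ca = next(iter(observed))
            oa = "N" if ca != "N" else "?"
            # monomorphic with no hint: invent a placeholder other allele
            oa = next(c for c in "ACGTN" if c != ca)
        else:
            ca, oa = "A", "C"  # all-missing column
        counted.append(ca)
        other.append(oa)
        for i in range(n):
            a, b = geno[i][j]
            if a in ("N", "0"):
                continue
            dosage[i, j] = (a == ca) + (b == ca)
    return GenotypeTable(
        subject_ids=subject_ids,
        dosage=dosage,
        snp_ids=snp_ids,
        counted_allele=counted,
        other_allele=other,
        status=None if status is None else np.asarray(status),
        age=None if age is None else np.asarray(age, dtype=float),
        positions=positions,
        chrom=chrom,
    )


def write_genotypes_tsv(table: GenotypeTable, path: str | Path) -> None:
    """Write the native TSV dialect, with ``#allele`` headers for round-tripping."""
    path = Path(path)
    with open(path, "w") as fh:
        for j, rsid in enumerate(table.snp_ids):
            fh.write(
                f"#allele {rsid} {table.counted_allele[j]} {table.other_allele[j]}\n"
            )
        cols = ["subject_id", "status", "age"] + table.snp_ids
        fh.write("\t".join(cols) + "\n")
        for i, sid in enumerate(table.subject_ids):
            s = "NA" if table.status is None else str(int(table.status[i]))
            a = "NA"
            if table.age is not None and not math.isnan(table.age[i]):
                a = f"{table.age[i]:.1f}"
            gts = []
            for j in range(table.n_snps):
                g = table.dosage[i, j]
                if g == MISSING:
                    gts.append("NN")
                else:
                    ca, oa = table.counted_allele[j], table.other_allele[j]
                    gts.append(ca * int(g) + oa * (2 - int(g)))
            fh.write("\t".join([sid, s, a] + gts) + "\n")


# ----------------------------------------------------------------- ped / map

def _ped_map_paths(path: Path) -> tuple[Path, Path]:
    if path.suffix == ".ped":
        return path, path.with_suffix(".map")
    if path.suffix == ".map":
        return path.with_suffix(".ped"), path
    return path.with_suffix(".ped"), path.with_suffix(".map")


def _read_ped_map(path: Path) -> GenotypeTable:
    ped_path, map_path = _ped_map_paths(path)
    snp_ids, chrom, positions = [], [], []
    with open(map_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) not in (3, 4):
                raise ParseError(f"{map_path} line {lineno}: expected 3-4 columns")
            chrom.append(parts[0])
            snp_ids.append(parts[1])
            positions.append(int(parts[-1]))
    m = len(snp_ids)
    subject_ids, status, geno = [], [], []
    with open(ped_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path} line {lineno}: {len(parts)} fields, expected "
                    f"{6 + 2 * m} for {m} SNPs"
                )
            subject_ids.append(parts[1])
            pheno = parts[5]
            status.append({"2": 1, "1": 0}.get(pheno))
            geno.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
            )
    any_status = any(s is not None for s in status)
    if any_status and any(s is None for s in status):
        raise ParseError(f"{ped_path}: mixed present/missing phenotypes")
    return _calls_to_table(
        subject_ids,
        snp_ids,
        geno,
        status=[int(s) for s in status] if any_status else None,
        age=None,
        allele_hints={},
        positions=positions,
        chrom=chrom,
    )


def write_ped_map(table: GenotypeTable, prefix: str | Path) -> tuple[Path, Path]:
    """Write a PLINK text ped/map pair; returns the two paths."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for j, rsid in enumerate(table.snp_ids):
            c = table.chrom[j] if table.chrom else "1"
            pos = table.positions[j] if table.positions else j + 1
            fh.write(f"{c}\t{rsid}\t0\t{pos}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(table.subject_ids):
            pheno = "0"
            if table.status is not None:
                pheno = "2" if table.status[i] == 1 else "1"
            fields = [f"F{sid}", sid, "0", "0", "0", pheno]
            for j in range(table.n_snps):
                g = table.dosage[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    ca, oa = table.counted_allele[j], table.other_allele[j]
                    alleles = [ca] * int(g) + [oa] * (2 - int(g))
                    fields += alleles
            fh.write("\t".join(fields) + "\n")
    return ped_path, map_path


# ----------------------------------------------------------------------- VCF

def _read_vcf(path: Path) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    snp_ids, counted, other, positions, chrom, cols = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"{rec.ID or rec.POS}: multi-allelic records are not supported"
            )
        rsid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        alt_dose = np.full(len(subject_ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):  # [allele0, allele1, phased]
            a0, a1 = gt[0], gt[1]
            if a0 >= 0 and a1 >= 0:
                alt_dose[i] = (a0 == 1) + (a1 == 1)
        snp_ids.append(rsid)
        counted.append(rec.ALT[0])
        other.append(rec.REF)
        positions.append(rec.POS)
        chrom.append(rec.CHROM)
        cols.append(alt_dose)
    if not snp_ids:
        raise ParseError(f"{path}: no usable variant records")
    return GenotypeTable(
        subject_ids=subject_ids,
        dosage=np.column_stack(cols),
        snp_ids=snp_ids,
        counted_allele=counted,
        other_allele=other,
        positions=positions,
        chrom=chrom,
    )


# --------------------------------------------------------------- score model

_MODEL_COLS = ["rsid", "risk_allele", "allelic_or", "risk_allele_freq"]


def read_score_model(path: str | Path, ld_prune_r2: float = 0.5) -> ScoreModel:
    """Read a score-model TSV (columns rsid, risk_allele, allelic_or,
    risk_allele_freq, optional freq_source).

    ORs below 1 are rejected: panels must be oriented to risk alleles first
    (see :func:`snpscore.score.build_model`).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str})
    if df.empty:
        raise ValidationError(f"{path}: score model file has no rows")
    missing = [c for c in _MODEL_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df["rsid"].duplicated().any():
        dup = df.loc[df["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValidationError(f"{path}: duplicate rsid {dup}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            SnpModelEntry(
                rsid=row["rsid"],
                risk_allele=str(row["risk_allele"]),
                allelic_or=float(row["allelic_or"]),
                risk_allele_freq=float(row["risk_allele_freq"]),
                freq_source=str(row.get("freq_source", "external")),
            )
        )
    return ScoreModel(entries=tuple(entries), ld_prune_r2=ld_prune_r2)


def write_score_model(model: ScoreModel, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "rsid": [e.rsid for e in model],
            "risk_allele": [e.risk_allele for e in model],
            "allelic_or": [e.allelic_or for e in model],
            "risk_allele_freq": [e.risk_allele_freq for e in model],
            "freq_source": [e.freq_source for e in model],
        }
    )
    df.to_csv(path, sep="\t", index=False)
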