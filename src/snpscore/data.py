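"""Typed containers for genotype, phenotype and score-model data.

Genotypes are stored as allele *dosages*: for each SNP a counted allele is
fixed and each subject carries 0, 1 or 2 copies of it (``MISSING`` = -1 for
a failed call). Which allele is counted is a property of the container, not
of the analysis: association and scoring re-orient dosages in memory to the
minor or risk allele as needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeTable",
    "SnpModelEntry",
    "ScoreModel",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input container or file violates a structural invariant."""


def _as_str_list(x: Sequence) -> list[str]:
    return [str(v) for v in x]


@dataclass
class GenotypeTable:
    """Subjects x SNPs dosage matrix with case/control status and covariates.

    Parameters
    ----------
    subject_ids:
        Unique subject identifiers, length n.
    dosage:
        (n, m) int8 array; entries in {0, 1, 2, MISSING}. Entry [i, j] is the
        number of copies of ``counted_allele[j]`` carried by subject i.
    snp_ids:
        rsIDs, length m.
    counted_allele, other_allele:
        Per-SNP base symbols; the dosage counts the former.
    status:
        Per-subject 1 = case, 0 = control; ``None`` for population samples
        without phenotype (e.g. simulated general-population draws or VCF
        input before a phenotype is attached).
    age:
        Per-subject age in years (float, NaN allowed) or ``None``.
    positions:
        Optional per-SNP 1-based coordinates, carried as opaque metadata.
    """

    subject_ids: list[str]
    dosage: np.ndarray
    snp_ids: list[str]
    counted_allele: list[str]
    other_allele: list[str]
    status: np.ndarray | None = None
    age: np.ndarray | None = None
    positions: list[int] | None = None
    chrom: list[str] | None = None

    def __post_init__(self) -> None:
        self.subject_ids = _as_str_list(self.subject_ids)
        self.snp_ids = _as_str_list(self.snp_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValidationError("dosage must be a 2-D subjects x SNPs array")
        n, m = self.dosage.shape
        if len(self.subject_ids) != n:
            raise ValidationError(
                f"{len(self.subject_ids)} subject ids for {n} dosage rows"
            )
        for name, lst in (
            ("snp_ids", self.snp_ids),
            ("counted_allele", self.counted_allele),
            ("other_allele", self.other_allele),
        ):
            if len(lst) != m:
                raise ValidationError(f"{name} has length {len(lst)}, expected {m}")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage[{i},{j}] = {self.dosage[i, j]} not in {{0,1,2,{MISSING}}}"
            )
        for j, (a, b) in enumerate(zip(self.counted_allele, self.other_allele)):
            if a == b:
                raise ValidationError(
                    f"SNP {self.snp_ids[j]}: counted and other allele are both {a!r}"
                )
        if len(set(self.snp_ids)) != m:
            raise ValidationError("duplicate SNP ids")
        if self.status is not None:
            self.status = np.asarray(self.status, dtype=np.int8)
            if self.status.shape != (n,):
                raise ValidationError("status length does not match subjects")
            if not np.isin(self.status, (0, 1)).all():
                raise ValidationError("status values must be 0 (control) or 1 (case)")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if self.age.shape != (n,):
                raise ValidationError("age length does not match subjects")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def snp_index(self, rsid: str) -> int:
        try:
            return self.snp_ids.index(rsid)
        except ValueError:
            raise KeyError(f"SNP {rsid!r} not in table") from None

    def dosage_of(self, rsid: str, allele: str | None = None) -> np.ndarray:
        """Dosage column for one SNP, optionally re-oriented to ``allele``.

        Missing calls stay ``MISSING`` whichever allele is counted.
        """
        j = self.snp_index(rsid)
        g = self.dosage[:, j].astype(np.int8)
        if allele is None or allele == self.counted_allele[j]:
            return g.copy()
        if allele == self.other_allele[j]:
            flipped = (2 - g).astype(np.int8)
            flipped[g == MISSING] = MISSING
            return flipped
        raise ValidationError(
            f"SNP {rsid}: allele {allele!r} is neither "
            f"{self.counted_allele[j]!r} nor {self.other_allele[j]!r}"
        )

    def with_status(self, status: Sequence[int], age: Sequence[float] | None = None
                    ) -> "GenotypeTable":
        """Return a copy with phenotype (and optionally age) attached."""
        return replace(
            self,
            status=np.asarray(status, dtype=np.int8),
            age=None if age is None else np.asarray(age, dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosage matrix as a DataFrame (subjects as index, rsIDs as columns)."""
        df = pd.DataFrame(self.dosage, index=self.subject_ids, columns=self.snp_ids)
        return df.replace(MISSING, pd.NA)


@dataclass(frozen=True)
class SnpModelEntry:
    """One scored SNP: risk allele, per-allele OR and population frequency.

    ``allelic_or`` must be >= 1: protective alleles are re-oriented (OR
    inverted, alleles swapped) before a model is built, mirroring how risk
    panels are conventionally reported.
    """

    rsid: str
    risk_allele: str
    allelic_or: float
    risk_allele_freq: float
    freq_source: str = "external"  # "controls" | "external"

    def __post_init__(self) -> None:
        if not self.allelic_or > 0:
            raise ValidationError(f"{self.rsid}: allelic OR must be positive")
        if self.allelic_or < 1.0:
            raise ValidationError(
                f"{self.rsid}: allelic OR {self.allelic_or} < 1; re-orient to the "
                "risk allele first (invert the OR and swap alleles, e.g. via "
                "build_model)"
            )
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValidationError(
                f"{self.rsid}: risk-allele frequency {self.risk_allele_freq} "
                "outside (0, 1)"
            )
        if self.freq_source not in ("controls", "external"):
            raise ValidationError(
                f"{self.rsid}: freq_source must be 'controls' or 'external'"
            )


@dataclass(frozen=True)
class ScoreModel:
    """An ordered panel of scored SNPs plus the LD-pruning threshold it honours."""

    entries: tuple[SnpModelEntry, ...]
    ld_prune_r2: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ValidationError("score model has no SNPs")
        rsids = [e.rsid for e in self.entries]
        if len(set(rsids)) != len(rsids):
            raise ValidationError("duplicate rsid in score model")
        if not 0.0 <= self.ld_prune_r2 <= 1.0:
            raise ValidationError("ld_prune_r2 outside [0, 1]")

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)
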