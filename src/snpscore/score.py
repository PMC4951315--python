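"""OR-weighted, population-normalized multiplicative genetic scores.

The score expresses each subject's risk *relative to the population average*.
For a SNP with per-allele odds ratio ``OR`` and risk-allele frequency ``p``:

* genotypic OR for ``g`` copies of the risk allele is ``OR**g``
  (multiplicative / log-additive model);
* the population-average genotypic OR under Hardy-Weinberg proportions is
  ``p²·OR² + 2p(1−p)·OR + (1−p)²``;
* the SNP's relative-risk factor is the ratio of the two, so its
  HWE-weighted mean over genotypes is exactly 1.

A subject's genetic score is the product of these factors over the panel's
SNPs. By construction the score averages 1 in a population at the model's
frequencies, so 0.8 reads as "below average inherited risk" and 1.2 as
"above average" without reference to disease prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeTable, ScoreModel, SnpModelEntry, ValidationError

__all__ = [
    "ScoreResult",
    "genotypic_or",
    "population_average_risk",
    "snp_relative_risk",
    "genetic_score",
    "score_table",
    "build_model",
]


@dataclass(frozen=True)
class ScoreResult:
    """One subject's genetic score and its per-SNP relative-risk factors."""

    subject_id: str
    score: float
    factors: dict[str, float]
    n_missing: int


def genotypic_or(allelic_or: float, g: int) -> float:
    """OR**g: the genotype-level OR under the multiplicative allelic model.

    Carrying two risk alleles gives OR², one gives OR, none gives 1.
    """
    if not allelic_or > 0:
        raise ValueError("allelic OR must be positive")
    if g not in (0, 1, 2):
        raise ValueError(f"dosage {g!r} not in {{0, 1, 2}}")
    return float(allelic_or) ** g


def population_average_risk(allelic_or: float, p: float) -> float:
    """HWE-genotype-frequency-weighted mean genotypic OR.

    ``p²·OR² + 2p(1−p)·OR + (1−p)²`` — the average risk level of a population
    with risk-allele frequency ``p`` under Hardy-Weinberg proportions,
    relative to non-carriers.
    """
    if not allelic_or > 0:
        raise ValueError("allelic OR must be positive")
    if not 0.0 < p < 1.0:
        raise ValueError("risk-allele frequency must lie strictly in (0, 1)")
    q = 1.0 - p
    return p * p * allelic_or * allelic_or + 2.0 * p * q * allelic_or + q * q


def snp_relative_risk(allelic_or: float, p: float, g: int) -> float:
    """One SNP's relative-risk factor: genotypic OR over the population mean."""
    return genotypic_or(allelic_or, g) / population_average_risk(allelic_or, p)


def genetic_score(
    dosages: Mapping[str, int], model: ScoreModel
) -> tuple[float, dict[str, float], int]:
    """Multiply per-SNP relative risks into one subject's genetic score.

    ``dosages`` maps rsid -> risk-allele dosage (0/1/2, ``MISSING`` allowed).
    A missing genotype contributes a neutral factor of 1 (the population-
    average risk) and is counted in ``n_missing``; a subject missing every
    model SNP has no defined score and raises.

    Returns ``(score, factors, n_missing)``.
    """
    factors: dict[str, float] = {}
    n_missing = 0
    for entry in model:
        try:
            g = dosages[entry.rsid]
        except KeyError:
            raise ValidationError(
                f"dosage for model SNP {entry.rsid} not supplied"
            ) from None
        if g == MISSING:
            factors[entry.rsid] = 1.0
            n_missing += 1
        else:
            factors[entry.rsid] = snp_relative_risk(
                entry.allelic_or, entry.risk_allele_freq, int(g)
            )
    if n_missing == len(model):
        raise ValidationError("all model SNPs missing; score undefined")
    score = float(np.prod(list(factors.values())))
    return score, factors, n_missing


def score_table(table: GenotypeTable, model: ScoreModel) -> pd.DataFrame:
    """Score every subject in a genotype table against a model.

    Dosages are re-oriented in memory to each entry's risk allele. Returns a
    DataFrame with subject_id, status (if present), score, n_missing, and one
    ``factor_<rsid>`` column per SNP.
    """
    missing_snps = [e.rsid for e in model if e.rsid not in table.snp_ids]
    if missing_snps:
        raise ValidationError(
            f"model SNP(s) absent from genotype data: {', '.join(missing_snps)}"
        )
    oriented = {e.rsid: table.dosage_of(e.rsid, e.risk_allele) for e in model}
    records = []
    for i, sid in enumerate(table.subject_ids):
        dosages = {rsid: int(col[i]) for rsid, col in oriented.items()}
        s, factors, n_miss = genetic_score(dosages, model)
        rec = {"subject_id": sid, "score": s, "n_missing": n_miss}
        if table.status is not None:
            rec["status"] = int(table.status[i])
        if table.age is not None:
            rec["age"] = float(table.age[i])
        for rsid, f in factors.items():
            rec[f"factor_{rsid}"] = f
        records.append(rec)
    df = pd.DataFrame(records)
    front = [c for c in ("subject_id", "status", "age", "score", "n_missing")
             if c in df.columns]
    return df[front + [c for c in df.columns if c not in front]]


def build_model(
    candidates: Iterable[tuple[str, str, str, float]],
    freqs: Mapping[str, float],
    ld: Mapping[frozenset, float] | None = None,
    ld_threshold: float = 0.5,
    *,
    pvalues: Mapping[str, float] | None = None,
    keep: Sequence[str] = (),
    freq_source: str = "external",
) -> ScoreModel:
    """Assemble an LD-pruned, risk-oriented score model.

    Parameters
    ----------
    candidates:
        Tuples ``(rsid, allele, other_allele, or_)`` — the reported effect
        allele, its partner, and the reported per-allele OR. Protective
        entries (OR < 1) are re-oriented: the OR is inverted and the risk
        allele becomes the other allele, so every model entry has OR >= 1.
    freqs:
        rsid -> frequency of the *reported* allele (flipped to 1-p on
        re-orientation).
    ld:
        Pairwise r² keyed by ``frozenset({rsid_a, rsid_b})``. Of any pair at
        or above ``ld_threshold`` only one SNP is retained: one named in
        ``keep`` if given, else the one with the smaller association p-value
        in ``pvalues``, else an error lists the unresolved pair.
    """
    entries = []
    for rsid, allele, other, or_ in candidates:
        if not or_ > 0:
            raise ValidationError(f"{rsid}: OR must be positive")
        p = freqs[rsid]
        if or_ < 1.0:
            or_, allele, p = 1.0 / or_, other, 1.0 - p
        entries.append(
            SnpModelEntry(
                rsid=rsid,
                risk_allele=allele,
                allelic_or=float(or_),
                risk_allele_freq=float(p),
                freq_source=freq_source,
            )
        )

    if ld:
        drop: set[str] = set()
        present = {e.rsid for e in entries}
        for pair, r2 in ld.items():
            a, b = sorted(pair)
            if r2 < ld_threshold or a not in present or b not in present:
                continue
            if a in drop or b in drop:
                continue
            if a in keep and b not in keep:
                drop.add(b)
            elif b in keep and a not in keep:
                drop.add(a)
            elif pvalues is not None and a in pvalues and b in pvalues:
                drop.add(a if pvalues[a] > pvalues[b] else b)
            else:
                raise ValidationError(
                    f"SNPs {a} and {b} are in LD (r²={r2:.2f} >= "
                    f"{ld_threshold}); designate which to keep"
                )
        entries = [e for e in entries if e.rsid not in drop]

    return ScoreModel(entries=tuple(entries), ld_prune_r2=ld_threshold)
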