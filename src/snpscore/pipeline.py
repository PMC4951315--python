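"""End-to-end stage runners: association screen, scoring, stratified report.

These functions tie the library stages together, add provenance headers to
every output TSV (config echo, seed, version) and are what the command-line
interface calls. Outputs are plain TSV for diffability.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    association_scan,
    bonferroni_alpha,
    group_compare,
    score_case_logistic,
)
from .data import GenotypeTable, ScoreModel
from .roc import roc_analysis
from .score import score_table
from .stratify import (
    assign_strata_fixed,
    assign_strata_quantile,
    cochran_armitage_trend,
    stratum_likelihood,
    stratum_or,
)

__all__ = ["PipelineConfig", "run_assoc", "run_score", "run_report"]


@dataclass
class PipelineConfig:
    """Analysis choices; defaults follow the conventional score workflow."""

    cutpoints: tuple[float, ...] = (0.8, 1.2)
    quantile_k: int = 4
    ld_prune_r2: float = 0.5
    alpha: float = 0.05
    freq_source: str = "external"
    ci_method: str = "delong"
    seed: int = 0

    def echo(self) -> str:
        return (
            f"cutpoints={','.join(map(str, self.cutpoints))} "
            f"quantile_k={self.quantile_k} ld_prune_r2={self.ld_prune_r2} "
            f"alpha={self.alpha} freq_source={self.freq_source} "
            f"ci_method={self.ci_method} seed={self.seed}"
        )


def _write_tsv(df: pd.DataFrame, path: str | Path, config: PipelineConfig,
               extra: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# snpscore {__version__}\n# {config.echo()}\n")
        for line in extra or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_assoc(table: GenotypeTable, config: PipelineConfig | None = None,
              out: str | Path | None = None) -> pd.DataFrame:
    """Per-SNP association screen with Bonferroni flagging (TSV optional)."""
    config = config or PipelineConfig()
    df = association_scan(table, alpha=config.alpha)
    threshold = df.attrs["bonferroni_threshold"]
    if out is not None:
        _write_tsv(df, out, config,
                   extra=[f"bonferroni_threshold={threshold:.6g}"])
    return df


def run_score(table: GenotypeTable, model: ScoreModel,
              config: PipelineConfig | None = None,
              out: str | Path | None = None) -> pd.DataFrame:
    """Score every subject; TSV gains per-group median/quartile summary lines."""
    config = config or PipelineConfig()
    df = score_table(table, model)
    extra = []
    if "status" in df.columns:
        for grp, name in ((1, "case"), (0, "control")):
            s = df.loc[df["status"] == grp, "score"]
            if len(s):
                q1, med, q3 = s.quantile([0.25, 0.5, 0.75])
                extra.append(
                    f"{name}_median={med:.4g} quartiles=({q1:.4g},{q3:.4g}) "
                    f"n={len(s)}"
                )
    if out is not None:
        _write_tsv(df, out, config, extra=extra)
    return df


def run_report(scores: pd.DataFrame, config: PipelineConfig | None = None,
               out_dir: str | Path | None = None) -> dict:
    """Stratified likelihoods (fixed cutpoints and quantiles), trend tests,
    between-extreme-stratum ORs and ROC/AUC for a scored cohort.

    ``scores`` needs ``score`` and ``status`` columns (from run_score).
    Returns a dict of results; writes strata and ROC TSVs when ``out_dir``
    is given. Empty strata are flagged in the tables and the pipeline
    continues.
    """
    config = config or PipelineConfig()
    if "status" not in scores.columns:
        raise ValueError("scored table has no status column")
    s = scores["score"].to_numpy(dtype=float)
    y = scores["status"].to_numpy(dtype=int)
    results: dict = {}

    cut = config.cutpoints
    fixed = assign_strata_fixed(s, cut)
    labels = (
        [f"<{cut[0]}"]
        + [f"[{a},{b})" for a, b in zip(cut[:-1], cut[1:])]
        + [f">={cut[-1]}"]
    )
    bounds = (
        [(-np.inf, cut[0])]
        + list(zip(cut[:-1], cut[1:]))
        + [(cut[-1], np.inf)]
    )
    tab_fixed = stratum_likelihood(fixed, y, labels=labels, bounds=bounds,
                                   k=len(cut) + 1)
    counts = np.column_stack([tab_fixed.n_case, tab_fixed.n_control])
    nonempty = counts.sum(axis=1) > 0
    chi2, p = cochran_armitage_trend(counts[nonempty])
    tab_fixed.chi2_trend, tab_fixed.p_trend = chi2, p
    or_extreme, corrected = stratum_or(
        counts, ref=0, target=len(labels) - 1
    )
    results["fixed"] = tab_fixed
    results["fixed_or_high_vs_low"] = or_extreme
    results["fixed_or_corrected"] = corrected

    k = config.quantile_k
    quart = assign_strata_quantile(s, k=k)
    qlabels = [f"Q{i + 1}" for i in range(k)]
    tab_q = stratum_likelihood(quart, y, labels=qlabels, k=k)
    qcounts = np.column_stack([tab_q.n_case, tab_q.n_control])
    qne = qcounts.sum(axis=1) > 0
    chi2q, pq = cochran_armitage_trend(qcounts[qne])
    tab_q.chi2_trend, tab_q.p_trend = chi2q, pq
    results["quantile"] = tab_q
    results["quantile_or_high_vs_low"], _ = stratum_or(qcounts, 0, k - 1)

    roc = roc_analysis(s, y, ci_method=config.ci_method)
    results["roc"] = roc

    mw = group_compare(s[y == 1], s[y == 0], method="mann_whitney",
                       variable="score")
    results["score_comparison"] = mw
    if "age" in scores.columns and scores["age"].notna().any():
        adj = score_case_logistic(s, y, scores["age"].to_numpy(dtype=float))
        results["score_comparison_age_adjusted"] = adj

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_tsv(
            tab_fixed.to_frame(), out_dir / "strata_fixed.tsv", config,
            extra=[
                f"trend chi2={chi2:.4g} p={p:.4g}",
                f"or_high_vs_low={or_extreme:.4g}",
            ],
        )
        _write_tsv(
            tab_q.to_frame(), out_dir / "strata_quantile.tsv", config,
            extra=[f"trend chi2={chi2q:.4g} p={pq:.4g}"],
        )
        curve = pd.DataFrame(roc.curve, columns=["fpr", "tpr"])
        _write_tsv(
            curve, out_dir / "roc_points.tsv", config,
            extra=[f"AUC={roc.auc:.4f} [{roc.ci_low:.4f}, {roc.ci_high:.4f}] "
                   f"({roc.ci_method})"],
        )
    return results
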