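"""Per-condition target summaries, RBP–target correlations and the
four-way classification of regulatory relationships.

For each RNA-binding protein the pipeline computes, per condition, the
mean, SD and CD (coefficient of deviation, SD/mean) of its targets' log
expression, correlates each summary with the RBP's own log expression
across conditions, and labels the RBP by the signs of the mean- and
CD-correlations. The class with rho_mean > 0 and rho_cd < 0 — co-expressed
with its targets while reducing their variation — is the buffering mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import Correlation, correlation
from .expression import ExpressionMatrix, TargetMap

log = logging.getLogger(__name__)

#: |mean| below this flags the CD as undefined for that (RBP, condition).
CD_MEAN_GUARD = 1e-8

REGIONS = (
    "pos_mean_pos_cd",
    "pos_mean_neg_cd",
    "neg_mean_pos_cd",
    "neg_mean_neg_cd",
)

#: the buffering class: co-expressed with targets, damping their variation.
BUFFERING_REGION = "pos_mean_neg_cd"


@dataclass(frozen=True)
class CorrelationResult:
    rbp_id: str
    statistic_name: str  # mean | sd | cd
    rho: float
    p_value: float
    method: str
    n_conditions: int
    degenerate: bool = False


@dataclass(frozen=True)
class RbpClassification:
    rbp_id: str
    region: str
    rho_mean: float
    rho_cd: float
    degenerate: bool = False


def summarize_targets(m: ExpressionMatrix, tm: TargetMap) -> pd.DataFrame:
    """One row per (RBP, condition): RBP log expression plus the mean, SD
    and CD of its targets' log expression in that condition.

    SD uses the sample (n-1) denominator. Targets missing from the matrix
    are dropped with a warning; an RBP with fewer than two surviving targets
    is excluded. Rows whose |mean| falls under ``CD_MEAN_GUARD`` get
    ``cd_defined=False`` and are excluded from CD correlations downstream.
    """
    if m.scale != "log":
        raise ValueError("summarize_targets requires a log-scale matrix")
    index = {g: i for i, g in enumerate(m.gene_ids)}
    rows = []
    for rbp in tm.regulators:
        if rbp not in index:
            raise KeyError(f"RBP {rbp!r} has no expression row")
        targets = [t for t in tm.targets_of(rbp) if t != rbp]
        missing = [t for t in targets if t not in index]
        if missing:
            log.warning("%s: dropping %d target(s) absent from matrix", rbp, len(missing))
        surviving = [t for t in targets if t in index]
        if len(surviving) < 2:
            warnings.warn(f"RBP {rbp!r} has < 2 targets with expression; excluded")
            continue
        sub = m.values[[index[t] for t in surviving]]  # targets x conditions
        rbp_expr = m.values[index[rbp]]
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=1)
        defined = np.abs(means) >= CD_MEAN_GUARD
        cds = np.where(defined, sds / np.where(defined, means, 1.0), np.nan)
        for c, cond in enumerate(m.condition_ids):
            rows.append(
                (rbp, cond, rbp_expr[c], means[c], sds[c], cds[c],
                 len(surviving), bool(defined[c]))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "rbp_id", "condition_id", "rbp_expr", "target_mean",
            "target_sd", "target_cd", "n_targets", "cd_defined",
        ],
    )


def correlate_rbp(
    summaries: pd.DataFrame, statistic: str, method: str = "spearman"
) -> CorrelationResult:
    """Correlate one RBP's expression with a target summary statistic
    across conditions (two-sided p)."""
    if statistic not in ("mean", "sd", "cd"):
        raise ValueError(f"statistic must be mean|sd|cd, got {statistic!r}")
    rbps = summaries["rbp_id"].unique()
    if len(rbps) != 1:
        raise ValueError("correlate_rbp expects summaries for exactly one RBP")
    sub = summaries
    if statistic == "cd":
        sub = summaries[summaries["cd_defined"]]
    x = sub["rbp_expr"].to_numpy()
    y = sub[f"target_{statistic}"].to_numpy()
    if len(x) < 3:
        raise ValueError(f"{rbps[0]}: need >= 3 conditions, have {len(x)}")
    c: Correlation = correlation(x, y, method=method)
    return CorrelationResult(
        rbp_id=str(rbps[0]),
        statistic_name=statistic,
        rho=c.rho,
        p_value=c.p_value,
        method=c.method,
        n_conditions=c.n,
        degenerate=c.degenerate,
    )


def correlate_all(
    summaries: pd.DataFrame,
    statistics: tuple[str, ...] = ("mean", "sd", "cd"),
    method: str = "spearman",
) -> pd.DataFrame:
    """correlate_rbp for every RBP and statistic, as a tidy frame."""
    results = []
    for rbp, grp in summaries.groupby("rbp_id", sort=True):
        for stat in statistics:
            r = correlate_rbp(grp, stat, method=method)
            results.append(r.__dict__)
    return pd.DataFrame(results)


def region_from_signs(rho_mean: float, rho_cd: float) -> tuple[str, bool]:
    """Four-way region label from the signs of the two correlations.

    Zero rho is a measure-zero tie broken deterministically (zero mean-rho
    counts as positive, zero CD-rho as negative) and flagged degenerate.
    """
    degenerate = rho_mean == 0.0 or rho_cd == 0.0
    mean_part = "pos_mean" if rho_mean >= 0.0 else "neg_mean"
    cd_part = "pos_cd" if rho_cd > 0.0 else "neg_cd"
    return f"{mean_part}_{cd_part}", degenerate


def classify_rbps(
    correlations: pd.DataFrame,
) -> tuple[list[RbpClassification], float]:
    """Assign each RBP a region from its mean- and CD-correlation signs and
    return the fraction falling in the buffering class."""
    out: list[RbpClassification] = []
    for rbp, grp in correlations.groupby("rbp_id", sort=True):
        by_stat = grp.set_index("statistic_name")
        if "mean" not in by_stat.index or "cd" not in by_stat.index:
            raise ValueError(f"{rbp}: need both a mean and a cd correlation")
        rho_mean = float(by_stat.loc["mean", "rho"])
        rho_cd = float(by_stat.loc["cd", "rho"])
        flagged = bool(
            by_stat.loc["mean", "degenerate"] or by_stat.loc["cd", "degenerate"]
        )
        region, tie = region_from_signs(rho_mean, rho_cd)
        out.append(
            RbpClassification(str(rbp), region, rho_mean, rho_cd, flagged or tie)
        )
    if not out:
        return out, float("nan")
    frac = sum(c.region == BUFFERING_REGION for c in out) / len(out)
    return out, frac


def coexpression_pipeline(
    matrix: ExpressionMatrix,
    tm: TargetMap,
    method: str = "spearman",
) -> dict:
    """summaries → correlations → classifications in one call.

    ``matrix`` must already be log-scale; apply ``log_transform`` first for
    raw RPKM input.
    """
    summaries = summarize_targets(matrix, tm)
    correlations = correlate_all(summaries, method=method)
    classifications, fraction_buffering = classify_rbps(correlations)
    return {
        "summaries": summaries,
        "correlations": correlations,
        "classifications": pd.DataFrame([c.__dict__ for c in classifications]),
        "fraction_buffering": fraction_buffering,
    }
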