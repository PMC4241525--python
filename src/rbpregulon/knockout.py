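"""Wild-type vs RBP-deletion comparison among the RBP's targets.

The deletion strain approximates target expression before the RBP acts;
the wild type, expression after. Per-target degradation efficiency is the
fraction of deletion-strain expression lost in the wild type, correlated
against expression level in the deletion strain; the CD comparison asks
whether losing the RBP raises the expression variation among its targets,
tested with a variance-ratio F-test on log expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import coefficient_of_deviation, correlation, variance_ratio_test
from .coexpression import CorrelationResult

log = logging.getLogger(__name__)


@dataclass
class KnockoutPair:
    """Paired WT / deletion-strain expression profiles (raw RPKM) with the
    regulator's target list."""

    gene_ids: list[str]
    wt_expr: np.ndarray
    ko_expr: np.ndarray
    rbp_id: str = "RBP"
    target_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wt_expr = np.asarray(self.wt_expr, dtype=float)
        self.ko_expr = np.asarray(self.ko_expr, dtype=float)
        n = len(self.gene_ids)
        if self.wt_expr.shape != (n,) or self.ko_expr.shape != (n,):
            raise ValueError("wt_expr and ko_expr must align with gene_ids")
        if (self.wt_expr < 0).any() or (self.ko_expr < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.target_ids:
            self.target_ids = list(self.gene_ids)

    def target_arrays(self, pseudocount: float = 0.0) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(wt, ko) restricted to targets present in the profiles."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        present = [t for t in self.target_ids if t in index]
        dropped = len(self.target_ids) - len(present)
        if dropped:
            log.warning("%s: %d target(s) absent from profiles, dropped",
                        self.rbp_id, dropped)
        idx = [index[t] for t in present]
        return (self.wt_expr[idx] + pseudocount,
                self.ko_expr[idx] + pseudocount, present)


def degradation_efficiency(
    pair: KnockoutPair, pseudocount: float = 0.0, log_base: float = 2.0
) -> pd.DataFrame:
    """Per-target efficiency = (KO - WT) / KO on raw RPKM, with KO-strain
    log expression for plotting/correlation.

    Efficiency is <= 1 by construction; negative values mean the gene is
    up-regulated in the WT and are retained (flagged ``upregulated``) —
    flooring them at zero would bias the efficiency-expression correlation.
    """
    wt, ko, present = pair.target_arrays(pseudocount)
    if (ko <= 0).any():
        raise ValueError(
            "KO expression + pseudocount must be positive; "
            "use a positive pseudocount for zero-RPKM targets"
        )
    eff = (ko - wt) / ko
    ko_level = np.log(ko) / math.log(log_base)
    return pd.DataFrame(
        {
            "gene_id": present,
            "efficiency": eff,
            "ko_level": ko_level,
            "upregulated": eff < 0,
        }
    )


def efficiency_vs_expression(
    records: pd.DataFrame, method: str = "spearman"
) -> CorrelationResult:
    """Correlation of degradation efficiency with KO-strain log expression."""
    if len(records) < 3:
        raise ValueError("need >= 3 degradation records")
    c = correlation(
        records["efficiency"].to_numpy(), records["ko_level"].to_numpy(),
        method=method,
    )
    return CorrelationResult(
        rbp_id="efficiency_vs_ko_level",
        statistic_name="efficiency",
        rho=c.rho,
        p_value=c.p_value,
        method=c.method,
        n_conditions=c.n,
        degenerate=c.degenerate,
    )


def cd_comparison(
    pair: KnockoutPair, log_base: float = 2.0, pseudocount: float = 0.0
) -> dict:
    """CD of target log expression in each strain plus a variance-ratio test.

    F = var(KO targets) / var(WT targets) on log expression, with a
    two-sided p from F(n-1, n-1). F > 1 with small p says variation among
    targets is higher without the RBP.
    """
    wt, ko, present = pair.target_arrays(pseudocount)
    n = len(present)
    if n < 3:
        raise ValueError("need >= 3 targets present in both profiles")
    if (wt <= 0).any() or (ko <= 0).any():
        raise ValueError("log transform needs positive values; add a pseudocount")
    log_wt = np.log(wt) / math.log(log_base)
    log_ko = np.log(ko) / math.log(log_base)
    f_stat, p = variance_ratio_test(log_ko, log_wt)
    return {
        "cd_wt": coefficient_of_deviation(log_wt),
        "cd_ko": coefficient_of_deviation(log_ko),
        "f_statistic": f_stat,
        "p_value": p,
        "n_targets": n,
        "n_upregulated": int((wt > ko).sum()),
    }


def knockout_pipeline(
    pair: KnockoutPair,
    pseudocount: float = 0.0,
    log_base: float = 2.0,
    method: str = "spearman",
) -> dict:
    """Degradation records, efficiency-expression correlation and the CD
    comparison in one call."""
    records = degradation_efficiency(pair, pseudocount, log_base)
    corr = efficiency_vs_expression(records, method=method)
    cds = cd_comparison(pair, log_base=log_base, pseudocount=pseudocount)
    return {
        "records": records,
        "rho": corr.rho,
        "p": corr.p_value,
        "n_upregulated": int(records["upregulated"].sum()),
        **cds,
    }
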