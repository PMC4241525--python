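"""Seeded generators for expression compendia, target maps and WT/knockout
pairs with planted regulatory structure.

These emulate the statistical shape the analysis assumes — a log-scale
expression compendium across ~150 conditions with RBP-driven co-regulation
and optional variance damping of targets, a target map with q-values, and a
paired WT/deletion experiment where degradation efficiency rises with
expression — without mimicking real RNA-Seq count noise. Every fixture is
fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, TargetMap
from .knockout import KnockoutPair
from .model import GeneKinetics


@dataclass
class CoexpressionScenario:
    """Knobs of the planted co-expression compendium.

    ``coactivation_strength`` sets how strongly target log expression
    follows the RBP's; ``damping_strength`` in [0, 1] shrinks the
    between-target deviations as the RBP level rises (the buffering
    mechanism); ``noise_sd`` is the per-target condition noise (log2 units).
    """

    n_rbps: int = 30
    n_targets_per_rbp: int = 12
    n_background_genes: int = 50
    n_conditions: int = 148
    coactivation_strength: float = 0.2
    damping_strength: float = 0.8
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets_per_rbp < 11:
            raise ValueError("need >= 11 targets per RBP to pass the target filter")
        if not (0.0 <= self.damping_strength <= 1.0):
            raise ValueError("damping_strength must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.coactivation_strength < 0:
            raise ValueError("coactivation_strength must be >= 0")


@dataclass
class KnockoutScenario:
    """Knobs of the planted WT/deletion pair.

    ``dependence_strength`` in [0, 1] sets how strongly degradation
    efficiency rises with the target's deletion-strain expression;
    ``damping`` couples efficiency to expression rank (False shuffles the
    same efficiencies across targets, keeping the marginal distribution)."""

    n_targets: int = 200
    dependence_strength: float = 0.8
    damping: bool = True
    noise_sd: float = 0.1
    base_efficiency: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dependence_strength <= 1.0):
            raise ValueError("dependence_strength must be in [0, 1]")


# log2 expression landscape of the compendium
_RBP_MEAN = 5.0
_RBP_SD = 1.0
_BASE_MEAN = 5.0
_BASE_SD = 0.5
_RESPONSE_SPREAD = 0.15  # SD of per-target responsiveness around coactivation


def planted_coexpression_fixture(
    s: CoexpressionScenario,
) -> tuple[ExpressionMatrix, TargetMap, pd.DataFrame]:
    """Generate (raw-RPKM matrix, target map, truth table).

    Per condition c the RBP r has log2 expression R_rc ~ N(5, 1). Each of
    its targets g responds with its own sensitivity beta_g (mean
    ``coactivation_strength``), and the whole between-target deviation —
    heterogeneous response plus N(0, noise_sd) noise — is multiplied by
    (1 - damping_strength * R_rc / max_c R_rc):

        x_gc = base_g + coact*R_rc
               + (1 - damping*R_rc/max(R_r)) * ((beta_g - coact)*R_rc + eps)

    With damping off, the heterogeneous response makes the across-target SD
    grow faster than the mean, so CD rises with the RBP (pos_mean_pos_cd);
    with strong damping the deviations are crushed at high RBP levels and
    CD falls (pos_mean_neg_cd, the buffering class). The matrix is returned
    on the raw scale (2**x) so it flows through the standard log transform.
    """
    rng = np.random.default_rng(s.seed)
    n_c = s.n_conditions
    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    entries: dict[str, dict[str, float]] = {}
    truth_rows = []

    for r in range(s.n_rbps):
        rbp_id = f"RBP{r:03d}"
        mu_r = rng.normal(_RBP_MEAN, 0.3)
        R = rng.normal(mu_r, _RBP_SD, size=n_c)
        r_max = R.max()
        damp = 1.0 - s.damping_strength * R / r_max
        if (damp < 0).any():
            raise ValueError(
                f"{rbp_id}: damping produces a non-positive deviation scale"
            )
        gene_ids.append(rbp_id)
        rows.append(R)

        base = rng.normal(_BASE_MEAN, _BASE_SD, size=s.n_targets_per_rbp)
        beta = rng.normal(
            s.coactivation_strength, _RESPONSE_SPREAD, size=s.n_targets_per_rbp
        )
        targets = {}
        for g in range(s.n_targets_per_rbp):
            tid = f"T{r:03d}_{g:03d}"
            eps = rng.normal(0.0, s.noise_sd, size=n_c)
            dev = (beta[g] - s.coactivation_strength) * R + eps
            x = base[g] + s.coactivation_strength * R + damp * dev
            gene_ids.append(tid)
            rows.append(x)
            targets[tid] = float(rng.uniform(1e-6, 9e-4))  # q < 0.001
        # a couple of decoy associations that the q filter must remove
        for d in range(2):
            targets[f"DECOY{r:03d}_{d}"] = float(rng.uniform(0.0011, 0.5))
        entries[rbp_id] = targets

        expected_cd = "neg" if s.damping_strength > 0 else "pos"
        region = (
            "pos_mean_neg_cd" if expected_cd == "neg" else "pos_mean_pos_cd"
        )
        truth_rows.append((rbp_id, "pos", expected_cd, region))

    for b in range(s.n_background_genes):
        gene_ids.append(f"BG{b:03d}")
        rows.append(rng.normal(_BASE_MEAN, 1.0, size=n_c))
    # decoy targets get background-like expression rows
    for r in range(s.n_rbps):
        for d in range(2):
            gene_ids.append(f"DECOY{r:03d}_{d}")
            rows.append(rng.normal(_BASE_MEAN, 1.0, size=n_c))

    log_values = np.vstack(rows)
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        condition_ids=[f"cond{c:03d}" for c in range(n_c)],
        values=np.power(2.0, log_values),
        scale="raw",
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["rbp_id", "expected_mean_sign", "expected_cd_sign", "planted_region"],
    )
    return matrix, TargetMap(entries), truth


def planted_knockout_fixture(
    s: KnockoutScenario,
) -> tuple[KnockoutPair, pd.DataFrame]:
    """Generate a WT/deletion pair with expression-dependent degradation.

    Deletion-strain (KO) expression is log-normal (log2 KO ~ N(5, 1)). Each
    target's efficiency is

        e_g = clip(base + dependence_strength * rank_norm(KO_g) + noise, 0.95)

    where rank_norm maps KO expression ranks onto [0, 1]; WT = KO*(1 - e).
    ``damping=False`` shuffles the efficiencies across targets, severing the
    expression link while preserving their distribution.
    """
    rng = np.random.default_rng(s.seed)
    n = s.n_targets
    ko = np.power(2.0, rng.normal(5.0, 1.0, size=n))
    order = np.argsort(np.argsort(ko))  # ranks 0..n-1, ko has no ties a.s.
    rank_norm = order / (n - 1)
    noise = rng.normal(0.0, s.noise_sd, size=n)
    eff = s.base_efficiency + s.dependence_strength * rank_norm + noise
    if not s.damping:
        eff = rng.permutation(eff)
    eff = np.minimum(eff, 0.95)
    wt = ko * (1.0 - eff)
    gene_ids = [f"T{i:03d}" for i in range(n)]
    pair = KnockoutPair(
        gene_ids=gene_ids, wt_expr=wt, ko_expr=ko,
        rbp_id="RBP_KO", target_ids=list(gene_ids),
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "efficiency": eff, "ko_expr": ko})
    return pair, truth


def model_oracle_fixture(seed: int = 0) -> pd.DataFrame:
    """Small table of kinetic draws with steady states computed by an
    independent exact-rational path, for regression-testing the model.

    Parameters are drawn as small rationals inside the sampling spaces with
    integer Hill coefficients, so A*Hill(m*rbp)/(k + j*rbp) is evaluated
    exactly with Fraction arithmetic, sharing no code with the model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(8):
        A = Fraction(int(rng.integers(11, 20)), 10)       # (1, 2)
        T = Fraction(int(rng.integers(1, 40)), 10)        # (0, 4)
        n = int(rng.integers(1, 4))                       # integer in [1, 3]
        k = Fraction(int(rng.integers(1, 10)), 10)        # (0, 1)
        tg0 = Fraction(int(rng.integers(1, 10)), 10)      # (0, 1)
        m = Fraction(int(rng.integers(1, 20)), 10)        # (0, 2)
        j = Fraction(int(rng.integers(0, 10)), 10)        # [0, 1)
        rbp = Fraction(int(rng.integers(1, 20)), 10)      # (0, 2)
        tf = m * rbp
        hill = tf**n / (T**n + tf**n)
        ss = A * hill / (k + j * rbp)
        rows.append(
            {
                "kinetics": GeneKinetics(
                    A=float(A), T=float(T), n=float(n), k=float(k), tg0=float(tg0)
                ),
                "rbp": float(rbp),
                "m": float(m),
                "j": float(j),
                "steady_state": float(ss),
            }
        )
    return pd.DataFrame(rows)
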