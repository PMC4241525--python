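"""TF–RBP kinetic model of target-gene expression and its phase diagram.

Each target gene i obeys

    d[TG]_i/dt = A_i * [TF]^n_i / (T_i^n_i + [TF]^n_i) - k_i*[TG]_i - j*[RBP]*[TG]_i

a Hill-activated production term driven by the transcription factor, linear
first-order decay at rate k_i, and RBP-mediated degradation at rate j per
unit of RBP. With [TF] = m*[RBP] (m is the TF:RBP abundance ratio) and both
regulators held constant, the equation is linear in [TG] with steady state

    TG_ss = A * Hill(m*RBP) / (k + j*RBP)

and exact solution TG(t) = SS + (TG0 - SS) * exp(-(k + j*RBP) t).

The Monte-Carlo sweep draws kinetic parameters per gene uniformly over
empirically motivated yeast ranges, evaluates all genes across a ladder of
RBP abundances, and correlates RBP level against the across-gene mean and
CD of target expression. The signs of the two correlations partition the
(m, j) plane into four regulatory regimes; the regime with rising mean and
falling CD is the buffering (incoherent-feed-forward-like) mode.

The default readout is the transcript level at a finite observation time
(t_obs = 1.0, about one decay time constant), via the exact solution above.
At steady state the initial pool [TG]_0 has fully washed out and RBP-driven
degradation can no longer dominate production anywhere in the (m, j) plane,
so the mean correlation is positive almost everywhere and the diagram
collapses to a single regime; the finite-time readout, where the RBP still
acts on the pre-existing transcript pool, is what produces all four
regimes. ``mode='steady_state'`` selects the asymptotic readout instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .coexpression import region_from_signs

#: open-interval sampling spaces for per-gene kinetics:
#: initial level TG0, maximal rate A, activation threshold T,
#: Hill coefficient n, decay rate k.
PARAM_SPACES = {
    "tg0": (0.0, 1.0),
    "A": (1.0, 2.0),
    "T": (0.0, 4.0),
    "n": (1.0, 4.0),
    "k": (0.0, 1.0),
}
RBP_SPACE = (0.0, 2.0)
M_SPACE = (0.0, 2.0)
J_SPACE = (0.0, 1.0)


@dataclass(frozen=True)
class GeneKinetics:
    """Kinetic parameters of one target gene."""

    A: float
    T: float
    n: float
    k: float
    tg0: float


@dataclass
class SystemParameters:
    """Shared settings of one phase-diagram simulation."""

    n_genes: int = 100
    n_rbp_levels: int = 1000
    n_reps: int = 10_000
    seed: int = 0
    method: str = "pearson"  # correlation inside the model
    mode: str = "timecourse"  # timecourse | steady_state
    t_obs: float = 1.0  # observation time for the timecourse readout
    rbp_levels: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.mode not in ("timecourse", "steady_state"):
            raise ValueError("mode must be 'timecourse' or 'steady_state'")
        if self.mode == "timecourse" and self.t_obs <= 0:
            raise ValueError("t_obs must be positive")
        if self.rbp_levels is None:
            self.rbp_levels = rbp_level_grid(self.n_rbp_levels)
        self.rbp_levels = np.asarray(self.rbp_levels, dtype=float)
        if len(self.rbp_levels) < 3:
            raise ValueError("need at least 3 RBP levels")
        lo, hi = RBP_SPACE
        if (self.rbp_levels <= lo).any() or (self.rbp_levels >= hi).any():
            raise ValueError(f"RBP levels must lie strictly inside {RBP_SPACE}")


def rbp_level_grid(n: int) -> np.ndarray:
    """Evenly spaced RBP abundances over (0, 2), endpoints excluded."""
    lo, hi = RBP_SPACE
    return np.linspace(lo, hi, n + 2)[1:-1]


def draw_kinetics(rng: np.random.Generator, n_genes: int) -> dict[str, np.ndarray]:
    """Independent uniform draws over each parameter space, one per gene."""
    return {
        name: rng.uniform(lo, hi, size=n_genes)
        for name, (lo, hi) in PARAM_SPACES.items()
    }


def steady_state(g: GeneKinetics, rbp: float, m: float, j: float) -> float:
    """Closed-form steady state A*Hill(m*rbp) / (k + j*rbp)."""
    return float(_steady_state_arrays(
        np.array([g.A]), np.array([g.T]), np.array([g.n]), np.array([g.k]),
        rbp, m, j,
    )[0])


def _steady_state_arrays(A, T, n, k, rbp, m, j):
    tf = m * rbp
    denom = k + j * rbp
    if np.any(denom == 0):
        raise ValueError("k + j*rbp must be nonzero")
    hill = tf**n / (T**n + tf**n)
    return A * hill / denom


def integrate_tg(
    g: GeneKinetics,
    rbp: float,
    m: float,
    j: float,
    t_end: float,
    dt: float,
) -> np.ndarray:
    """Numerically integrate one gene's trajectory from tg0.

    With constant TF and RBP the equation is linear, so this exists to
    validate the closed form and to support finite-time readouts.
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    tf = m * rbp
    production = g.A * tf**g.n / (g.T**g.n + tf**g.n)
    loss = g.k + j * rbp

    def rhs(_t, y):
        return production - loss * y

    t_eval = np.arange(0.0, t_end + 0.5 * dt, dt)
    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), [g.tg0], t_eval=t_eval,
        rtol=1e-10, atol=1e-12, method="RK45",
    )
    traj = sol.y[0]
    if not np.all(np.isfinite(traj)):
        raise FloatingPointError(f"non-finite trajectory for {g}, rbp={rbp}, m={m}, j={j}")
    return traj


def closed_form_trajectory(
    g: GeneKinetics, rbp: float, m: float, j: float, t: np.ndarray
) -> np.ndarray:
    """Exact solution SS + (tg0 - SS) * exp(-(k + j*rbp) t)."""
    ss = steady_state(g, rbp, m, j)
    rate = g.k + j * rbp
    return ss + (g.tg0 - ss) * np.exp(-rate * np.asarray(t, dtype=float))


def _correlate_rows(rows: np.ndarray, x: np.ndarray, method: str) -> np.ndarray:
    """Pearson (optionally on ranks) of each row of ``rows`` against x.

    Degenerate (constant) rows return NaN; callers resample those reps.
    """
    if method == "spearman":
        from scipy.stats import rankdata

        rows = rankdata(rows, axis=1)
        x = rankdata(x)
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    rc = rows - rows.mean(axis=1, keepdims=True)
    sr = np.sqrt((rc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ xc) / (sr * sx)
    rho[sr == 0.0] = np.nan
    return np.clip(rho, -1.0, 1.0)


def _batch_reps(
    m: float,
    j: float,
    n_reps: int,
    n_genes: int,
    rbp: np.ndarray,
    rng: np.random.Generator,
    method: str,
    t_obs: float | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised Monte-Carlo reps for one (m, j) cell.

    ``t_obs=None`` reads out the steady state; otherwise the exact solution
    at time t_obs. Returns per-rep correlations (rho_mean, rho_cd) and the
    number of degenerate reps that were discarded and redrawn.
    """
    rho_mean = np.empty(n_reps)
    rho_cd = np.empty(n_reps)
    filled = 0
    discarded = 0
    while filled < n_reps:
        batch = n_reps - filled
        p = {k: rng.uniform(lo, hi, size=(batch, n_genes))
             for k, (lo, hi) in PARAM_SPACES.items()}
        tf = m * rbp  # (levels,)
        # tg: (batch, levels, genes)
        tf_n = tf[None, :, None] ** p["n"][:, None, :]
        hill = tf_n / (p["T"][:, None, :] ** p["n"][:, None, :] + tf_n)
        loss = p["k"][:, None, :] + j * rbp[None, :, None]
        tg = p["A"][:, None, :] * hill / loss
        if t_obs is not None:
            tg = tg + (p["tg0"][:, None, :] - tg) * np.exp(-loss * t_obs)
        means = tg.mean(axis=2)
        sds = tg.std(axis=2, ddof=1)
        cds = sds / means  # transcript levels are strictly positive
        rm = _correlate_rows(means, rbp, method)
        rcd = _correlate_rows(cds, rbp, method)
        ok = np.isfinite(rm) & np.isfinite(rcd)
        n_ok = int(ok.sum())
        discarded += batch - n_ok
        rho_mean[filled:filled + n_ok] = rm[ok]
        rho_cd[filled:filled + n_ok] = rcd[ok]
        filled += n_ok
        if discarded > 100 * n_reps:
            raise RuntimeError(f"cell m={m}, j={j}: almost all reps degenerate")
    return rho_mean, rho_cd, discarded


def simulate_rep(
    params: SystemParameters,
    m: float,
    j: float,
    rng: np.random.Generator | None = None,
) -> dict:
    """One Monte-Carlo repetition: draw kinetics for every gene once, hold
    them fixed across all RBP levels, and correlate RBP level against the
    across-gene mean and CD of target expression (finite-time readout by
    default, steady state when params.mode='steady_state')."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t_obs = params.t_obs if params.mode == "timecourse" else None
    rho_mean, rho_cd, discarded = _batch_reps(
        m, j, 1, params.n_genes, params.rbp_levels, rng, params.method, t_obs
    )
    return {
        "rho_mean": float(rho_mean[0]),
        "rho_cd": float(rho_cd[0]),
        "n_discarded": discarded,
    }


def sweep_phase_diagram(
    grid_m,
    grid_j,
    params: SystemParameters,
    chunk_reps: int = 200,
) -> pd.DataFrame:
    """Monte-Carlo phase diagram over an (m, j) grid.

    Every cell gets an independent, order-insensitive random substream
    spawned from the master seed, runs ``params.n_reps`` repetitions, and is
    labelled by the signs of the rep-averaged correlations.
    """
    grid_m = np.asarray(grid_m, dtype=float)
    grid_j = np.asarray(grid_j, dtype=float)
    if (grid_m <= M_SPACE[0]).any() or (grid_m >= M_SPACE[1]).any():
        raise ValueError(f"m grid must lie strictly inside {M_SPACE}")
    if (grid_j <= J_SPACE[0]).any() or (grid_j >= J_SPACE[1]).any():
        raise ValueError(f"j grid must lie strictly inside {J_SPACE}")
    master = np.random.SeedSequence(params.seed)
    children = master.spawn(len(grid_m) * len(grid_j))
    t_obs = params.t_obs if params.mode == "timecourse" else None
    rows = []
    cell = 0
    for m in grid_m:
        for j in grid_j:
            rng = np.random.default_rng(children[cell])
            cell += 1
            done = 0
            sums = np.zeros(2)
            discarded = 0
            while done < params.n_reps:
                k = min(chunk_reps, params.n_reps - done)
                rm, rcd, dis = _batch_reps(
                    m, j, k, params.n_genes, params.rbp_levels, rng,
                    params.method, t_obs,
                )
                sums += (rm.sum(), rcd.sum())
                discarded += dis
                done += k
            mean_rm = sums[0] / params.n_reps
            mean_rcd = sums[1] / params.n_reps
            region, _ = region_from_signs(mean_rm, mean_rcd)
            rows.append((m, j, mean_rm, mean_rcd, region, params.n_reps, discarded))
    return pd.DataFrame(
        rows,
        columns=["m", "j", "mean_rho_mean", "mean_rho_cd", "region",
                 "n_reps_used", "n_discarded"],
    )
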