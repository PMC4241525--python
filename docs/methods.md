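# Methods

## Scope and data model

The package analyses the coordination between an RNA-binding protein
(RBP) and its mRNA targets at three levels: observational co-expression
across many conditions, causal perturbation (wild type vs deletion
strain), and a mechanistic kinetic model. Expression is handled as a
dense genes × conditions matrix of non-negative RPKM-like values
(`ExpressionMatrix`), with an explicit `scale` tag (`raw` or `log`) so
that statistics defined on log expression cannot silently run on raw
values. Regulator→target relations carry q-values (`TargetMap`). Missing
cells are a hard error; no imputation is performed anywhere.

## Target selection

Targets are kept when `q < q_cutoff` (default 0.001) and present in the
expression universe; self-targeting entries (an RBP binding its own
mRNA) are removed before anything is counted, because a regulator's
trivial correlation with itself would contaminate the co-expression
analysis. A regulator is retained only with at least `min_targets`
surviving targets; the default of 11 encodes a "more than 10 targets"
rule. The filter is idempotent.

## Co-expression statistics

For each RBP and condition, the targets' log expression is summarised by
its mean, sample SD (n−1 denominator) and CD = SD/mean (the coefficient
of variation). CD is computed on log values as stored: it is invariant
to rescaling the log values but not to shifting them, so the choice of
log base and pseudocount matters and is recorded on the matrix. When
|mean| < 1e−8 the ratio is numerically meaningless; such rows are
flagged `cd_defined=False` and excluded from CD correlations instead of
propagating an exploding value.

Each summary statistic is then correlated with the RBP's own log
expression across conditions. The default is Spearman on average ranks
with a two-sided p-value: exact by permutation for n ≤ 10 (the tie-free
null distribution depends only on n and is cached; tied inputs are
enumerated directly), and the t approximation above, matching R's
`cor.test`. Pearson is available by option. Constant vectors yield a
flagged degenerate result rather than NaN. Raw p-values are reported
per RBP; no multiple-testing correction is applied by default.

The signs of `rho_mean` and `rho_cd` classify each RBP into four
regions; `pos_mean_neg_cd` — co-expressed with targets, suppressing
their variation — is the buffering class, and the classification
reports the fraction of RBPs falling in it. A rho of exactly zero is a
measure-zero tie broken deterministically (zero mean-rho counts as
positive, zero CD-rho as negative) and flagged `degenerate`.

## Knockout analysis

The deletion strain approximates target expression before the RBP acts.
Degradation efficiency is computed on raw RPKM as
`e = (KO − WT)/(KO + pseudocount)`: a fraction ≤ 1, negative when the
gene is higher in WT. Negative efficiencies are retained and counted
(`n_upregulated`) rather than floored, since discarding them would bias
the efficiency–expression correlation. The ordinate for that correlation
is log2 expression in the deletion strain.

The CD comparison reports the CD of target log2 expression in each
strain. The attached significance test is a two-sided variance-ratio
F-test on log expression, `F = var(KO)/var(WT)` with df (n−1, n−1): an
F-test compares variances, not CDs, so the CDs are reported alongside
the test rather than being its literal subject. Swapping the strains
inverts F and preserves the two-sided p. Zero WT variance yields an
infinite F with p at its limit of 0.

## The TF–RBP kinetic model

Each of `n_genes` target genes obeys

    d[TG]_i/dt = A_i·[TF]^n_i/(T_i^n_i + [TF]^n_i) − k_i·[TG]_i − j·[RBP]·[TG]_i

Hill-type transcriptional activation (maximal rate A_i, threshold T_i,
steepness n_i), first-order decay k_i, and RBP-mediated degradation at
rate j per unit RBP. With [TF] = m·[RBP] (m the TF:RBP abundance ratio)
and both regulators constant, the equation is linear in [TG]:

    TG(t) = SS + (TG0 − SS)·exp(−(k + j·RBP)·t),  SS = A·Hill(m·RBP)/(k + j·RBP)

Per-gene parameters are drawn independently and uniformly over open
intervals: TG0 ∈ (0,1), A ∈ (1,2) (so TG0 < A always), T ∈ (0,4),
n ∈ (1,4), k ∈ (0,1); RBP abundance spans (0,2) on an evenly spaced grid
(uniform-random placement of levels is available), m ∈ (0,2), j ∈ (0,1).
One Monte-Carlo repetition draws kinetics once, holds them fixed across
all RBP levels (the same genes observed at different regulator doses),
computes expression for every gene at every level, and correlates the
RBP level with the across-gene mean and CD (Pearson by default — the
relationships are smooth and near-monotone; Spearman selectable).
Repetitions with a constant mean or CD vector are discarded and redrawn,
with the count reported.

**Readout time.** The default readout is the transcript level at a
finite observation time, `t_obs = 1.0` — about one decay time constant
given k ∈ (0,1) — evaluated with the exact exponential solution. This is
a deliberate design choice: at steady state the initial transcript pool
has fully washed out, and the steady-state level rises with RBP
abundance for essentially every admissible parameter draw (the Hill
numerator always grows faster near the origin than the linear loss
term), so the whole (m, j) plane collapses into the single
rising-mean/falling-CD regime. At a finite readout the RBP still acts on
the pre-existing pool, degradation can dominate production at low m and
high j, and all four sign regimes appear — with the buffering regime
occupying the high-m/low-j bulk of the plane (~73 of 100 cells on the
default grid), stable across seeds. It is also the only reading under
which the initial condition TG0 has any role at all.
`mode="steady_state"` selects the asymptotic readout.

The numerical integrator (`integrate_tg`, RK45 with rtol 1e−10) exists
to validate the closed form — agreement to |Δ| < 1e−6 over 50 time
constants across random draws — and to support custom time courses; the
sweep itself always uses the exact solution. An independent
rational-arithmetic oracle (`model_oracle_fixture`, exact `Fraction`
evaluation of the steady state on small rational parameter draws) guards
the closed form against regression.

**Scale.** Full-scale settings are 100 genes × 1,000 RBP levels × 10,000
repetitions per cell. The test suite and acceptance script run a
scaled-down profile — 10×10 grid, 200 repetitions, 200 levels, 100
genes — which reproduces the qualitative structure (all four regimes,
buffering corner) with run times of seconds per grid. Reproducibility
uses one master `SeedSequence` spawning an independent substream per
grid cell, so cells are order-insensitive and a rerun with the same seed
is bit-identical.

## Synthetic data generators

`planted_coexpression_fixture` emulates a multi-condition compendium:
per condition c, RBP r has log2 expression R_rc ~ N(μ_r, 1) with
μ_r ≈ 5; each target g has

    x_gc = base_g + β̄·R_rc + (1 − d·R_rc/max_c R_rc) · ((β_g − β̄)·R_rc + ε_gc)

with baseline base_g ~ N(5, 0.5), mean responsiveness β̄ =
`coactivation_strength` (default 0.2), per-target responsiveness
β_g ~ N(β̄, 0.15), noise ε ~ N(0, `noise_sd`=0.5), and damping strength
d ∈ [0, 1]. The damping factor multiplies the *whole* between-target
deviation, not just the noise: biologically, a buffering RBP suppresses
all dispersion among its targets, whichever source it comes from. This
makes the two knobs genuinely independent: with d = 0 the heterogeneous
response makes the across-target SD grow faster than the mean, so CD
rises with the RBP (`pos_mean_pos_cd` planted truth); with d = 0.8 the
deviations are crushed at high RBP levels and CD falls
(`pos_mean_neg_cd`). Planted targets get q-values below 1e−3, decoy
associations above it, and background genes are independent noise. The
matrix is emitted on the raw scale (2^x) so it exercises the standard
log-transform path.

`planted_knockout_fixture` draws deletion-strain expression log-normally
(log2 KO ~ N(5, 1)) and assigns each target an efficiency
`e = min(0.1 + dependence·rank_norm(KO) + N(0, 0.1), 0.95)`, where
rank_norm maps expression ranks onto [0, 1]; WT = KO·(1 − e), so
`degradation_efficiency` recovers the planted e exactly at pseudocount
0. The 0.95 clip keeps WT positive. `damping=False` permutes the
efficiencies across targets, severing the expression link while keeping
their marginal distribution.

What these generators do **not** emulate: RNA-Seq count overdispersion,
library-size artefacts, replicate structure, or the biology of any
specific regulon. Passing tests demonstrate that the statistics recover
structure of the planted kind at compendium-like sample sizes (148
conditions, ~tens of targets), not that any particular real dataset
would classify the same way.

## Defaults and degenerate inputs

- Log base: 10 for compendium-style analysis, 2 for knockout analysis
  (both configurable); pseudocount default 1 for raw RPKM input, with a
  hard error if value + pseudocount ≤ 0.
- Correlations require ≥ 3 observations; target summaries require ≥ 2
  surviving targets per RBP.
- The CLI refuses non-empty output directories without `--force` and
  writes a `manifest.json` (tool version, configuration, seed) with
  every run.

## Known limitations

- The kinetic model is deterministic (no intrinsic-noise kinetics) and
  has a single TF and a single RBP acting on all genes.
- The exact Spearman permutation p is limited to n ≤ 10; beyond that the
  t approximation is used, which is slightly anticonservative at n
  around 15 with heavy ties.
- CD on log-scale expression depends on the chosen base and pseudocount;
  comparisons are only meaningful within one convention.
- The scaled-down sweep resolves the regime geometry coarsely; regime
  boundaries (not the corner regions) can shift by a cell between seeds.
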