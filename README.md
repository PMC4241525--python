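# rbpregulon

RNA-binding proteins (RBPs) bind sets of mRNAs — post-transcriptional
regulons — and control their stability. A recurring observation in yeast
expression compendia is that an RBP's own expression correlates
*positively* with the average expression of its targets, yet *negatively*
with the variation among them: the regulator is co-expressed with its
regulon while buffering its spread, much like an incoherent feed-forward
loop. `rbpregulon` implements the three analyses behind that observation
as a tested Python library:

1. **Co-expression statistics.** For each RBP, per-condition summaries of
   its targets' log expression — mean, SD and CD (coefficient of
   deviation, SD/mean) — are correlated (Spearman `cor.test`-style, exact
   permutation p at small n) against the RBP's own expression across
   conditions. The signs of `rho_mean` and `rho_cd` classify each RBP into
   one of four regulatory relationships; `pos_mean_neg_cd` is the
   buffering class.
2. **Knockout degradation analysis.** Given paired wild-type and
   RBP-deletion expression profiles, the per-target degradation
   efficiency `(KO − WT)/KO` is correlated with expression level in the
   deletion strain, and the CDs of target expression in the two strains
   are compared with a two-sided variance-ratio F-test on log expression.
3. **TF–RBP kinetic model.** Target genes follow
   `d[TG]_i/dt = A_i·[TF]^n_i/(T_i^n_i+[TF]^n_i) − k_i·[TG]_i − j·[RBP]·[TG]_i`
   with `[TF] = m·[RBP]`. A Monte-Carlo sweep over the (m, j) plane draws
   per-gene kinetics uniformly from yeast-motivated ranges, evaluates all
   genes across a ladder of RBP abundances, and maps the four sign
   regimes of the mean- and CD-correlations — the buffering regime
   occupies the high-m/low-j region where transcript generation outweighs
   RBP-mediated degradation.

Seeded synthetic-data generators (`planted_coexpression_fixture`,
`planted_knockout_fixture`) provide compendium-shaped inputs with known
planted structure, so every pipeline runs end-to-end with no downloads.

## Worked example

`python examples/knockout_comparison.py` simulates a paired WT/deletion
experiment with 200 targets whose degradation rises with expression, then
recovers the signature:

```
targets analysed: 200
efficiency vs KO-strain log2 expression: rho = 0.929 (p = 1.43e-87)
CD among targets, WT strain: 0.143
CD among targets, deletion strain: 0.184
variance-ratio F = 3.03 (two-sided p = 2.59e-14, df = (199,199))
```

The positive rho says highly expressed targets lose the largest fraction
of their mRNA to the RBP; the lower WT CD and F ≫ 1 say the strain *with*
the RBP shows less expression variation among the targets — the RBP
buffers its regulon. The other examples cover the co-expression
classification (`examples/coexpression_analysis.py`), the phase diagram
(`examples/phase_diagram.py`, printing a ±/± region map over the (m, j)
grid) and fixture generation (`examples/synthetic_fixtures.py`).

A thin CLI wraps the same stages:

```
rbpregulon synth coexpression --seed 1 --out fixtures/
rbpregulon coexpress --expr fixtures/expression.tsv --targets fixtures/targets.tsv \
    --log-base 2 --pseudocount 0 --out run/
rbpregulon model --grid-m 0.1:1.9:10 --grid-j 0.05:0.95:10 --reps 200 --out sweep/
```

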