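"""Write seeded synthetic fixtures to disk in the package's TSV dialects.

Every fixture is byte-identical for a given seed, so pipelines built on
them are fully reproducible.
"""

from pathlib import Path

import pandas as pd

from rbpregulon import (
    CoexpressionScenario,
    KnockoutScenario,
    planted_coexpression_fixture,
    planted_knockout_fixture,
    write_expression_matrix,
    write_target_map,
)

out = Path("scratch/example_fixtures")
out.mkdir(parents=True, exist_ok=True)

matrix, target_map, truth = planted_coexpression_fixture(
    CoexpressionScenario(n_rbps=5, n_conditions=40, seed=1)
)
write_expression_matrix(matrix, out / "expression.tsv")
write_target_map(target_map, out / "targets.tsv")
truth.to_csv(out / "coexpression_truth.tsv", sep="\t", index=False)
print(f"co-expression fixture: {matrix.shape[0]} genes x "
      f"{matrix.shape[1]} conditions, {target_map.n_pairs()} target pairs")

pair, ko_truth = planted_knockout_fixture(KnockoutScenario(n_targets=50, seed=2))
pd.DataFrame(
    {"gene_id": pair.gene_ids, "wt": pair.wt_expr, "ko": pair.ko_expr}
).to_csv(out / "wt_ko.tsv", sep="\t", index=False)
ko_truth.to_csv(out / "knockout_truth.tsv", sep="\t", index=False)
print(f"knockout fixture: {len(pair.gene_ids)} targets, "
      f"planted efficiencies in [{ko_truth.efficiency.min():.2f}, "
      f"{ko_truth.efficiency.max():.2f}]")
print(f"files under {out}/")
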