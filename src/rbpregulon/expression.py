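"""Expression matrices and regulator→target maps.

The on-disk dialect is deliberately rigid: tab-separated UTF-8, one header
row of condition ids (first header cell ignored), one gene per row. Target
maps are three-column TSV (rbp_id, target_id, q_value) with a header row.
Missing cells are an error — no imputation is performed anywhere.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes × conditions table of non-negative expression values.

    ``scale`` is 'raw' (RPKM-like units) or 'log'; when 'log', ``log_base``
    records the base used so downstream statistics are interpretable.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray
    scale: str = "raw"
    log_base: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        dupes = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate gene id(s): {sorted(set(dupes))}")
        if pd.Index(self.condition_ids).duplicated().any():
            raise ValueError("duplicate condition ids")
        if np.isnan(self.values).any():
            g, c = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at gene {self.gene_ids[g]!r}, "
                f"condition {self.condition_ids[c]!r}"
            )
        if self.scale == "raw":
            if (self.values < 0).any():
                g, c = np.argwhere(self.values < 0)[0]
                raise ValueError(
                    f"negative raw expression at gene {self.gene_ids[g]!r}, "
                    f"condition {self.condition_ids[c]!r}"
                )
            self.log_base = None
        elif self.scale == "log":
            if self.log_base is None or self.log_base <= 1:
                raise ValueError("log-scale matrix requires log_base > 1")
        else:
            raise ValueError(f"scale must be 'raw' or 'log', got {self.scale!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.condition_ids
        )

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a raw-scale expression matrix from TSV.

    Raises on duplicate gene ids (naming the gene) and on non-numeric or
    negative cells (naming the coordinates).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene id(s) in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        g, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[g]!r}, "
            f"condition {df.columns[c]!r} in {path}"
        )
    if numeric.isna().any().any():
        g, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing cell at gene {df.index[g]!r}, condition {df.columns[c]!r}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        condition_ids=[str(c) for c in df.columns],
        values=numeric.to_numpy(dtype=float),
        scale="raw",
    )


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def rpkm(
    read_counts: np.ndarray,
    gene_lengths_bp: np.ndarray,
    library_sizes: np.ndarray,
    gene_ids: list[str] | None = None,
    condition_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Reads Per Kilobase per Million mapped reads.

    value[g, c] = count[g, c] / (length_kb[g] * library_size_millions[c]).
    Provided for fixture construction; the analysis path starts from RPKM.
    """
    counts = np.asarray(read_counts, dtype=float)
    lengths = np.asarray(gene_lengths_bp, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if (counts < 0).any():
        raise ValueError("read counts must be non-negative")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    if counts.shape != (len(lengths), len(libs)):
        raise ValueError("counts shape must be (n_genes, n_conditions)")
    values = counts / (lengths[:, None] / 1e3) / (libs[None, :] / 1e6)
    n_g, n_c = counts.shape
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(n_g)],
        condition_ids=condition_ids or [f"c{i}" for i in range(n_c)],
        values=values,
        scale="raw",
    )


def log_transform(
    m: ExpressionMatrix, base: float = 10.0, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log_base(value + pseudocount) of a raw-scale matrix."""
    if m.scale != "raw":
        raise ValueError("matrix is already log-scale")
    if base <= 1:
        raise ValueError("log base must be > 1")
    shifted = m.values + pseudocount
    if (shifted <= 0).any():
        raise ValueError(
            "value + pseudocount <= 0 encountered; supply a positive pseudocount"
        )
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        condition_ids=list(m.condition_ids),
        values=np.log(shifted) / math.log(base),
        scale="log",
        log_base=base,
    )


@dataclass
class TargetMap:
    """regulator_id → {target_id: q_value} associations."""

    entries: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rbp, targets in self.entries.items():
            for tgt, q in targets.items():
                if not (0.0 <= q <= 1.0):
                    raise ValueError(
                        f"q-value {q} for ({rbp!r}, {tgt!r}) outside [0, 1]"
                    )

    @property
    def regulators(self) -> list[str]:
        return list(self.entries)

    def targets_of(self, rbp_id: str) -> dict[str, float]:
        return self.entries[rbp_id]

    def n_pairs(self) -> int:
        return sum(len(t) for t in self.entries.values())


def read_target_map(path) -> TargetMap:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"target map {path} needs columns rbp_id, target_id, q_value")
    entries: dict[str, dict[str, float]] = {}
    for rbp, tgt, q in df.iloc[:, :3].itertuples(index=False):
        entries.setdefault(str(rbp), {})[str(tgt)] = float(q)
    return TargetMap(entries)


def write_target_map(tm: TargetMap, path) -> None:
    rows = [
        (rbp, tgt, q)
        for rbp, targets in tm.entries.items()
        for tgt, q in sorted(targets.items())
    ]
    pd.DataFrame(rows, columns=["rbp_id", "target_id", "q_value"]).to_csv(
        path, sep="\t", index=False
    )


def filter_targets(
    tm: TargetMap,
    q_cutoff: float = 0.001,
    min_targets: int = 11,
    universe: set[str] | None = None,
) -> TargetMap:
    """Apply the target-selection filters.

    Keeps (target, q) pairs with q < q_cutoff that fall inside ``universe``
    (when given), removes self-targeting entries, then drops regulators with
    fewer than ``min_targets`` surviving targets. The default of 11 encodes
    the "more than 10 targets" rule.
    """
    if not (0.0 < q_cutoff <= 1.0):
        raise ValueError("q_cutoff must be in (0, 1]")
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    out: dict[str, dict[str, float]] = {}
    for rbp, targets in tm.entries.items():
        kept = {}
        for tgt, q in targets.items():
            if tgt == rbp:
                log.info("removed self-target entry for %s", rbp)
                continue
            if q >= q_cutoff:
                continue
            if universe is not None and tgt not in universe:
                continue
            kept[tgt] = q
        if len(kept) >= min_targets:
            out[rbp] = kept
    if not out:
        warnings.warn("filter_targets: no regulators survive the filters")
    return TargetMap(out)
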