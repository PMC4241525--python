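import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rbpregulon import (
    ExpressionMatrix,
    TargetMap,
    filter_targets,
    log_transform,
    read_expression_matrix,
    rpkm,
    write_expression_matrix,
)


class TestReadWrite:
    def test_round_trip_shape_and_labels(self, tiny_matrix_tsv, tmp_path):
        m = read_expression_matrix(tiny_matrix_tsv)
        assert m.shape == (3, 2)
        assert m.gene_ids == ["g1", "g2", "g3"]
        assert m.condition_ids == ["c1", "c2"]
        assert m.scale == "raw"
        out = tmp_path / "out.tsv"
        write_expression_matrix(m, out)
        m2 = read_expression_matrix(out)
        np.testing.assert_allclose(m2.values, m.values)
        assert m2.gene_ids == m.gene_ids

    def test_duplicate_gene_row_names_the_gene(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\tc1\ng1\t1.0\ng1\t2.0\n")
        with pytest.raises(ValueError, match="g1"):
            read_expression_matrix(path)

    def test_non_numeric_cell_names_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tc1\tc2\ng1\t1.0\toops\n")
        with pytest.raises(ValueError, match="g1.*c2"):
            read_expression_matrix(path)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ExpressionMatrix(["g1"], ["c1"], np.array([[-1.0]]))

    def test_missing_cell_rejected(self, tmp_path):
        path = tmp_path / "gap.tsv"
        path.write_text("gene_id\tc1\tc2\ng1\t1.0\t\n")
        with pytest.raises(ValueError, match="missing"):
            read_expression_matrix(path)


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [
            (10, 2000, 1_000_000, 5.0),
            (0, 2000, 1_000_000, 0.0),
            (100, 500, 2_000_000, 100.0),
        ],
    )
    def test_closed_form(self, count, length, lib, expected):
        m = rpkm(np.array([[count]]), np.array([length]), np.array([lib]))
        assert m.values[0, 0] == pytest.approx(expected)

    def test_zero_length_or_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm(np.array([[1]]), np.array([0]), np.array([10]))
        with pytest.raises(ValueError):
            rpkm(np.array([[1]]), np.array([100]), np.array([0]))

    @given(
        counts=hnp.arrays(
            np.int64, (3, 2), elements=st.integers(min_value=0, max_value=10**6)
        )
    )
    def test_linearity_in_counts(self, counts):
        lengths = np.array([500, 1000, 1500])
        libs = np.array([1_000_000, 2_000_000])
        one = rpkm(counts, lengths, libs)
        two = rpkm(2 * counts, lengths, libs)
        np.testing.assert_allclose(two.values, 2 * one.values)

    @given(
        counts=hnp.arrays(
            np.int64, (2, 2), elements=st.integers(min_value=1, max_value=10**6)
        )
    )
    def test_rpkm_then_log_finite_on_positive_counts(self, counts):
        m = rpkm(counts, np.array([500, 800]), np.array([10**6, 10**6]))
        logged = log_transform(m, base=10, pseudocount=0.0)
        assert np.isfinite(logged.values).all()


class TestLogTransform:
    @pytest.mark.parametrize(
        "value,base,pseudo,expected",
        [(100.0, 10, 0.0, 2.0), (0.0, 10, 1.0, 0.0), (7.0, 2, 1.0, 3.0)],
    )
    def test_closed_form(self, value, base, pseudo, expected):
        m = ExpressionMatrix(["g"], ["c"], np.array([[value]]))
        out = log_transform(m, base=base, pseudocount=pseudo)
        assert out.values[0, 0] == pytest.approx(expected)
        assert out.scale == "log" and out.log_base == base

    def test_zero_with_zero_pseudocount_is_an_error(self):
        m = ExpressionMatrix(["g"], ["c"], np.array([[0.0]]))
        with pytest.raises(ValueError, match="pseudocount"):
            log_transform(m, base=10, pseudocount=0.0)

    def test_double_log_rejected(self):
        m = ExpressionMatrix(["g"], ["c"], np.array([[1.0]]))
        with pytest.raises(ValueError):
            log_transform(log_transform(m), base=10)


def _toy_map():
    # counts of q<0.001 non-self targets: r9 -> 9, r10 -> 10, r11 -> 11, r12 -> 12
    entries = {}
    for name, n in [("r9", 9), ("r10", 10), ("r11", 11), ("r12", 12)]:
        targets = {f"{name}_t{i}": 1e-5 for i in range(n)}
        targets[f"{name}_weak"] = 0.01  # fails the q cutoff
        targets[name] = 0.0  # self-target, must be removed before counting
        entries[name] = targets
    return TargetMap(entries)


class TestFilterTargets:
    def test_more_than_ten_rule(self):
        tm = _toy_map()
        out = filter_targets(tm, q_cutoff=0.001, min_targets=11)
        assert sorted(out.regulators) == ["r11", "r12"]
        assert len(out.targets_of("r11")) == 11

    def test_q_threshold_is_strict(self):
        tm = TargetMap({"r": {f"t{i}": 0.0005 for i in range(11)} | {"edge": 0.001}})
        out = filter_targets(tm, q_cutoff=0.001, min_targets=11)
        assert "edge" not in out.targets_of("r")

    def test_self_target_removed_before_counting(self):
        tm = TargetMap({"r": {"r": 0.0} | {f"t{i}": 1e-5 for i in range(10)}})
        # 10 surviving non-self targets: dropped under the more-than-10 rule
        assert filter_targets(tm, min_targets=11).regulators == []

    def test_universe_restriction(self):
        tm = TargetMap({"r": {f"t{i}": 1e-5 for i in range(12)}})
        universe = {f"t{i}" for i in range(11)} | {"r"}
        out = filter_targets(tm, min_targets=11, universe=universe)
        assert len(out.targets_of("r")) == 11

    def test_idempotent(self):
        tm = _toy_map()
        once = filter_targets(tm, q_cutoff=0.001, min_targets=11)
        twice = filter_targets(once, q_cutoff=0.001, min_targets=11)
        assert once.entries == twice.entries

    def test_empty_result_warns_not_raises(self):
        tm = TargetMap({"r": {"t": 0.5}})
        with pytest.warns(UserWarning):
            out = filter_targets(tm)
        assert out.regulators == []
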