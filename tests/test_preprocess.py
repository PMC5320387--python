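"""Zero imputation, log transform, miRNA selection and matrix merging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trinet import (ValidationError, combine, log_transform, preprocess,
                    replace_zeros, select_mirna_by_symbol)

from conftest import make_matrix


class TestReplaceZeros:
    def test_zero_becomes_column_minimum_nonzero(self):
        m = make_matrix([[0.0], [2.0], [5.0]])
        out = replace_zeros(m)
        np.testing.assert_array_equal(out.values.to_numpy().ravel(),
                                      [2.0, 2.0, 5.0])

    def test_no_zeros_is_identity(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(replace_zeros(m).values.to_numpy(),
                                      m.values.to_numpy())

    def test_all_zero_sample_rejected_by_name(self):
        m = make_matrix([[0.0, 1.0], [0.0, 2.0]], sample_ids=["BAD", "OK"])
        with pytest.raises(ValidationError, match="BAD"):
            replace_zeros(m)

    @given(st.lists(
        st.lists(st.floats(0, 100, allow_nan=False, width=32),
                 min_size=3, max_size=6),
        min_size=2, max_size=5).filter(
            lambda rows: len({len(r) for r in rows}) == 1))
    def test_column_minimum_preserved(self, rows):
        arr = np.asarray(rows, dtype=float)
        if (arr == 0).all(axis=0).any():
            return  # degenerate columns are a tested error, not this property
        out = replace_zeros(make_matrix(arr)).values.to_numpy()
        for j in range(arr.shape[1]):
            before = arr[:, j]
            nonzero = before[before > 0]
            assert out[:, j].min() == nonzero.min()
            # nonzero entries untouched
            np.testing.assert_array_equal(out[before > 0, j], nonzero)
            assert (out[:, j] > 0).all()


class TestLogTransform:
    def test_exact_powers(self):
        m = make_matrix([[8.0], [1.0]])
        out = log_transform(m, base=2)
        np.testing.assert_array_equal(out.values.to_numpy().ravel(),
                                      [3.0, 0.0])
        assert out.log_transformed

    def test_elementwise_column(self):
        m = make_matrix([[2.0], [2.0], [5.0]])
        out = log_transform(m, base=2).values.to_numpy().ravel()
        np.testing.assert_allclose(out, [1.0, 1.0, np.log2(5.0)])

    def test_round_trip_with_exponentiation(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.01, 50, size=(4, 5))
        out = log_transform(make_matrix(vals), base=2).values.to_numpy()
        np.testing.assert_allclose(np.power(2.0, out), vals, rtol=1e-12)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValidationError, match="replace_zeros"):
            log_transform(make_matrix([[0.0], [1.0]]))

    def test_double_transform_rejected(self):
        m = log_transform(make_matrix([[1.0, 2.0]]))
        with pytest.raises(ValidationError):
            log_transform(m)


class TestSelectMirna:
    def test_prefix_match_relabels_type(self):
        m = make_matrix([[1.0], [2.0]], gene_ids=["hsa-mir-126", "LINC00001"],
                        types=["lncRNA", "lncRNA"])
        out = select_mirna_by_symbol(m, ["hsa-mir"])
        assert out.gene_ids == ["hsa-mir-126"]
        assert list(out.gene_types) == ["miRNA"]

    def test_match_is_case_insensitive(self):
        m = make_matrix([[1.0]], gene_ids=["HSA-MIR-1"], types=["lncRNA"])
        assert select_mirna_by_symbol(m, ["hsa-mir"]).n_genes == 1

    def test_empty_pattern_list_warns_and_returns_empty(self):
        m = make_matrix([[1.0]], gene_ids=["hsa-mir-1"], types=["lncRNA"])
        with pytest.warns(UserWarning):
            out = select_mirna_by_symbol(m, [])
        assert out.n_genes == 0

    def test_all_rows_match(self):
        m = make_matrix([[1.0], [2.0]], gene_ids=["mir-a", "mir-b"],
                        types=["lncRNA", "lncRNA"])
        out = select_mirna_by_symbol(m, ["mir"])
        assert out.n_genes == 2
        assert set(out.gene_types) == {"miRNA"}


class TestCombine:
    def _three(self):
        m = make_matrix(np.arange(8.0).reshape(2, 4),
                        gene_ids=["A", "B"],
                        sample_ids=["S1", "S2", "S3", "S4"])
        l = make_matrix(np.arange(12.0).reshape(3, 4) + 100,
                        gene_ids=["L1", "L2", "L3"],
                        sample_ids=["S1", "S2", "S3", "S4"],
                        types=["lncRNA"] * 3)
        i = make_matrix([[9.0, 8.0, 7.0, 6.0]], gene_ids=["M1"],
                        sample_ids=["S1", "S2", "S3", "S4"], types=["miRNA"])
        return m, l, i

    def test_shape_and_type_conservation(self):
        out = combine(*self._three())
        assert out.shape == (6, 4)
        assert out.type_counts() == {"mRNA": 2, "lncRNA": 3, "miRNA": 1}

    def test_invariant_to_input_column_permutations(self):
        m, l, i = self._three()
        ref = combine(m, l, i)
        perm = combine(m.with_samples(["S3", "S1", "S4", "S2"]),
                       l.with_samples(["S4", "S3", "S2", "S1"]), i)
        assert ref.sample_ids == perm.sample_ids
        np.testing.assert_array_equal(ref.values.to_numpy(),
                                      perm.values.to_numpy())

    def test_shared_gene_id_rejected(self):
        m, l, i = self._three()
        dup = make_matrix([[1.0] * 4], gene_ids=["A"],
                          sample_ids=["S1", "S2", "S3", "S4"],
                          types=["lncRNA"])
        with pytest.raises(ValidationError, match="'A'"):
            combine(m, dup, i)

    def test_sample_mismatch_lists_difference(self):
        m, l, i = self._three()
        other = make_matrix([[1.0] * 4], gene_ids=["M9"],
                            sample_ids=["S1", "S2", "S3", "SX"],
                            types=["miRNA"])
        with pytest.raises(ValidationError) as exc:
            combine(m, l, other)
        assert "S4" in str(exc.value) and "SX" in str(exc.value)


def test_preprocess_chain_end_state():
    """Zeros imputed, log applied, three classes stacked over sorted samples."""
    m = make_matrix([[0.0, 2.0], [4.0, 8.0]], sample_ids=["S2", "S1"])
    l = make_matrix([[1.0, 1.0]], gene_ids=["L1"], sample_ids=["S1", "S2"],
                    types=["lncRNA"])
    nc = make_matrix([[2.0, 4.0], [5.0, 6.0]],
                     gene_ids=["hsa-mir-9", "LINCX"],
                     sample_ids=["S1", "S2"], types=["lncRNA", "lncRNA"])
    out = preprocess(m, l, noncoding=nc)
    assert out.log_transformed
    assert out.sample_ids == ["S1", "S2"]
    assert out.gene_ids == ["G0", "G1", "L1", "hsa-mir-9"]
    # G0 zero (in sample S2) was floored to that sample's min nonzero (4.0)
    assert out.values.loc["G0", "S2"] == pytest.approx(2.0)  # log2(4)
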