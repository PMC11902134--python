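import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmirecal import (
    BfBands,
    CutoffSet,
    WHO_CUTOFFS,
    WeightCategory,
    agreement_rates,
    chi_squared_independence,
    classify_bf,
    classify_bmi,
    cohen_kappa,
    cross_tabulate,
    kappa_label,
)
from bmirecal.classification import round_half_up
from bmirecal.errors import DegenerateTableError, DomainError

from conftest import table_to_labels

TABLE2 = [[449, 2], [149, 22]]
TABLE3 = [[574, 6], [24, 18]]


def kappa_oracle(table):
    """Brute-force kappa: explicit Po/Pe summation over expanded label pairs."""
    t = np.asarray(table, dtype=int)
    k = t.shape[0]
    a, b = table_to_labels(t, list(range(k)), list(range(k)))
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    pe = sum((a.count(lab) / n) * (b.count(lab) / n) for lab in range(k))
    return (po - pe) / (1 - pe)


class TestClassify:
    def test_bf_below_band(self):
        assert classify_bf(20.9) is WeightCategory.NORMAL

    def test_bf_overweight_boundary_inclusive(self):
        assert classify_bf(21.0) is WeightCategory.OVERWEIGHT

    def test_bf_obesity_boundary_inclusive(self):
        assert classify_bf(26.0) is WeightCategory.OBESITY

    def test_bf_domain_error(self):
        for bad in (0.0, -3.0, 100.0):
            with pytest.raises(DomainError):
                classify_bf(bad)

    def test_bmi_who_boundary(self):
        assert classify_bmi(25.0, WHO_CUTOFFS) is WeightCategory.OVERWEIGHT
        assert classify_bmi(24.9, WHO_CUTOFFS) is WeightCategory.NORMAL
        assert classify_bmi(30.0, WHO_CUTOFFS) is WeightCategory.OBESITY

    def test_bmi_derived_boundary(self):
        derived = CutoffSet("derived", 28.2, 33.7)
        assert classify_bmi(28.2, derived) is WeightCategory.OVERWEIGHT

    def test_bmi_domain_error(self):
        with pytest.raises(DomainError):
            classify_bmi(0.0)

    @given(
        bmi=st.floats(10.0, 60.0),
        bump=st.floats(0.0, 30.0),
    )
    def test_bmi_monotone(self, bmi, bump):
        order = [WeightCategory.NORMAL, WeightCategory.OVERWEIGHT, WeightCategory.OBESITY]
        lo = order.index(classify_bmi(bmi))
        hi = order.index(classify_bmi(bmi + bump))
        assert hi >= lo

    def test_invalid_bands(self):
        with pytest.raises(DomainError):
            BfBands(26.0, 21.0)
        with pytest.raises(DomainError):
            CutoffSet("bad", 30.0, 25.0)


class TestCohenKappa:
    def test_table2_value(self):
        assert round_half_up(cohen_kappa(TABLE2), 3) == 0.169

    def test_table3_value(self):
        assert round_half_up(cohen_kappa(TABLE3), 3) == 0.522

    def test_diagonal_is_one(self):
        assert cohen_kappa([[7, 0], [0, 3]]) == pytest.approx(1.0)
        assert cohen_kappa(np.diag([5, 1, 9])) == pytest.approx(1.0)

    def test_chance_table_is_zero(self):
        # cells equal to expected counts under independence
        assert cohen_kappa([[10, 10], [10, 10]]) == pytest.approx(0.0)
        assert cohen_kappa([[4, 8], [1, 2]]) == pytest.approx(0.0)

    def test_undefined_when_pe_one(self):
        assert math.isnan(cohen_kappa([[5, 0], [0, 0]]))

    def test_rejects_non_square_and_empty(self):
        with pytest.raises(DegenerateTableError):
            cohen_kappa([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(DegenerateTableError):
            cohen_kappa([[0, 0], [0, 0]])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 50), min_size=9, max_size=9).filter(lambda c: sum(c) > 0)
    )
    def test_closed_form_equals_brute_force_oracle(self, cells):
        table = np.array(cells).reshape(3, 3)
        pe = float(table.sum(axis=1) @ table.sum(axis=0)) / table.sum() ** 2
        if math.isclose(pe, 1.0):
            assert math.isnan(cohen_kappa(table))
        else:
            assert cohen_kappa(table) == pytest.approx(kappa_oracle(table), abs=1e-12)


class TestChiSquared:
    def test_table2_value(self):
        chi2, df, p = chi_squared_independence(TABLE2)
        assert round_half_up(chi2, 3) == 51.575
        assert df == 1
        assert p < 0.001

    def test_table3_value(self):
        chi2, df, p = chi_squared_independence(TABLE3)
        assert round_half_up(chi2, 3) == 184.662
        assert df == 1
        assert p < 0.001

    def test_exact_independence_is_zero(self):
        chi2, df, _ = chi_squared_independence([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_squared_independence([[5, 0], [3, 0]])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(1, 40), min_size=6, max_size=6))
    def test_transpose_symmetry(self, cells):
        table = np.array(cells).reshape(2, 3)
        chi2_a, _, p_a = chi_squared_independence(table)
        chi2_b, _, p_b = chi_squared_independence(table.T)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)
        assert p_a == pytest.approx(p_b, rel=1e-9)


class TestAgreementRates:
    def test_table2_rates(self):
        capture, fp = agreement_rates(TABLE2)
        assert round_half_up(capture, 1) == 91.7
        assert round_half_up(fp, 1) == 24.9

    def test_table3_rates(self):
        capture, fp = agreement_rates(TABLE3)
        assert round_half_up(capture, 1) == 75.0
        assert round_half_up(fp, 1) == 4.0

    def test_diagonal_rates(self):
        capture, fp = agreement_rates([[9, 0], [0, 4]])
        assert capture == 100.0
        assert fp == 0.0

    def test_zero_column_flagged(self):
        capture, fp = agreement_rates([[5, 0], [2, 0]])
        assert capture is None
        assert fp is not None


class TestKappaLabel:
    @pytest.mark.parametrize(
        "kappa, label",
        [
            (0.522, "moderate"),
            (0.169, "slight"),
            (1.0, "almost perfect"),
            (0.0, "poor"),
            (-0.5, "poor"),
            (0.20, "slight"),
            (0.21, "fair"),
            (0.40, "fair"),
            (0.60, "moderate"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
        ],
    )
    def test_bands(self, kappa, label):
        assert kappa_label(kappa) == label

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            kappa_label(1.5)


class TestCrossTabulate:
    def test_reproduces_table2_cells(self):
        a, b = table_to_labels(
            TABLE2,
            [WeightCategory.NORMAL, WeightCategory.OVERWEIGHT_OR_OBESITY],
            [WeightCategory.NORMAL, WeightCategory.OVERWEIGHT_OR_OBESITY],
        )
        res = cross_tabulate(a, b, collapse=True)
        assert res.n == 622
        np.testing.assert_array_equal(res.table, TABLE2)
        np.testing.assert_array_equal(res.table.sum(axis=1), [451, 171])
        np.testing.assert_array_equal(res.table.sum(axis=0), [598, 24])
        assert round_half_up(res.kappa, 3) == 0.169
        assert res.kappa_label == "slight"

    def test_reproduces_table3_cells(self):
        a, b = table_to_labels(
            TABLE3,
            [WeightCategory.NORMAL, WeightCategory.OVERWEIGHT_OR_OBESITY],
            [WeightCategory.NORMAL, WeightCategory.OVERWEIGHT_OR_OBESITY],
        )
        res = cross_tabulate(a, b, collapse=True)
        assert res.n == 622
        np.testing.assert_array_equal(res.table, TABLE3)
        assert round_half_up(res.kappa, 3) == 0.522
        assert res.kappa_label == "moderate"
        assert round_half_up(res.capture_rate, 1) == 75.0
        assert round_half_up(res.false_positive_rate, 1) == 4.0

    def test_self_agreement_diagonal(self):
        cats = [WeightCategory.NORMAL] * 5 + [WeightCategory.OVERWEIGHT] * 3 + [
            WeightCategory.OBESITY
        ] * 2
        res = cross_tabulate(cats, cats, collapse=False)
        off_diag = res.table - np.diag(np.diag(res.table))
        assert off_diag.sum() == 0
        assert res.kappa == pytest.approx(1.0)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(DomainError):
            cross_tabulate([WeightCategory.NORMAL], [], collapse=True)
        with pytest.raises(DomainError):
            cross_tabulate([], [], collapse=True)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from(["normal", "overweight", "obesity"]),
                      st.sampled_from(["normal", "overweight", "obesity"])),
            min_size=1,
            max_size=60,
        )
    )
    def test_collapse_preserves_n_and_normal_counts(self, pairs):
        a = [WeightCategory(x) for x, _ in pairs]
        b = [WeightCategory(y) for _, y in pairs]
        full = cross_tabulate(a, b, collapse=False)
        two = cross_tabulate(a, b, collapse=True)
        assert two.n == full.n
        assert two.table[0, 0] == full.table[0, 0]
        assert two.table.sum(axis=1)[0] == full.table.sum(axis=1)[0]
        assert two.table.sum(axis=0)[0] == full.table.sum(axis=0)[0]
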