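"""Compositional primitives: closure, zero replacement, means, ILR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import timeuse_coda as tc
from timeuse_coda.errors import (
    ConfigurationError,
    DegenerateInputError,
    DomainError,
    PreconditionError,
)

from conftest import random_compositions


class TestClosure:
    def test_already_closed_is_unchanged(self):
        x = np.array([720.0, 720.0, 0.0, 0.0, 0.0, 0.0])
        assert np.allclose(tc.closure(x), x)

    def test_equal_parts_close_symmetrically(self):
        assert np.allclose(tc.closure(np.ones(6)), np.full(6, 240.0))

    def test_table_profile_already_sums_to_1440(self, weekday_gm):
        assert np.allclose(tc.closure(weekday_gm), weekday_gm)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            tc.closure(np.zeros(4))

    def test_negative_parts_rejected(self):
        with pytest.raises(DomainError):
            tc.closure(np.array([-1.0, 10.0]))

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8))
    def test_closure_sums_to_total(self, parts):
        assert abs(tc.closure(np.array(parts)).sum() - 1440.0) < 1e-6


class TestZeroReplacement:
    def test_no_zeros_identity(self, weekday_gm):
        out = tc.multiplicative_zero_replace(weekday_gm, impute=5.0)
        assert np.allclose(out, weekday_gm)

    def test_single_zero_hand_arithmetic(self, weekday_gm):
        x = pd.Series([900.0, 0.0, 200.0, 50.0, 60.0, 230.0], index=weekday_gm.index)
        out = tc.multiplicative_zero_replace(x, impute=5.0)
        # non-zero parts scale by 1435/1440
        expected = [896.875, 5.0, 199.3055555556, 49.8263888889, 59.7916666667, 229.2013888889]
        assert np.allclose(out, expected, atol=1e-9)
        assert abs(out.sum() - 1440.0) < 1e-9

    def test_two_zeros_scale_1430_over_1440(self, weekday_gm):
        x = pd.Series([900.0, 0.0, 0.0, 250.0, 60.0, 230.0], index=weekday_gm.index)
        out = tc.multiplicative_zero_replace(x, impute=5.0)
        nz = x > 0
        assert np.allclose(out[nz], x[nz] * 1430.0 / 1440.0)
        assert np.allclose(out[~nz], 5.0)
        assert abs(out.sum() - 1440.0) < 1e-9

    def test_impute_at_or_above_slot_resolution_rejected(self):
        with pytest.raises(ConfigurationError):
            tc.multiplicative_zero_replace(pd.Series([1440.0, 0.0]), impute=10.0)

    def test_unclosed_input_rejected(self):
        with pytest.raises(PreconditionError):
            tc.multiplicative_zero_replace(pd.Series([1.0, 0.0, 1.0]), impute=5.0)

    @given(
        st.lists(st.floats(1.0, 1000.0), min_size=2, max_size=8),
        st.data(),
    )
    def test_ratios_of_nonzero_parts_preserved_exactly(self, parts, data):
        x = tc.closure(np.array(parts))
        n_zero = data.draw(st.integers(0, len(x) - 1))
        x[:n_zero] = 0.0
        x = tc.closure(x)
        out = tc.multiplicative_zero_replace(x, impute=5.0)
        nz = np.nonzero(x)[0]
        for i in nz:
            for j in nz:
                # identical multiplicative scaling => ratios exact
                assert out[i] * x[j] == pytest.approx(out[j] * x[i], rel=1e-15)
        assert abs(out.sum() - 1440.0) < 1e-6


class TestCompositionalMean:
    def test_identical_compositions_give_themselves(self, weekday_gm):
        xs = pd.DataFrame([weekday_gm] * 7)
        assert np.allclose(tc.compositional_mean(xs), weekday_gm)

    def test_two_part_hand_arithmetic(self):
        xs = pd.DataFrame([[720.0, 720.0], [180.0, 1260.0]], columns=["a", "b"])
        out = tc.compositional_mean(xs)
        # gm = (sqrt(720*180), sqrt(720*1260)) = (360, 952.470472...),
        # closed: 360*1440/1312.470472 = 394.980315
        gm_b = np.sqrt(720.0 * 1260.0)
        assert out["a"] == pytest.approx(360.0 * 1440.0 / (360.0 + gm_b), abs=1e-9)
        assert out["a"] == pytest.approx(394.980315, abs=1e-6)
        assert out["b"] == pytest.approx(1440.0 - 394.980315, abs=1e-6)

    def test_permutation_equivariance(self, weekday_gm):
        rng = np.random.default_rng(7)
        xs = pd.DataFrame(
            random_compositions(rng, 20, 6), columns=weekday_gm.index
        )
        perm = ["media", "sleep", "domestic", "school", "hobbies", "physical_activity"]
        m1 = tc.compositional_mean(xs)
        m2 = tc.compositional_mean(xs[perm])
        assert np.allclose(m1[perm], m2)

    def test_zero_parts_rejected(self):
        xs = pd.DataFrame([[0.0, 1440.0], [720.0, 720.0]])
        with pytest.raises(PreconditionError):
            tc.compositional_mean(xs)


class TestPivotBasis:
    def test_two_part_closed_form(self):
        b = tc.make_pivot_basis(2)
        assert np.allclose(b.V[:, 0], [1 / np.sqrt(2), -1 / np.sqrt(2)])

    @pytest.mark.parametrize("D", [2, 3, 4, 6, 9])
    def test_orthonormal_and_centred(self, D):
        b = tc.make_pivot_basis(D)
        assert np.max(np.abs(b.V.T @ b.V - np.eye(D - 1))) < 1e-12
        assert np.max(np.abs(b.V.sum(axis=0))) < 1e-12

    def test_pivot_order_permutes_rows(self):
        parts = ["a", "b", "c"]
        b1 = tc.make_pivot_basis(parts)
        b2 = tc.make_pivot_basis(parts, pivot_order=["c", "a", "b"])
        # first coordinate of b2 pivots part 'c'
        z = tc.ilr(pd.Series({"a": 100.0, "b": 100.0, "c": 400.0}), b2)
        expected = np.sqrt(2.0 / 3.0) * np.log(400.0 / 100.0)
        assert z[0] == pytest.approx(expected, abs=1e-12)
        assert b1.parts == b2.parts

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ConfigurationError):
            tc.make_pivot_basis(["a", "b", "c"], pivot_order=["a", "b", "b"])


class TestIlr:
    def test_barycentre_maps_to_zero(self):
        b = tc.make_pivot_basis(6)
        assert np.allclose(tc.ilr(np.full(6, 240.0), b), 0.0)

    def test_two_part_closed_form(self):
        b = tc.make_pivot_basis(2)
        z = tc.ilr(np.array([1080.0, 360.0]), b)
        assert z[0] == pytest.approx(np.log(3.0) / np.sqrt(2.0), abs=1e-12)

    def test_scale_invariance(self, weekday_gm):
        b = tc.make_pivot_basis(list(weekday_gm.index))
        assert np.allclose(tc.ilr(weekday_gm, b), tc.ilr(2.0 * weekday_gm, b))

    def test_zero_part_rejected(self):
        b = tc.make_pivot_basis(3)
        with pytest.raises(DomainError):
            tc.ilr(np.array([0.0, 720.0, 720.0]), b)

    def test_inverse_at_origin_gives_equal_parts(self):
        b = tc.make_pivot_basis(6)
        assert np.allclose(tc.ilr_inverse(np.zeros(5), b), 240.0)

    def test_two_part_inverse_closed_form(self):
        b = tc.make_pivot_basis(2)
        x = tc.ilr_inverse(np.array([np.log(3.0) / np.sqrt(2.0)]), b)
        assert np.allclose(x, [1080.0, 360.0], atol=1e-6)

    def test_roundtrip_on_1000_random_compositions(self):
        rng = np.random.default_rng(11)
        for D in (4, 6):
            b = tc.make_pivot_basis(D)
            xs = random_compositions(rng, 1000, D)
            back = tc.ilr_inverse(tc.ilr(xs, b), b).to_numpy()
            assert np.max(np.abs(back - xs)) < 1e-9


class TestSubcomposition:
    def test_keep_all_is_identity(self, weekday_gm):
        out = tc.subcomposition(weekday_gm, list(weekday_gm.index))
        assert np.allclose(out, weekday_gm)

    def test_weekend_subset_hand_arithmetic(self, weekday_gm):
        keep = ["sleep", "media", "hobbies", "domestic"]
        out = tc.subcomposition(weekday_gm, keep)
        expected = weekday_gm[keep] * (1440.0 / 1367.0)
        assert np.allclose(out, expected)
        assert abs(out.sum() - 1440.0) < 1e-9

    def test_empty_keep_rejected(self, weekday_gm):
        with pytest.raises(ConfigurationError):
            tc.subcomposition(weekday_gm, [])


class TestPartPercentages:
    def test_weekday_profile_matches_reported_percentages(self, weekday_gm):
        pct = tc.part_percentages(weekday_gm)
        assert pct.tolist() == [62, 2, 10, 3, 4, 18]

    def test_weekend_profile_matches_reported_percentages(self, weekend_gm):
        pct = tc.part_percentages(weekend_gm)
        assert pct.tolist() == [59, 14, 8, 19]

    def test_equal_six_parts_round_to_17(self):
        pct = tc.part_percentages(pd.Series(np.full(6, 240.0)))
        assert (pct == 17).all()
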