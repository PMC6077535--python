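"""Interval type-2 fuzzy inference: fuzzification, firing, Karnik-Mendel
type reduction (against an exhaustive oracle), and prediction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sodbci.it2fls import (
    IT2FParams,
    IT2MembershipFunction,
    N_PARAMS,
    compute_firing_intervals,
    defuzzify,
    fuzzify,
    predict,
    predict_batch,
    type_reduce_cos,
)
from sodbci.types import NoRuleFiredError, PhaseLagVector


def km_brute_force(c_l, c_r, f_low, f_high):
    """Exhaustive oracle: the type-reduced bounds are attained at vertices
    of the firing-weight box, so enumerate every low/high assignment."""
    c_l, c_r = np.asarray(c_l, float), np.asarray(c_r, float)
    f_low, f_high = np.asarray(f_low, float), np.asarray(f_high, float)
    n = c_l.size
    y_l, y_r = np.inf, -np.inf
    for bits in itertools.product((0, 1), repeat=n):
        w = np.where(bits, f_high, f_low)
        s = w.sum()
        if s == 0:
            continue
        y_l = min(y_l, float(w @ c_l / s))
        y_r = max(y_r, float(w @ c_r / s))
    return y_l, y_r


def _random_instance(rng, n_rules):
    f_high = rng.uniform(0.05, 1.0, n_rules)
    f_low = f_high * rng.uniform(0.0, 1.0, n_rules)
    c_l = rng.uniform(200.0, 600.0, n_rules)
    c_r = c_l + rng.uniform(0.0, 100.0, n_rules)
    return c_l, c_r, f_low, f_high


def _simple_params(**overrides):
    base = dict(
        m_low=np.tile([80.0, 180.0, 280.0], (4, 1)),
        m_high=np.tile([100.0, 200.0, 300.0], (4, 1)),
        sigma=np.full((4, 3), 40.0),
        c_l=np.array([280.0, 320.0, 360.0]),
        c_r=np.array([300.0, 340.0, 380.0]),
    )
    base.update(overrides)
    return IT2FParams(**base)


class TestMembership:
    def test_collapsed_fou_at_center(self):
        mf = IT2MembershipFunction(m_low=90.0, m_high=90.0, sigma=20.0)
        assert mf.grades(90.0) == (1.0, 1.0)

    def test_upper_is_one_inside_mean_band(self):
        mf = IT2MembershipFunction(m_low=80.0, m_high=100.0, sigma=20.0)
        lower, upper = mf.grades(90.0)
        assert upper == 1.0
        assert lower < 1.0

    def test_far_tail_negligible(self):
        mf = IT2MembershipFunction(m_low=80.0, m_high=100.0, sigma=10.0)
        lower, upper = mf.grades(250.0)  # 15 sigma away
        assert upper < 1e-6 and lower < 1e-6

    def test_upper_dominates_lower_everywhere(self):
        mf = IT2MembershipFunction(m_low=100.0, m_high=140.0, sigma=25.0)
        for x in np.linspace(0.0, 360.0, 73):
            lower, upper = mf.grades(float(x))
            assert lower <= upper


class TestFiring:
    def test_unit_grades_give_unit_firing(self):
        grades = (np.ones((4, 3)), np.ones((4, 3)))
        f_low, f_high = compute_firing_intervals(grades)
        np.testing.assert_allclose(f_low, 1.0)
        np.testing.assert_allclose(f_high, 1.0)

    def test_zero_lower_grade_annihilates(self):
        lower = np.ones((4, 3))
        lower[2, 1] = 0.0
        f_low, _ = compute_firing_intervals((lower, np.ones((4, 3))))
        assert f_low[1] == 0.0

    def test_product_arithmetic(self):
        lower = np.array([[0.5], [0.5], [1.0], [1.0]])
        upper = np.array([[0.8], [0.8], [1.0], [1.0]])
        f_low, f_high = compute_firing_intervals((lower, upper))
        assert f_low[0] == pytest.approx(0.25)
        assert f_high[0] == pytest.approx(0.64)


class TestTypeReduction:
    def test_single_rule_returns_consequent(self):
        y_l, y_r = type_reduce_cos(
            (np.array([0.3]), np.array([0.7])), (np.array([300.0]), np.array([320.0]))
        )
        assert (y_l, y_r) == (300.0, 320.0)

    def test_type1_limit_is_weighted_mean(self):
        f = np.array([0.2, 0.5, 0.3])
        c = np.array([300.0, 340.0, 380.0])
        y_l, y_r = type_reduce_cos((f, f), (c, c))
        expected = float(f @ c / f.sum())
        assert y_l == pytest.approx(expected)
        assert y_r == pytest.approx(expected)

    def test_all_zero_firing_signaled(self):
        with pytest.raises(NoRuleFiredError):
            type_reduce_cos(
                (np.zeros(3), np.zeros(3)),
                (np.array([300.0, 310.0, 320.0]), np.array([305.0, 315.0, 325.0])),
            )

    @pytest.mark.parametrize("n_rules", [2, 3, 4, 5])
    def test_matches_exhaustive_oracle(self, rng, n_rules):
        for _ in range(500):
            c_l, c_r, f_low, f_high = _random_instance(rng, n_rules)
            y_l, y_r = type_reduce_cos((f_low, f_high), (c_l, c_r))
            bl, br = km_brute_force(c_l, c_r, f_low, f_high)
            assert abs(y_l - bl) < 1e-9
            assert abs(y_r - br) < 1e-9
            assert y_l <= y_r + 1e-12


class TestDefuzzify:
    def test_midpoint(self):
        assert defuzzify(300.0, 320.0) == 310.0

    def test_degenerate_interval(self):
        assert defuzzify(310.0, 310.0) == 310.0

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            defuzzify(320.0, 300.0)


class TestPredict:
    def test_constant_consequents_give_constant_output(self):
        params = _simple_params(
            c_l=np.full(3, 333.0), c_r=np.full(3, 333.0)
        )
        for x in ([10, 100, 200, 300], [90, 190, 290, 30]):
            assert predict(np.array(x, float), params).value == pytest.approx(333.0)

    def test_consequent_shift_shifts_output(self):
        params = _simple_params()
        x = np.array([90.0, 190.0, 290.0, 90.0])
        y0 = predict(x, params).value
        shifted = _simple_params(c_l=params.c_l + 25.0, c_r=params.c_r + 25.0)
        assert predict(x, shifted).value == pytest.approx(y0 + 25.0)

    def test_output_within_consequent_hull(self, rng):
        params = _simple_params()
        for _ in range(200):
            x = rng.uniform(0.0, 360.0, 4)
            y = predict(x, params).value
            assert params.c_l.min() <= y <= params.c_r.max()

    def test_batch_agrees_with_scalar_path(self, rng):
        params = _simple_params()
        X = rng.uniform(50.0, 320.0, (40, 4))
        batch = predict_batch(X, params)
        scalar = np.array([predict(x, params).value for x in X])
        np.testing.assert_allclose(batch, scalar, atol=1e-12)

    def test_zero_width_fou_collapses_to_type1(self, rng):
        """With m_low == m_high and c_l == c_r the system is an ordinary
        type-1 Sugeno-style model; check against a direct evaluation."""
        m = np.tile([80.0, 180.0, 280.0], (4, 1))
        sigma = np.full((4, 3), 50.0)
        c = np.array([300.0, 340.0, 380.0])
        params = IT2FParams(m_low=m, m_high=m, sigma=sigma, c_l=c, c_r=c)
        for _ in range(50):
            x = rng.uniform(0.0, 360.0, 4)
            g = np.exp(-0.5 * ((x[:, None] - m) / sigma) ** 2)
            f = g.prod(axis=0)
            expected = float(f @ c / f.sum())
            assert predict(x, params).value == pytest.approx(expected, abs=1e-9)

    def test_accepts_phase_lag_vector(self):
        params = _simple_params()
        plv = PhaseLagVector(
            lags={0.0: 90.0, 90.0: 190.0, 180.0: 290.0, 270.0: 30.0}, node_id=0
        )
        assert predict(plv, params).value > 0


class TestParams:
    def test_vector_codec_round_trip(self, rng):
        vec = rng.uniform(0.0, 1.0, N_PARAMS) * 300 + 10
        params = IT2FParams.from_vector(vec, repair=True)
        back = IT2FParams.from_vector(params.to_vector())
        np.testing.assert_array_equal(params.to_vector(), back.to_vector())

    def test_json_round_trip_exact(self, tmp_path, rng):
        params = IT2FParams.from_vector(
            rng.uniform(10.0, 300.0, N_PARAMS), repair=True
        )
        path = tmp_path / "params.json"
        params.to_json(path)
        loaded = IT2FParams.from_json(path)
        np.testing.assert_array_equal(params.to_vector(), loaded.to_vector())

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            _simple_params(sigma=np.full((4, 3), -1.0))
        with pytest.raises(ValueError):
            _simple_params(c_l=np.array([400.0, 320.0, 360.0]))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    f=st.lists(
        st.tuples(
            st.floats(0.0, 1.0, allow_nan=False),
            st.floats(0.01, 1.0, allow_nan=False),
        ),
        min_size=2,
        max_size=5,
    ),
    c=st.lists(
        st.tuples(
            st.floats(200.0, 600.0, allow_nan=False),
            st.floats(0.0, 100.0, allow_nan=False),
        ),
        min_size=2,
        max_size=5,
    ),
)
def test_type_reduction_interval_property(f, c):
    """y_l <= y_r and both lie inside the consequent hull, for arbitrary
    valid firing intervals."""
    n = min(len(f), len(c))
    f_high = np.array([max(a * b, 1e-6) for a, b in f[:n]])
    f_low = f_high * np.array([a for a, _ in f[:n]])
    c_l = np.array([a for a, _ in c[:n]])
    c_r = c_l + np.array([b for _, b in c[:n]])
    y_l, y_r = type_reduce_cos((f_low, f_high), (c_l, c_r))
    assert y_l <= y_r + 1e-9
    assert c_l.min() - 1e-9 <= y_l and y_r <= c_r.max() + 1e-9
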