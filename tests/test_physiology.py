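"""Discrimination, iWUE and oxygen-isotope equations against independent
brute-force evaluation and their algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoring.exceptions import DomainError, InsufficientDataError
from isoring.physiology import (
    DEFAULT_CONSTANTS,
    FractionationConstants,
    carbon_discrimination,
    ci_from_discrimination,
    iwue,
    oxygen_discrimination,
    predict_d18op,
    relative_change,
)

A, B = DEFAULT_CONSTANTS.a, DEFAULT_CONSTANTS.b

# independently coded brute-force forms of the five equations
brute_delta13c = lambda da, dw: (da - dw) / (1 + dw / 1000)
brute_ci = lambda ca, d: ca * (d - 4.4) / (27 - 4.4)
brute_iwue = lambda ca, d: (ca - brute_ci(ca, d)) / 1.6
brute_delta18o = lambda w, s: (w - s) / (1 + s / 1000)
brute_d18op = lambda t, p, e: (
    0.52 * t - 0.006 * t * t + 2.42 * p - 1.43 * p * p - 0.046 * e**0.5 - 13.0
)


@pytest.mark.parametrize(
    "da, dw, expected",
    [(-8.3, -8.3, 0.0), (-8.3, -26.0, 18.172), (-8.0, -27.3, 19.842)],
)
def test_carbon_discrimination_values(da, dw, expected):
    assert carbon_discrimination(da, dw) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize(
    "ca, delta, expected_ci",
    [(390.0, 4.4, 0.0), (390.0, 27.0, 390.0), (390.0, 18.172, 237.66)],
)
def test_ci_from_discrimination_values(ca, delta, expected_ci):
    assert ci_from_discrimination(ca, delta) == pytest.approx(expected_ci, abs=5e-3)


@pytest.mark.parametrize(
    "ca, delta, expected",
    [(390.0, 27.0, 0.0), (390.0, 4.4, 243.75), (390.0, 18.172, 95.2135)],
)
def test_iwue_values(ca, delta, expected):
    assert iwue(ca, delta) == pytest.approx(expected, abs=5e-3)


@pytest.mark.parametrize(
    "t, p, e, expected",
    [(0.0, 0.0, 0.0, -13.0), (9.7, 0.662, 80.0, -7.96), (8.1, 0.796, 400.0, -9.08)],
)
def test_predict_d18op_values(t, p, e, expected):
    assert predict_d18op(t, p, e) == pytest.approx(expected, abs=5e-3)


@pytest.mark.parametrize(
    "w, s, expected",
    [(30.0, 30.0, 0.0), (30.0, -8.0, 38.31), (28.5, 0.0, 28.5)],
)
def test_oxygen_discrimination_values(w, s, expected):
    assert oxygen_discrimination(w, s) == pytest.approx(expected, abs=5e-3)


def test_domain_errors():
    with pytest.raises(DomainError):
        carbon_discrimination(-8.0, -1000.0)
    with pytest.raises(DomainError):
        oxygen_discrimination(30.0, -1000.0)
    with pytest.raises(DomainError):
        predict_d18op(10.0, 0.7, -5.0)
    with pytest.raises(DomainError):
        ci_from_discrimination(-1.0, 18.0)
    with pytest.raises(DomainError):
        FractionationConstants(a=30.0, b=27.0)


def test_unit_confusion_warning():
    with pytest.warns(UserWarning, match="metres"):
        predict_d18op(10.0, 700.0, 80.0)


def test_out_of_range_discrimination_flagged_not_clipped():
    with pytest.warns(UserWarning, match="outside"):
        ci = ci_from_discrimination(390.0, 30.0)
    assert ci > 390.0  # unclipped


def test_equation_oracle_equivalence():
    """1000 random tuples agree with the brute-force evaluator to 1e-10."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        da = rng.uniform(-9.0, -6.5)
        dw = rng.uniform(-30.0, -20.0)
        ca = rng.uniform(300.0, 420.0)
        w = rng.uniform(20.0, 35.0)
        s = rng.uniform(-12.0, 0.0)
        t = rng.uniform(0.0, 15.0)
        p = rng.uniform(0.3, 1.5)
        e = rng.uniform(0.0, 600.0)
        d = carbon_discrimination(da, dw)
        assert abs(d - brute_delta13c(da, dw)) < 1e-10
        assert abs(ci_from_discrimination(ca, d) - brute_ci(ca, d)) < 1e-10
        assert abs(iwue(ca, d) - brute_iwue(ca, d)) < 1e-10
        assert abs(oxygen_discrimination(w, s) - brute_delta18o(w, s)) < 1e-10
        assert abs(predict_d18op(t, p, e) - brute_d18op(t, p, e)) < 1e-10


@given(
    ca=st.floats(200.0, 500.0),
    delta=st.floats(0.0, 27.0),
)
@settings(max_examples=200, derandomize=True)
def test_iwue_identity_with_ci(ca, delta):
    """iWUE == (c_a − c_i)/1.6 exactly (algebraic identity)."""
    ci = ci_from_discrimination(ca, delta) if delta >= A else ca * (delta - A) / (B - A)
    assert iwue(ca, delta) == pytest.approx((ca - ci) / 1.6, abs=1e-9)


@given(
    da=st.floats(-10.0, -6.0),
    dw1=st.floats(-35.0, -15.0),
    dw2=st.floats(-35.0, -15.0),
)
@settings(max_examples=200, derandomize=True)
def test_discrimination_monotone_decreasing_in_wood_delta(da, dw1, dw2):
    if dw1 == dw2:
        return
    lo, hi = sorted([dw1, dw2])
    assert carbon_discrimination(da, lo) > carbon_discrimination(da, hi)


@given(delta=st.floats(-5.0, 35.0), ca=st.floats(250.0, 450.0))
@settings(max_examples=200, derandomize=True)
def test_ci_ratio_bounds_iff_delta_in_fractionation_band(delta, ca):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratio = ci_from_discrimination(ca, delta) / ca
    assert (0.0 <= ratio <= 1.0) == (A <= delta <= B)


@given(w=st.floats(20.0, 35.0), s=st.floats(-1.0, 1.0))
@settings(max_examples=200, derandomize=True)
def test_oxygen_discrimination_small_source_limit(w, s):
    """Δ18O → (w − s) as source δ → 0, with error O(s(w−s)/1000)."""
    err = abs(oxygen_discrimination(w, s) - (w - s))
    assert err <= abs(s * (w - s)) / 1000.0 * 1.01 + 1e-12


def test_relative_change():
    years = [1980, 1995, 2010]
    assert relative_change(years, [80.0, 88.0, 96.0]) == pytest.approx(0.20)
    assert relative_change(years, [100.0, 150.0, 200.0]) == pytest.approx(1.0)
    assert relative_change(years, [5.0, 5.0, 5.0]) == 0.0
    with pytest.raises(InsufficientDataError, match="2010"):
        relative_change([1980, 1990], [1.0, 2.0])
    with pytest.raises(DomainError):
        relative_change(years, [0.0, 1.0, 2.0])
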