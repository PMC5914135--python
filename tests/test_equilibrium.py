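"""Mass balance of the competing dimerization + nucleation-elongation model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suprafit import (
    ObservableCoefficients,
    ThermoParams,
    elongation_concentration,
    free_monomer,
    observable_series,
    species_distribution,
    truncated_sum_oracle,
)
from suprafit.equilibrium import _mass_balance_total


def test_no_aggregation_limit_recovers_ct():
    params = ThermoParams(K_J1=1e-12, K_N=1e-12, K_J2=1e-12)
    for c in (1e-7, 1e-5, 1e-3):
        assert free_monomer(params, c) == pytest.approx(c, rel=1e-6)


def test_isodesmic_limit_closed_form():
    # with K_N = K_J2 = K and no dimer pathway, c_T = m/(1-Km)^2, so at
    # c_T*K = 1 the scaled monomer Km solves a quadratic: Km = (3-sqrt(5))/2
    K = 1e5
    params = ThermoParams(K_J1=1e-30, K_N=K, K_J2=K)
    m = free_monomer(params, 1e-5)
    assert K * m == pytest.approx((3.0 - np.sqrt(5.0)) / 2.0, rel=1e-9)
    assert m == pytest.approx(3.8197e-6, rel=1e-4)


def test_study_constants_monomer_and_trace_polymer(study_params):
    # below the elongation concentration the dimer pathway dominates:
    # neglecting the polymer term gives the quadratic root
    # m = (sqrt(1 + 8 K_J1 c) - 1) / (4 K_J1) ~ 8.236e-6 M at c_T = 1e-5 M
    m = free_monomer(study_params, 1e-5)
    assert m == pytest.approx(8.236e-6, rel=1e-3)
    dist = species_distribution(study_params, 1e-5)
    assert dist.phi_polymer < 1e-4


def test_dilution_limit_is_monomeric(study_params):
    assert species_distribution(study_params, 1e-12).phi_mono > 0.999


def test_polymer_overtakes_dimer_above_onset(study_params):
    dist = species_distribution(study_params, 3e-5)
    assert dist.phi_polymer > dist.phi_dimer


@given(
    st.floats(min_value=0.0, max_value=8.0),   # log10 K_J1
    st.floats(min_value=-3.0, max_value=5.0),  # log10 K_N
    st.floats(min_value=2.0, max_value=7.0),   # log10 K_J2
    st.floats(min_value=0.01, max_value=0.9),  # x = K_J2 * m
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_closed_form_matches_truncated_series(lk1, lkn, lk2, x):
    params = ThermoParams(10**lk1, 10**lkn, 10**lk2)
    m = x / params.K_J2
    closed = _mass_balance_total(params, m)
    oracle = truncated_sum_oracle(params, m, 500)
    assert oracle.last_term <= 1e-12 * closed
    assert oracle.total == pytest.approx(float(closed), rel=1e-10)


def test_truncated_sum_two_terms(study_params):
    m = 1e-6
    expected = m + 2 * study_params.K_J1 * m**2 + 2 * study_params.K_N * m**2
    assert truncated_sum_oracle(study_params, m, 2).total == pytest.approx(
        expected, rel=1e-14)


def test_truncated_sum_diverges_at_unit_x(study_params):
    with pytest.raises(ValueError, match="diverges"):
        truncated_sum_oracle(study_params, 2.0 / study_params.K_J2, 10)


@given(st.floats(min_value=-7.5, max_value=-4.0))
@settings(max_examples=40, derandomize=True, deadline=None)
def test_fractions_sum_to_one_and_monomer_monotone(log_ct):
    params = ThermoParams(1.3e4, 2.4e-2, 1.0e5)
    c = 10.0**log_ct
    dist = species_distribution(params, c)
    assert dist.phi_mono + dist.phi_dimer + dist.phi_polymer == pytest.approx(
        1.0, abs=1e-9)
    assert dist.dp_n >= 2.0
    # strict monotonicity of free monomer in total concentration
    assert free_monomer(params, 1.02 * c) > free_monomer(params, c)


def test_polymer_fraction_nondecreasing(study_params):
    grid = np.geomspace(1e-8, 5e-5, 40)
    phi_p = np.array([species_distribution(study_params, c).phi_polymer
                      for c in grid])
    assert np.all(np.diff(phi_p) >= -1e-12)


def test_cooperative_sharpness():
    # sigma <= 1e-6: polymer rises from <1% to >50% within one decade of 1/K
    params = ThermoParams(K_J1=1e-30, K_N=1e-1, K_J2=1e5)
    assert params.sigma <= 1e-6
    ce = elongation_concentration(params)
    low = species_distribution(params, ce / np.sqrt(10.0)).phi_polymer
    high = species_distribution(params, ce * np.sqrt(10.0)).phi_polymer
    assert low < 0.01
    assert high > 0.5


def test_elongation_concentration(study_params):
    assert elongation_concentration(study_params) == pytest.approx(1e-5)
    assert elongation_concentration(study_params) < 1.2e-5  # printed onset
    doubled = ThermoParams(study_params.K_J1, study_params.K_N,
                           2 * study_params.K_J2)
    assert elongation_concentration(doubled) == pytest.approx(5e-6)


class TestObservableSeries:
    def test_degenerate_coefficients_constant(self, study_params):
        coeffs = ObservableCoefficients(2.0, 2.0, 2.0, 0.5, 0.5, 0.5)
        series = observable_series(study_params, coeffs,
                                   np.geomspace(1e-7, 3e-5, 9))
        np.testing.assert_allclose(series["epsilon_obs"], 2.0, rtol=1e-9)
        np.testing.assert_allclose(series["delta_epsilon_obs"], 0.5, rtol=1e-9)

    def test_monomer_dominated_regime(self, study_params, coeffs):
        series = observable_series(study_params, coeffs, [5e-7])
        assert series["epsilon_obs"].iloc[0] == pytest.approx(
            coeffs.eps_mono, abs=0.02 * max(coeffs.eps, key=abs))

    def test_convex_combination_bounds(self, study_params, coeffs):
        series = observable_series(study_params, coeffs,
                                   np.geomspace(5e-7, 3e-5, 15))
        assert (series["epsilon_obs"] >= min(coeffs.eps) - 1e-12).all()
        assert (series["epsilon_obs"] <= max(coeffs.eps) + 1e-12).all()


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ThermoParams(K_J1=-1.0, K_N=1.0, K_J2=1.0)
    with pytest.raises(ValueError):
        ThermoParams(K_J1=1.0, K_N=1.0, K_J2=1.0, T=0.0)
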