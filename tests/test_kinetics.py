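"""Kinetic schemes and their analytic properties."""

import numpy as np
import pytest
import scipy.integrate
from hypothesis import given, settings, strategies as st

import flipkin as fk
from flipkin.kinetics import (
    ExchangeParams,
    FaceKinetics,
    FlippingParams,
    face_occupancy,
    heterotypic_flipping_params,
    hexasome_flipping_params,
)


@pytest.mark.parametrize(
    "params, composition, n_states",
    [
        (FlippingParams(), "canonical", 4),
        (heterotypic_flipping_params(), "heterotypic", 3),
        (hexasome_flipping_params(), "hexasome", 3),
    ],
)
def test_flipping_scheme_structure(params, composition, n_states):
    scheme = fk.build_flipping_scheme(params, composition)
    assert scheme.n_states == n_states
    assert np.abs(scheme.rate_matrix.sum(axis=1)).max() < 1e-12
    off = scheme.rate_matrix.copy()
    np.fill_diagonal(off, 0.0)
    assert (off >= 0).all()
    assert abs(scheme.entry_distribution.sum() - 1.0) < 1e-9
    assert set(scheme.fret_class.values()) == {"distal", "proximal"}


def test_heterotypic_distal_exit_rate_is_reciprocal_lifetime():
    # the Htz1-containing face decays as a single 0.63-s exponential
    scheme = fk.build_flipping_scheme(heterotypic_flipping_params(), "heterotypic")
    i = scheme.index("distal")
    assert scheme.rate_matrix[i, i] == pytest.approx(-1.0 / 0.63)


def test_degenerate_entry_probability_gives_single_exponential_face():
    params = FlippingParams(
        distal=FaceKinetics(tau_slow=3.0, tau_fast=0.5, p_slow_entry=1.0),
        proximal=FaceKinetics(),
    )
    t = np.linspace(0, 20, 200)
    f = fk.face_dwell_density(params, "distal", t)
    assert np.allclose(f, np.exp(-t / 3.0) / 3.0)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        FaceKinetics(tau_slow=-1.0)
    with pytest.raises(ValueError):
        FlippingParams(fraction_dynamic=0.9, fraction_static_distal=0.9,
                       fraction_static_proximal=0.2)
    with pytest.raises(ValueError):
        fk.build_flipping_scheme(FlippingParams(), "octasome")
    with pytest.raises(ValueError):
        ExchangeParams(k_ex1=-1.0)


def test_stationary_distribution_solves_pi_Q():
    scheme = fk.build_flipping_scheme(FlippingParams())
    pi = fk.stationary_distribution(scheme)
    assert np.abs(pi @ scheme.rate_matrix).max() < 1e-10
    assert pi.sum() == pytest.approx(1.0)
    # symmetric canonical scheme: each face occupies half the time
    occ = face_occupancy(scheme)
    assert occ["distal"] == pytest.approx(0.5, abs=1e-9)
    # ~80% of bound time in the engaged (slow) sub-states
    slow = pi[scheme.index("distal_slow")] + pi[scheme.index("proximal_slow")]
    assert slow == pytest.approx(0.80, abs=0.005)


def test_heterotypic_occupancy_matches_renewal_ratio():
    # alternating renewal: time fraction = mean dwell ratio, with the
    # proximal mean dwell A1*tau1 + A2*tau2 = 2.159 s vs distal 0.63 s
    occ = face_occupancy(fk.build_flipping_scheme(heterotypic_flipping_params(), "heterotypic"))
    expected = 2.1592 / (2.1592 + 0.63)
    assert occ["proximal"] == pytest.approx(expected, abs=1e-3)


def test_stationary_occupancy_matches_long_gillespie_run():
    scheme = fk.build_flipping_scheme(FlippingParams())
    pi = fk.stationary_distribution(scheme)
    path = fk.sample_state_path(scheme, 5e4, seed=7)
    knots = np.append(path.times, path.duration)
    occ = np.zeros(scheme.n_states)
    np.add.at(occ, path.states, np.diff(knots))
    occ /= occ.sum()
    assert np.abs(occ - pi).max() < 0.01


def test_reducible_chain_reports_absorbing_component():
    scheme = fk.build_exchange_scheme(ExchangeParams())
    with pytest.raises(ValueError, match="final"):
        fk.stationary_distribution(scheme)


def test_face_dwell_density_closed_form_mean():
    params = FlippingParams()
    t = np.linspace(0, 200, 400001)
    f = fk.face_dwell_density(params, "distal", t)
    mean = np.trapezoid(t * f, t)
    assert mean == pytest.approx(0.384 * 4.5 + 0.616 * 0.7, abs=1e-3)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    tau_slow=st.floats(0.5, 20.0),
    tau_fast=st.floats(0.05, 0.5),
    p=st.floats(0.0, 1.0),
)
def test_face_dwell_density_normalized(tau_slow, tau_fast, p):
    params = FlippingParams(distal=FaceKinetics(tau_slow, tau_fast, p))
    total, _ = scipy.integrate.quad(
        lambda t: float(fk.face_dwell_density(params, "distal", t)), 0, np.inf
    )
    assert total == pytest.approx(1.0, abs=1e-6)


class TestTauAve:
    def test_single_component_returns_tau1(self):
        assert fk.tau_ave(1.0, 2.5, 0.0, 1.0) == pytest.approx(2.5)

    def test_canonical_value(self):
        assert fk.tau_ave(0.384, 4.5, 0.616, 0.7) == pytest.approx(3.741, abs=1e-3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a1=st.floats(0.01, 0.99), tau=st.floats(0.1, 50.0), c=st.floats(0.1, 10.0))
    def test_equal_lifetimes_and_scale_invariance(self, a1, tau, c):
        assert fk.tau_ave(a1, tau, 1 - a1, tau) == pytest.approx(tau)
        assert fk.tau_ave(c * a1, 3.0, c * (1 - a1), 0.5) == pytest.approx(
            fk.tau_ave(a1, 3.0, 1 - a1, 0.5)
        )

    def test_undefined_for_zero_amplitudes(self):
        with pytest.raises(ValueError):
            fk.tau_ave(0.0, 1.0, 0.0, 1.0)

    def test_equals_survival_weighted_mean_by_quadrature(self):
        a1, t1, a2, t2 = 0.384, 4.5, 0.616, 0.7
        w = lambda t: a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)
        num, _ = scipy.integrate.quad(lambda t: t * w(t), 0, np.inf, epsabs=1e-12)
        den, _ = scipy.integrate.quad(w, 0, np.inf, epsabs=1e-12)
        assert fk.tau_ave(a1, t1, a2, t2) == pytest.approx(num / den, abs=1e-8)


class TestSelectivity:
    def test_identical_fits_give_unity(self):
        assert fk.selectivity(3.74, 3.74) == pytest.approx(1.0)

    def test_heterotypic_sixfold(self):
        assert fk.selectivity(3.741, 0.63) == pytest.approx(5.94, abs=0.01)

    def test_antisymmetry(self):
        assert fk.selectivity(2.0, 4.0) == pytest.approx(1.0 / fk.selectivity(4.0, 2.0))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fk.selectivity(1.0, 0.0)


class TestExchangeScheme:
    def test_no_loss_means_fully_processive(self):
        assert ExchangeParams(k_loss=0.0).processive_fraction == pytest.approx(1.0)

    def test_default_processive_fraction(self):
        assert ExchangeParams().processive_fraction == pytest.approx(0.57, abs=0.001)

    def test_first_exchange_split(self):
        p = ExchangeParams(p_first_proximal=0.55)
        scheme = fk.build_exchange_scheme(p)
        i = scheme.index("bound_pre")
        to_p = scheme.rate_matrix[i, scheme.index("bound_intermediate_p")]
        to_d = scheme.rate_matrix[i, scheme.index("bound_intermediate_d")]
        assert to_p / (to_p + to_d) == pytest.approx(0.55)
        assert to_p + to_d == pytest.approx(p.k_ex1)

    def test_single_exchange_variant(self):
        scheme = fk.build_exchange_scheme(fk.heterotypic_exchange_params())
        assert scheme.state_labels == ["unbound_pre", "bound_pre", "final"]
        assert scheme.rate_matrix[1, 2] == pytest.approx(1.0 / 100.0)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            ExchangeParams(k_ex1=0, k_ex2=0, k_loss=0, k_bind=0, k_rebind=0)

    def test_non_monotone_fret_levels_rejected(self):
        with pytest.raises(ValueError):
            ExchangeParams(fret_levels={"pre": 0.5, "intermediate_distal": 0.4,
                                        "intermediate_proximal": 0.6, "final": 0.8})


def test_scheme_json_round_trip():
    scheme = fk.build_flipping_scheme(FlippingParams())
    back = fk.KineticScheme.from_json(scheme.to_json())
    assert back.state_labels == scheme.state_labels
    assert np.allclose(back.rate_matrix, scheme.rate_matrix)
    assert back.fret_class == scheme.fret_class
    assert back.bound_states == scheme.bound_states
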