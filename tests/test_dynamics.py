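"""Coherent hole dynamics: probabilities, time averages, rates, dipoles."""

import numpy as np
import pytest

from fishbonewire import (
    InitialCondition,
    ValidationError,
    build_hamiltonian,
    default_parameters,
    dipole_moment,
    eigensystem,
    expansion_coefficients,
    first_crossing_time,
    homopolymer_spec,
    mean_probabilities_analytic,
    mean_probabilities_numeric,
    monomer_probability_sums,
    predicted_monomer_sums,
    simulate,
    site_probabilities,
    transfer_rates,
)
from fishbonewire.dynamics import default_time_grid, to_atomic_units

from conftest import TWO_LEVEL_FREQ_HZ


def test_expansion_coefficients_are_eigenvector_row(g10_ts1):
    _, es = g10_ts1
    for alpha in (1, 2, 17, 30):
        c = expansion_coefficients(es, alpha)
        np.testing.assert_array_equal(c, es.eigenvectors[alpha - 1])
        assert c @ c == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        expansion_coefficients(es, 31)


def test_monomer_state_avoids_antisymmetric_sugar_level():
    """A hole on the base pair never populates the E_S eigenstate (N=1)."""
    p = default_parameters(0.5)
    es = eigensystem(build_hamiltonian(homopolymer_spec("G", 1), p))
    c = expansion_coefficients(es, 2)
    k_es = int(np.argmin(np.abs(es.eigenvalues - 9.0)))
    assert abs(c[k_es]) < 1e-12


def test_initial_condition_and_unitarity(g10_ts1):
    h, es = g10_ts1
    c = expansion_coefficients(es, 2)
    p0 = site_probabilities(es, c, np.array([0.0]), h.params)[:, 0]
    expected = np.zeros(30)
    expected[1] = 1.0
    np.testing.assert_allclose(p0, expected, atol=1e-12)
    times = np.random.default_rng(7).uniform(0, 1e-12, 1000)
    probs = site_probabilities(es, c, times, h.params)
    np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-10)
    assert probs.min() >= -1e-12


def test_two_level_rabi_oscillation(gg_two_level):
    """GG dimer, t_S=0: transfer follows sin^2(pi f t) with f = 0.2 eV / h."""
    h, es, c = gg_two_level
    t = np.linspace(0.0, 3.0 / TWO_LEVEL_FREQ_HZ, 500)
    probs = site_probabilities(es, c, t, h.params)
    np.testing.assert_allclose(probs[4], np.sin(np.pi * TWO_LEVEL_FREQ_HZ * t) ** 2,
                               atol=1e-8)
    np.testing.assert_allclose(probs[1], np.cos(np.pi * TWO_LEVEL_FREQ_HZ * t) ** 2,
                               atol=1e-8)


def test_two_level_crossing_time_and_rate(gg_two_level):
    """sin^2 reaches its mean 1/2 first at t = 1/(4f); k = 0.5 / t."""
    h, es, c = gg_two_level
    rates = transfer_rates(es, c, 2, h.params)
    t_expected = 1.0 / (4.0 * TWO_LEVEL_FREQ_HZ)
    assert rates.crossing_times[4] == pytest.approx(t_expected, rel=1e-6)
    assert rates.rates[4] == pytest.approx(0.5 / t_expected, rel=1e-6)
    assert rates.unreachable[[0, 2, 3, 5]].all()  # sugars decoupled at t_S=0
    assert (rates.rates[[0, 2, 3, 5]] == 0.0).all()


def test_mean_probabilities_analytic_vs_numeric():
    for ts, alpha in ((0.5, 2), (1.0, 3)):
        p = default_parameters(ts)
        es = eigensystem(build_hamiltonian(homopolymer_spec("G", 6), p))
        c = expansion_coefficients(es, alpha)
        ana = mean_probabilities_analytic(es, c)
        num = mean_probabilities_numeric(es, c, p)
        np.testing.assert_allclose(ana, num, atol=1e-3)
        assert ana.sum() == pytest.approx(1.0, abs=1e-10)
        assert ana.min() >= 0.0


def test_eigenstate_initial_condition_is_stationary():
    p = default_parameters(0.7)
    es = eigensystem(build_hamiltonian(homopolymer_spec("G", 3), p))
    c = np.zeros(9)
    c[4] = 1.0  # a single eigenstate
    times = np.linspace(0, 1e-13, 50)
    probs = site_probabilities(es, c, times, p)
    np.testing.assert_allclose(probs, np.repeat(probs[:, :1], 50, axis=1), atol=1e-12)
    np.testing.assert_allclose(mean_probabilities_numeric(es, c, p),
                               probs[:, 0], atol=1e-9)


def test_no_transfer_from_sugar_without_coupling():
    """t_S = 0, hole on a sugar: it stays there forever."""
    p = default_parameters(0.0)
    es = eigensystem(build_hamiltonian(homopolymer_spec("G", 10), p))
    c = expansion_coefficients(es, 3)
    means = mean_probabilities_analytic(es, c)
    assert means[2] == pytest.approx(1.0)
    assert np.abs(np.delete(means, 2)).max() < 1e-12
    rates = transfer_rates(es, c, 3, p)
    assert rates.unreachable[np.arange(30) != 2].all()


@pytest.mark.parametrize("n", range(2, 11))
@pytest.mark.parametrize("ts", [0.1, 0.5, 1.0, 2.0])
def test_monomer_sums_match_closed_form(n, ts):
    """Dynamics-derived monomer sums equal the closed-form psi/chi/omega/phi."""
    p = default_parameters(ts)
    h = build_hamiltonian(homopolymer_spec("G", n), p)
    es = eigensystem(h)
    for alpha, kind in ((2, "base-pair"), (3, "sugar")):
        c = expansion_coefficients(es, alpha)
        sums = monomer_probability_sums(mean_probabilities_analytic(es, c), h.site_map)
        np.testing.assert_allclose(sums, predicted_monomer_sums(n, kind).per_monomer,
                                   atol=1e-6)


def test_palindromicity_of_base_pair_start(g10_ts1):
    h, es = g10_ts1
    c = expansion_coefficients(es, 2)
    sums = monomer_probability_sums(mean_probabilities_analytic(es, c), h.site_map)
    np.testing.assert_allclose(sums, sums[::-1], atol=1e-9)


def test_monomer_sum_ratio_law():
    """First-monomer ratio (alpha=2 over alpha=3) is 6/(2N+5); others are 1/2."""
    for n in (4, 7, 10):
        bp = predicted_monomer_sums(n, "base-pair").per_monomer
        sg = predicted_monomer_sums(n, "sugar").per_monomer
        assert bp[0] / sg[0] == pytest.approx(6.0 / (2 * n + 5))
        np.testing.assert_allclose(bp[1:] / sg[1:], 2.0)


def test_predicted_monomer_sums_values_and_normalization():
    bp = predicted_monomer_sums(10, "base-pair")
    assert (bp.first, bp.middle, bp.last) == pytest.approx((3/22, 1/11, 3/22))
    sg = predicted_monomer_sums(10, "sugar")
    assert (sg.first, sg.middle, sg.last) == pytest.approx((25/44, 1/22, 3/44))
    for kind in ("base-pair", "sugar"):
        assert predicted_monomer_sums(10, kind).per_monomer.sum() == pytest.approx(1.0)
    central = predicted_monomer_sums(9, "base-pair", central=True)
    assert central.per_monomer[4] == pytest.approx(2 / 10)
    assert central.per_monomer.sum() == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        predicted_monomer_sums(1, "base-pair")
    with pytest.raises(ValidationError):
        predicted_monomer_sums(10, "base-pair", central=True)


def test_first_crossing_time_on_traces():
    times = np.linspace(0.0, 1.0, 101)
    assert first_crossing_time(times, np.full(101, 0.3), 0.3) == 0.0
    trace = times.copy()  # linear ramp crosses 0.5 at t=0.5
    assert first_crossing_time(times, trace, 0.5) == pytest.approx(0.5)
    assert first_crossing_time(times, trace, 2.0) is None


def test_rate_decreases_with_length():
    from fishbonewire import end_to_end_rate_series
    k = end_to_end_rate_series("G", range(2, 11), 0.5, alpha=2)
    assert np.all(np.diff(k) < 0)


def test_dipole_moment(g10_ts1):
    h, es = g10_ts1
    times = default_time_grid(es, h.params)[:2000]
    c2 = expansion_coefficients(es, 2)
    probs = site_probabilities(es, c2, times, h.params)
    px, py = dipole_moment(probs, h.site_map, h.params)
    assert np.abs(py).max() < 1e-10                    # symmetric across strands
    assert px[0] == pytest.approx(3.4 * (1 - 5.5))     # -15.3 e*Å at t=0
    c3 = expansion_coefficients(es, 3)
    probs3 = site_probabilities(es, c3, times, h.params)
    px3, _ = dipole_moment(probs3, h.site_map, h.params)
    assert px3.max() < 0.0          # carrier stays in the negative-x half
    _, py_e = dipole_moment(probs3, h.site_map, h.params, carrier="electron")
    _, py_h = dipole_moment(probs3, h.site_map, h.params, carrier="hole")
    np.testing.assert_allclose(py_e, -py_h)
    assert to_atomic_units(np.array([0.529177210903])) == pytest.approx(1.0)


def test_simulate_bundles_everything():
    p = default_parameters(0.5)
    h = build_hamiltonian(homopolymer_spec("G", 4), p)
    res = simulate(h, alpha=2)
    assert res.probabilities.shape[0] == 12
    np.testing.assert_allclose(res.probabilities.sum(axis=0), 1.0, atol=1e-10)
    assert res.mean_probabilities.sum() == pytest.approx(1.0)
    assert res.rates.total > 0
    assert np.isnan(res.rates.rates[1])  # the initial site has no rate
    InitialCondition(2).validate(12)
    with pytest.raises(ValidationError):
        InitialCondition(13).validate(12)
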