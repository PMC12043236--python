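"""Epileptor vector field, integrator and excitability regimes."""

import numpy as np
import pytest

from epicohort.dynamics import (EpileptorParameters, NetworkModelSpec,
                                StimulationExtensionParameters,
                                classify_regime, coupling_term,
                                epileptor_deriv, integrate, resting_x1,
                                seizure_onset_boundary, stim_epileptor_deriv,
                                up_state_boundary)


def _state(*vals):
    return np.array(vals, dtype=float).reshape(len(vals), 1)


def test_deriv_hand_evaluation_at_reference_state():
    d = epileptor_deriv(_state(0, 0, 0, 0, 3, 0),
                        EpileptorParameters(x0=-1.6), 0.0)
    assert np.allclose(d.ravel(), [0.1, 1.0, 0.6, 0.15, 0.00119, 0.0])


def test_deriv_piecewise_branches():
    p = EpileptorParameters(x0=-1.6)
    # x1 = -1: cubic branch, f1 = a(-1)^3 - b(-1)^2 = -4
    d = epileptor_deriv(_state(-1, 0, 0, 0, 0, 0), p, 0.0)
    assert np.isclose(d[0, 0], 0 - (-4) - 0 + 3.1)
    # x2 = -0.3: f2 = 0 so dy2 = -y2 / tau
    d = epileptor_deriv(_state(0, 0, -0.3, 2.0, 0, 0), p, 0.0)
    assert np.isclose(d[3, 0], -2.0 / 10.0)
    # z = 1: f3 = 0; z = -1: f3 = 0.1 adds to dz
    d_pos = epileptor_deriv(_state(0, 0, 0, 0, 1, 0), p, 0.0)
    assert np.isclose(d_pos[4, 0], 0.00035 * (4 * 1.6 - 1))
    d_neg = epileptor_deriv(_state(0, 0, 0, 0, -1, 0), p, 0.0)
    assert np.isclose(d_neg[4, 0], 0.00035 * (4 * 1.6 + 1 + 0.1))


def test_stim_deriv_reduces_to_base_without_stimulus():
    p = EpileptorParameters(x0=-2.2)
    sp = StimulationExtensionParameters()
    state7 = _state(-1.3, -7.0, -0.2, 0.1, 3.0, -0.1, 0.0)
    d7 = stim_epileptor_deriv(state7, p, sp, 0.0, 0.0)
    d6 = epileptor_deriv(state7[:6], p, 0.0)
    assert np.allclose(d7[:6], d6)
    assert d7[6, 0] == 0.0


def test_stim_deriv_m_accumulation_hand_value():
    p = EpileptorParameters()
    sp = StimulationExtensionParameters()
    state7 = _state(0, 0, 0, 0, 3, 0, 1.0)
    d = stim_epileptor_deriv(state7, p, sp, 0.0, istim=2.0)
    assert np.isclose(d[6, 0], 0.006 * (20 * 2 - 0.3 * 1.0))  # 0.2382


def test_stim_deriv_heaviside_engages_at_threshold():
    p = EpileptorParameters(x0=-2.2)
    sp = StimulationExtensionParameters(mthresh=1.5)
    below = _state(0, 0, 0, 0, 3, 0, 1.49)
    at = _state(0, 0, 0, 0, 3, 0, 1.5)   # H(0) = 1
    dz_below = stim_epileptor_deriv(below, p, sp)[4, 0]
    dz_at = stim_epileptor_deriv(at, p, sp)[4, 0]
    assert np.isclose(dz_at - dz_below, 0.00035 * (-4.0))


def test_coupling_term_hand_cases():
    W = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert np.allclose(coupling_term([0.0, 1.0], W, 2.0), [2.0, -2.0])
    assert np.allclose(coupling_term([0.7, 0.7], W, 5.0), 0.0)
    assert np.allclose(coupling_term([0.0, 1.0], W, 0.0), 0.0)
    with pytest.raises(ValueError):
        coupling_term([0.0, 1.0, 2.0], W, 1.0)


def test_integration_is_deterministic_given_seed():
    spec = NetworkModelSpec(np.zeros((2, 2)), K=0.0,
                            params=EpileptorParameters(x0=[-2.2, -1.6]),
                            noise=0.02, seed=99)
    a = integrate(spec, 2000.0, burn_in_ms=500.0)
    b = integrate(spec, 2000.0, burn_in_ms=500.0)
    assert np.array_equal(a.data, b.data)
    spec2 = NetworkModelSpec(np.zeros((2, 2)), K=0.0,
                             params=EpileptorParameters(x0=[-2.2, -1.6]),
                             noise=0.02, seed=100)
    c = integrate(spec2, 2000.0, burn_in_ms=500.0)
    assert not np.array_equal(a.data, c.data)


def test_stimulation_variant_reduces_to_base_trajectory():
    """With Istim = 0 and m(0) = 0 the 7D model must retrace the 6D one."""
    rng = np.random.default_rng(3)
    W = np.abs(rng.normal(size=(3, 3)))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    W /= W.max()
    p = EpileptorParameters(x0=np.array([-2.2, -1.6, -1.9]))
    base = NetworkModelSpec(W, K=1.0, params=p, noise=0.01, seed=5)
    stim = NetworkModelSpec(W, K=1.0, params=p, noise=0.01, seed=5,
                            stim_params=StimulationExtensionParameters())
    a = integrate(base, 5000.0, burn_in_ms=1000.0, record_every=1)
    b = integrate(stim, 5000.0, burn_in_ms=1000.0, record_every=1)
    assert np.max(np.abs(a.data - b.data[:6])) <= 1e-12
    assert np.max(np.abs(b.var("m"))) == 0.0


def test_divergence_reports_step_index():
    # dt = 0.5 ms is Euler-unstable for this vector field
    spec = NetworkModelSpec(np.zeros((1, 1)), K=0.0,
                            params=EpileptorParameters(x0=-1.6), dt=0.5)
    with pytest.raises(RuntimeError, match="step"):
        integrate(spec, 5000.0, burn_in_ms=0.0)


def test_isolated_regimes_match_excitability():
    """Down state below the critical x0, seizure oscillation above it,
    up-state equilibrium at high x0."""
    labels = classify_regime([-2.2, -1.6, -0.8], duration_ms=60000.0)
    assert labels == ["down", "oscillating", "up"]


def test_onset_boundary_converges_under_step_halving():
    kw = dict(lo=-2.09, hi=-2.03, resolution=0.005, duration_ms=100000.0)
    b1 = seizure_onset_boundary(dt=0.05, **kw)
    b2 = seizure_onset_boundary(dt=0.025, **kw)
    assert abs(b1 - b2) < 0.005


def test_resting_equilibrium_branch():
    # deep down state: x1 well below -4/3; near the up-state birth the
    # equilibrium approaches zero from below
    assert resting_x1(-2.1) < -4 / 3
    assert -0.05 < resting_x1(-1.03) < 0.0
    b = up_state_boundary()
    assert abs(b - (-(1.0 + 3.1) / 4.0)) < 1e-3


def test_noise_requires_valid_shape():
    spec = NetworkModelSpec(np.zeros((2, 2)), noise=np.ones(5))
    with pytest.raises(ValueError):
        spec.noise_vector()
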