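import numpy as np
import pytest
from scipy.linalg import expm

from cmlpipe.lineage import (
    evaluate_feedback,
    rhs_normal,
    integrate,
    find_steady_state,
    analytic_equilibrium,
)
from cmlpipe.params import NormalParameterSet


def test_zero_regulators_return_max(simple_params):
    rates = evaluate_feedback(simple_params, 0.0, 0.0, 0.0)
    assert rates.p0 == simple_params.p0_max
    assert rates.eta1 == simple_params.eta1_max
    assert rates.eta2 == simple_params.eta2_max


def test_unit_feedback_halves(simple_params):
    P = 1.0 / simple_params.gamma1
    rates = evaluate_feedback(simple_params, 0.0, P, 0.0)
    assert rates.p0 == pytest.approx(simple_params.p0_max / 2.0)


def test_characteristic_self_renewal(simple_params):
    # the characteristic effective self-renewal at the reference
    # progenitor level 1e5
    N = 1.0e5
    rates = evaluate_feedback(simple_params, 0.0, N, 0.0)
    expected = simple_params.p0_max / (1.0 + simple_params.gamma1 * N)
    assert rates.p0 == pytest.approx(expected)


def test_negative_inputs_rejected(simple_params):
    with pytest.raises(ValueError):
        evaluate_feedback(simple_params, -1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        evaluate_feedback(simple_params, 0.0, 0.0, 0.0, delta=-0.1)


def test_feedback_monotone_in_regulators(simple_params):
    # each effective rate strictly decreases in its regulator
    grid = np.logspace(2, 7, 12)
    p0 = [evaluate_feedback(simple_params, 0, P, 0).p0 for P in grid]
    e1 = [evaluate_feedback(simple_params, S, 0, 0).eta1 for S in grid]
    e2 = [evaluate_feedback(simple_params, S, 0, 0).eta2 for S in grid]
    p1 = [evaluate_feedback(simple_params, 0, 0, M).p1 for M in grid]
    q1 = [evaluate_feedback(simple_params, 0, 0, M).q1 for M in grid]
    for seq in (p0, e1, e2, p1, q1):
        assert np.all(np.diff(seq) < 0)


def test_extinction_is_fixed_point(simple_params):
    rates = evaluate_feedback(simple_params, 0, 0, 0)
    assert np.all(rhs_normal([0, 0, 0, 0], rates, simple_params) == 0)


def test_balanced_self_renewal_freezes_stem(simple_params):
    rates = evaluate_feedback(simple_params, 0, 0, 0)._replace(p0=0.5)
    dy = rhs_normal([1234.0, 0, 0, 0], rates, simple_params)
    assert dy[0] == 0.0


def test_decoupled_exponential_growth():
    # with vanishing feedback the stem equation is linear:
    # S(t) = S0 exp((2 p0_max - 1) eta1_max t)
    eps = 1e-30
    ps = NormalParameterSet(
        p0_max=0.8, p1_max=0.3, q1_max=0.4, eta1_max=0.05, eta2_max=0.5,
        d_l=0.02, d_m=0.03,
        gamma1=eps, gamma2=eps, gamma3=eps, gamma4=eps, gamma5=eps,
    )
    S0 = 100.0
    t = np.linspace(0, 80, 9)
    traj = integrate([S0, 0, 0, 0], ps, 80.0, t_eval=t, rtol=1e-11, atol=1e-8)
    expected = S0 * np.exp((2 * ps.p0_max - 1) * ps.eta1_max * t)
    assert np.allclose(traj.y[:, 0], expected, rtol=1e-6)


def test_linear_regime_matches_matrix_exponential():
    eps = 1e-30
    ps = NormalParameterSet(
        p0_max=0.7, p1_max=0.3, q1_max=0.4, eta1_max=0.05, eta2_max=0.5,
        d_l=0.02, d_m=0.03,
        gamma1=eps, gamma2=eps, gamma3=eps, gamma4=eps, gamma5=eps,
    )
    p0, p1, q1 = ps.p0_max, ps.p1_max, ps.q1_max
    e1, e2 = ps.eta1_max, ps.eta2_max
    A = np.array(
        [
            [(2 * p0 - 1) * e1, 0, 0, 0],
            [2 * (1 - p0) * e1, (2 * p1 - 1) * e2, 0, 0],
            [0, 2 * q1 * e2, -ps.d_l, 0],
            [0, 2 * (1 - p1 - q1) * e2, 0, -ps.d_m],
        ]
    )
    y0 = np.array([50.0, 20.0, 5.0, 7.0])
    for t in (5.0, 30.0, 90.0):
        traj = integrate(y0, ps, t, t_eval=[t], rtol=1e-11, atol=1e-8)
        expected = expm(A * t) @ y0
        assert np.allclose(traj.final_state, expected, rtol=1e-6)


def test_integrate_validates_inputs(simple_params):
    with pytest.raises(ValueError):
        integrate([1, 0, 0, 0], simple_params, 0.0)
    with pytest.raises(ValueError):
        integrate([-1, 0, 0, 0], simple_params, 10.0)


def test_all_zero_initial_state(simple_params):
    ss, converged = find_steady_state(simple_params, [0, 0, 0, 0])
    assert converged and np.all(ss == 0)


def test_steady_state_fixed_point_identities(simple_params):
    ss, converged = find_steady_state(simple_params, [1e3, 0, 0, 0])
    assert converged
    # progenitor pinned by the stem balance
    Pbar = (2 * simple_params.p0_max - 1) / simple_params.gamma1
    assert ss[1] == pytest.approx(Pbar, rel=1e-6)
    # lymphoid balance
    rates = evaluate_feedback(simple_params, ss[0], ss[1], ss[3])
    assert ss[2] == pytest.approx(
        2 * rates.q1 * rates.eta2 * ss[1] / simple_params.d_l, rel=1e-6
    )
    # myeloid balance
    assert ss[3] == pytest.approx(
        2 * (1 - rates.p1 - rates.q1) * rates.eta2 * ss[1] / simple_params.d_m,
        rel=1e-6,
    )
    # stem influx balances progenitor net self-renewal deficit
    assert rates.eta1 * ss[0] == pytest.approx(
        (1 - 2 * rates.p1) * rates.eta2 * ss[1], rel=1e-6
    )


def test_steady_state_preserved_under_integration(simple_params):
    ss, _ = find_steady_state(simple_params, [1e3, 0, 0, 0])
    traj = integrate(ss, simple_params, 200.0, t_eval=np.linspace(0, 200, 5))
    assert np.allclose(traj.y, ss[None, :], rtol=1e-5)


def test_analytic_equilibrium_matches_integration(simple_params):
    eq = analytic_equilibrium(simple_params)
    ss, converged = find_steady_state(simple_params, [1e3, 0, 0, 0])
    assert converged
    assert np.allclose(eq, ss, rtol=1e-5)


@pytest.mark.parametrize("fraction", [0.1, 0.5, 0.9])
def test_myeloid_depletion_recovers_monotonically(simple_params, fraction):
    ss, _ = find_steady_state(simple_params, [1e3, 0, 0, 0])
    y0 = ss.copy()
    y0[3] *= 1.0 - fraction
    t_eval = np.linspace(0, 600, 121)
    traj = integrate(y0, simple_params, 600.0, t_eval=t_eval)
    tdm = traj.y[:, 3]
    # monotone recovery back to the same equilibrium
    assert np.all(np.diff(tdm) > -1e-6 * ss[3])
    assert traj.final_state == pytest.approx(ss, rel=1e-2)


def test_non_negativity_from_mixed_states(simple_params):
    rng = np.random.default_rng(0)
    for _ in range(5):
        y0 = rng.uniform(0, 1e5, size=4)
        traj = integrate(y0, simple_params, 400.0)
        assert np.all(traj.y >= 0)
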