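"""Kinetic-scheme unit and property tests: generators, propagation,
stationary laws, the pore-block algebra, gating flux and the Gillespie oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kvclamp.scheme import (
    CONDITIONS,
    Condition,
    HIGH_K,
    ND96,
    RateParams,
    StateScheme,
    akv1_scheme,
    build_generator,
    dn_scheme,
    gating_flux,
    gillespie_sample,
    occupancy_from_samples,
    propagate,
    steady_state,
    total_forward_charge,
    two_state_block,
)
from scipy.linalg import expm

ZERO_K = Condition(K_out=0.0)


def _rand_params():
    return RateParams(
        kd=0.3, ku=0.2, kb=0.05, kub=0.01, kci=0.002, kcr=3e-4, theta_push=0.7
    )


class TestGenerator:
    def test_zero_rates_gives_zero_matrix(self):
        scheme = akv1_scheme()
        params = RateParams(a0=0.0, b0=0.0, ko=0.0, kc=0.0)
        Q = build_generator(scheme, params, ND96.at(10.0))
        assert np.all(Q == 0.0)

    def test_two_state_matrix_is_forced_by_definition(self, two_state):
        scheme, params = two_state(0.04, 0.01)
        Q = build_generator(scheme, params, ZERO_K.at(40.0))
        np.testing.assert_allclose(Q, [[-0.04, 0.04], [0.01, -0.01]])

    def test_modulators_are_neutral_without_k_and_zn(self):
        params = _rand_params()
        cond = ZERO_K.at(40.0)
        assert params.rate("kci", cond) == params.kci
        assert params.rate("kub", cond) == params.kub

    def test_k_and_zn_modulators(self):
        params = _rand_params()
        assert params.rate("kci", HIGH_K) < params.rate("kci", ND96) < params.kci
        zn = Condition(K_out=0.0, Zn=params.K_Zn)
        assert params.rate("kci", zn) == pytest.approx(
            params.kci * (1 + params.eta_Zn / 2)
        )
        assert params.rate("kub", HIGH_K) > params.rate("kub", ND96)

    def test_u_type_inverts_k_dependence(self):
        params = RateParams(kci0=1e-3, u_type=True, K_K=98.0)
        assert params.rate("kci0", HIGH_K) > params.rate("kci0", ND96)

    def test_unknown_rate_name_rejected(self):
        bad = StateScheme(
            "bad",
            ("A", "B"),
            frozenset({"A"}),
            (("A", "B", "nope", 1.0), ("B", "A", "nope", -1.0)),
        )
        with pytest.raises(KeyError):
            build_generator(bad, RateParams(), ND96)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        rates=st.lists(
            st.floats(min_value=0.0, max_value=10.0), min_size=8, max_size=8
        ),
        v=st.floats(min_value=-120, max_value=60),
    )
    def test_rows_sum_to_zero_for_any_rates(self, rates, v):
        kd, ku, kb, kub, kci, kcr, a0, b0 = rates
        params = RateParams(
            a0=a0 + 1e-6, b0=b0 + 1e-6, kd=kd, ku=ku, kb=kb, kub=kub, kci=kci, kcr=kcr
        )
        Q = build_generator(akv1_scheme(), params, ND96.at(v))
        scale = max(1.0, np.abs(Q).max())
        assert np.abs(Q.sum(axis=1)).max() < 1e-12 * scale
        off = Q - np.diag(np.diag(Q))
        assert off.min() >= 0.0


class TestPropagate:
    def test_zero_generator_keeps_p0(self):
        Q = np.zeros((3, 3))
        p0 = np.array([0.2, 0.5, 0.3])
        traj = propagate(Q, p0, np.linspace(0, 100, 11))
        np.testing.assert_allclose(traj, np.tile(p0, (11, 1)))

    def test_two_state_closed_form(self, two_state):
        scheme, params = two_state(0.05, 0.05)
        Q = build_generator(scheme, params, ZERO_K)
        t = np.linspace(0, 200, 401)
        traj = propagate(Q, np.array([1.0, 0.0]), t)
        np.testing.assert_allclose(
            traj[:, 1], 0.5 * (1 - np.exp(-0.1 * t)), atol=1e-12
        )

    def test_matches_matrix_exponential(self, akv1):
        for v in (-80.0, 40.0):
            Q = build_generator(akv1.scheme, akv1.params, ND96.at(v))
            p0 = np.zeros(Q.shape[0])
            p0[0] = 1.0
            for t in (0.5, 37.0, 1000.0):
                exact = p0 @ expm(Q * t)
                got = propagate(Q, p0, np.array([t]))[0]
                assert np.abs(got - exact).max() < 1e-8

    def test_occupancy_stays_on_simplex(self, akv1):
        Q = build_generator(akv1.scheme, akv1.params, ND96.at(40.0))
        p0 = steady_state(build_generator(akv1.scheme, akv1.params, ND96.at(-80.0)))
        traj = propagate(Q, p0, np.linspace(0, 5000, 501))
        assert traj.min() >= 0.0
        assert np.abs(traj.sum(axis=1) - 1).max() < 1e-9

    def test_rejects_nonconservative_generator(self):
        Q = np.array([[-1.0, 0.5], [0.2, -0.2]])
        with pytest.raises(ValueError, match="non-conservative"):
            propagate(Q, np.array([1.0, 0.0]), np.array([1.0]))


class TestSteadyState:
    def test_symmetric_two_state(self, two_state):
        scheme, params = two_state(0.03, 0.03)
        Q = build_generator(scheme, params, ZERO_K)
        np.testing.assert_allclose(steady_state(Q), [0.5, 0.5])

    def test_printed_block_relations(self, two_state):
        # alpha 0.045, beta 0.005: conducting fraction beta/(alpha+beta) = 0.1,
        # decay tau 1/(alpha+beta) = 20 ms
        scheme, params = two_state(0.045, 0.005)
        Q = build_generator(scheme, params, ZERO_K)
        pi = steady_state(Q)
        assert pi[0] == pytest.approx(0.1, abs=1e-12)
        relax = -np.sort(np.linalg.eigvals(Q).real)[0]
        assert 1.0 / relax == pytest.approx(20.0, rel=1e-12)

    def test_random_generator_matches_long_propagation(self):
        rng = np.random.default_rng(42)
        Q = rng.uniform(0.001, 0.05, size=(5, 5))
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(5)] = -Q.sum(axis=1)
        pi = steady_state(Q)
        p_inf = propagate(Q, np.eye(5)[0], np.array([1e6]))[0]
        assert np.abs(pi - p_inf).max() < 1e-6

    def test_reducible_generator_warns(self):
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[1, 0] = 0.1
        Q[2, 3] = Q[3, 2] = 0.2
        Q[np.diag_indices(4)] -= Q.sum(axis=1)
        with pytest.warns(UserWarning, match="reducible"):
            pi = steady_state(Q)
        assert pi.sum() == pytest.approx(1.0)


class TestTwoStateBlock:
    def test_symmetric_case(self):
        alpha, beta = two_state_block(20.0, 0.5)
        assert alpha == pytest.approx(0.025)
        assert beta == pytest.approx(0.025)

    def test_published_fast_component_inversion(self):
        # fast decay tau 24.2 ms with stationary fraction 0.512
        alpha, beta = two_state_block(24.2, 0.512)
        assert alpha + beta == pytest.approx(1.0 / 24.2, rel=1e-15)
        assert beta / (alpha + beta) == pytest.approx(0.512, rel=1e-15)

    def test_round_trip_is_exact(self, two_state):
        alpha, beta = two_state_block(37.0, 0.23)
        scheme, params = two_state(alpha, beta)
        Q = build_generator(scheme, params, ZERO_K)
        pi = steady_state(Q)
        tau = -1.0 / np.sort(np.linalg.eigvals(Q).real)[0]
        assert pi[0] == pytest.approx(0.23, rel=1e-12)
        assert tau == pytest.approx(37.0, rel=1e-12)

    def test_degenerate_fraction_zero_gives_zero_unblock(self):
        _alpha, beta = two_state_block(20.0, 0.0)
        assert beta == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_state_block(-1.0, 0.5)
        with pytest.raises(ValueError):
            two_state_block(20.0, 1.0)


class TestGatingFlux:
    def test_zero_charges_give_zero_trace(self, two_state):
        scheme, params = two_state(0.05, 0.01)
        zero_z = StateScheme(
            "z0",
            scheme.states,
            scheme.conducting,
            (("O", "N", "kb", 0.0), ("N", "O", "kub", 0.0)),
        )
        Q = build_generator(zero_z, params, ZERO_K)
        p = propagate(Q, np.array([1.0, 0.0]), np.linspace(0, 50, 51))
        assert np.all(gating_flux(Q, p, zero_z) == 0.0)

    def test_single_step_charge_conservation(self):
        # saturating depolarization moves exactly the step's charge
        scheme = StateScheme(
            "step",
            ("C", "A"),
            frozenset(),
            (("C", "A", "a", 2.5), ("A", "C", "b", -2.5)),
        )
        params = RateParams(a0=1.0, b0=1e-9)  # effectively irreversible step
        Q = build_generator(scheme, params, ND96.at(40.0))
        t = np.linspace(0, 50, 20001)
        p = propagate(Q, np.array([1.0, 0.0]), t)
        q = np.trapezoid(gating_flux(Q, p, scheme), t)
        assert q == pytest.approx(2.5, rel=1e-4)

    def test_closed_cycle_moves_zero_net_charge(self, akv1):
        # ON pulse + complete OFF recovery back to equilibrium: net charge 0
        scheme, params = akv1.scheme, akv1.params
        Q_on = build_generator(scheme, params, ND96.at(40.0))
        Q_off = build_generator(scheme, params, ND96.at(-80.0))
        p0 = steady_state(Q_off)
        t_on = np.linspace(0, 50, 50001)
        traj_on = propagate(Q_on, p0, t_on)
        q_on = np.trapezoid(gating_flux(Q_on, traj_on, scheme), t_on)
        t_off = np.linspace(0, 60000, 600001)
        traj_off = propagate(Q_off, traj_on[-1], t_off)
        q_off = np.trapezoid(gating_flux(Q_off, traj_off, scheme), t_off)
        assert q_on > 5.0  # a real depolarization moves most of the 10 e0
        assert abs(q_on + q_off) < 1e-2 * q_on

    def test_scheme_total_charge(self):
        assert total_forward_charge(akv1_scheme()) == pytest.approx(10.0)
        assert total_forward_charge(dn_scheme()) == pytest.approx(10.0)


class TestGillespie:
    def test_same_seed_reproduces(self, two_state):
        scheme, params = two_state(0.05, 0.02)
        t = np.linspace(0, 100, 11)
        a = gillespie_sample(scheme, params, ZERO_K, 500, seed=7, t_grid=t)
        b = gillespie_sample(scheme, params, ZERO_K, 500, seed=7, t_grid=t)
        np.testing.assert_array_equal(a, b)

    def test_zero_rates_stay_put(self, two_state):
        scheme, params = two_state(0.0, 0.0)
        s = gillespie_sample(scheme, params, ZERO_K, 1, seed=1, t_grid=np.arange(5.0))
        assert np.all(s == 0)

    def test_two_state_blocked_fraction_within_3se(self, two_state):
        alpha = beta = 0.05
        scheme, params = two_state(alpha, beta)
        n = 20_000
        tau = 1.0 / (alpha + beta)
        samples = gillespie_sample(
            scheme, params, ZERO_K, n, seed=11, t_grid=np.array([tau])
        )
        frac = (samples[:, 0] == 1).mean()
        expected = 0.5 * (1 - np.exp(-1.0))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se


class TestMonotonicity:
    """Occupancy of the C-type inactivated pool after a 1-s depolarization
    moves the right way with kci, external K+ and Zn2+."""

    @staticmethod
    def _nc_after_pulse(params, cond):
        scheme = akv1_scheme()
        Q_hold = build_generator(scheme, params, cond.at(-80.0))
        Q = build_generator(scheme, params, cond.at(40.0))
        p = propagate(Q, steady_state(Q_hold), np.array([1000.0]))[0]
        return p[scheme.index["NC"]]

    def test_kci_increases_slow_pool(self):
        base = _rand_params()
        vals = [
            self._nc_after_pulse(
                RateParams(**{**base.__dict__, "kci": k}), ND96
            )
            for k in (0.001, 0.002, 0.004)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_external_k_suppresses_slow_pool(self):
        params = _rand_params()
        conds = [Condition(K_out=k) for k in (0.5, 2.0, 98.0)]
        vals = [self._nc_after_pulse(params, c) for c in conds]
        assert vals[0] > vals[1] > vals[2]

    def test_u_type_flag_inverts_k_effect(self):
        params = RateParams(
            kd=0.3, ku=0.2, kb=0.05, kub=0.01, kci=0.002, kcr=3e-4, u_type=True,
            K_K=98.0,
        )
        lo = self._nc_after_pulse(params, Condition(K_out=2.0))
        hi = self._nc_after_pulse(params, Condition(K_out=98.0))
        assert hi > lo

    def test_zn_increases_slow_pool(self):
        params = _rand_params()
        vals = [
            self._nc_after_pulse(params, Condition(K_out=2.0, Zn=z))
            for z in (0.0, 100.0, 300.0)
        ]
        assert vals[0] < vals[1] < vals[2]
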