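"""Model definitions: right-hand sides, observables, scenarios, conservation."""

import numpy as np
import pytest

from udekit.models import (
    build_glycolysis_ode,
    build_glycolysis_ude,
    build_stat5_ode,
    build_stat5_scenario,
    epo_input,
    get_problem,
    stat5_observables,
    stat5_rhs,
    stat5_x0,
)
from udekit.models.glycolysis import (
    GlycolysisConstants,
    ODE_PARAMETER_NAMES,
    REFERENCE_CONSTANTS,
    REFERENCE_X0,
    UDE_PARAMETER_NAMES,
    glycolysis_rhs,
    _jac_theta,
    _jac_x,
    _rhs,
)
from udekit.models.stat5 import (
    PARAMETER_NAMES,
    REFERENCE_PARAMETERS,
    V_CYT,
    V_NUC,
)
from udekit.nn import ANNSpec
from udekit.simulate import integrate


class TestGlycolysisRHS:
    def test_hand_evaluated_first_equation(self):
        # S1=1, A3=1, J0=k1=K1=1: dS1/dt = 1 - 1*1*(1/(1+1)) = 0.5
        c = GlycolysisConstants(J0=1.0, k1=1.0, K1=1.0)
        x = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0])
        dx = glycolysis_rhs(0.0, x, c)
        assert dx[0] == pytest.approx(0.5)

    def test_zero_state(self):
        c = REFERENCE_CONSTANTS
        dx = glycolysis_rhs(0.0, np.zeros(7), c)
        assert dx[0] == pytest.approx(c.J0)
        assert dx[6] == pytest.approx(0.0)  # S4 = S4_ex = 0
        assert np.allclose(dx[1:6], 0.0)

    def test_hill_factor_vanishes_at_large_atp(self):
        c = REFERENCE_CONSTANTS
        x = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 1e9, 0.0])
        dx = glycolysis_rhs(0.0, x, c)
        # k1 consumption term vanished; only the ATP drain acts on dS1 via J0
        assert dx[0] == pytest.approx(c.J0, rel=1e-12)

    def test_analytic_jacobians_against_sympy(self):
        sympy = pytest.importorskip("sympy")
        xs = sympy.symbols("S1 S2 S3 S4 N2 A3 S4e", positive=True)
        ths = sympy.symbols(" ".join(ODE_PARAMETER_NAMES), positive=True)
        expr = sympy.Matrix(_rhs(0.0, list(xs), list(ths), include_k5=True))
        Jx = sympy.lambdify((xs, ths), expr.jacobian(xs), "numpy")
        Jt = sympy.lambdify((xs, ths), expr.jacobian(ths), "numpy")
        rng = np.random.default_rng(0)
        theta = np.array([getattr(REFERENCE_CONSTANTS, n) for n in ODE_PARAMETER_NAMES])
        for _ in range(5):
            x = rng.uniform(0.05, 2.0, size=7)
            np.testing.assert_allclose(
                _jac_x(0.0, x, theta, include_k5=True), Jx(x, theta), rtol=1e-10
            )
            np.testing.assert_allclose(
                _jac_theta(0.0, x, theta, include_k5=True), Jt(x, theta), rtol=1e-10
            )

    def test_reference_oscillates_sustained(self):
        prob = build_glycolysis_ode()
        times = np.linspace(0, 5, 1001)
        traj = integrate(prob, times, rtol=1e-9, atol=1e-11)
        assert traj.success
        from scipy.signal import find_peaks

        for j in prob.observable_indices:
            peaks, _ = find_peaks(traj.states[:, j])
            assert len(peaks) >= 3


class TestGlycolysisUDE:
    def test_parameter_bookkeeping(self, glyc_ude):
        assert len(glyc_ude.parameters) == 11
        assert "k5" not in glyc_ude.parameters.names
        assert len(build_glycolysis_ode().parameters) == 12

    def test_requires_7_to_1_network(self):
        with pytest.raises(ValueError):
            build_glycolysis_ude(ANNSpec(6, 1))

    def test_zero_network_equals_truncated_ode(self, glyc_ude, small_ann_spec):
        from udekit.nn import ann_init

        theta = glyc_ude.parameters.values
        x = REFERENCE_X0 * 1.1
        dx_ude = glyc_ude.rhs(0.0, x, theta, ann_params=ann_init(small_ann_spec, 1))
        dx_trunc = glyc_ude.rhs_mechanistic(0.0, x, theta)
        np.testing.assert_allclose(dx_ude, dx_trunc)
        # and the truncated system differs from the full one only in dA3/dt
        full = np.array([getattr(REFERENCE_CONSTANTS, n) for n in ODE_PARAMETER_NAMES])
        dx_full = _rhs(0.0, x, full, include_k5=True)
        np.testing.assert_allclose(np.delete(dx_ude, 5), np.delete(dx_full, 5))
        assert dx_ude[5] - dx_full[5] == pytest.approx(REFERENCE_CONSTANTS.k5 * x[5])

    def test_oracle_substitution_recovers_full_ode(self, glyc_ude):
        k5 = REFERENCE_CONSTANTS.k5
        times = np.linspace(0, 5, 51)
        full = integrate(build_glycolysis_ode(), times, rtol=1e-10, atol=1e-12)
        hybrid = integrate(
            glyc_ude,
            times,
            ann_override=lambda u: np.array([-k5 * u[5]]),
            rtol=1e-10,
            atol=1e-12,
        )
        assert hybrid.success
        np.testing.assert_allclose(hybrid.states, full.states, rtol=1e-6)


class TestSTAT5:
    def test_epo_input_values(self):
        assert epo_input(0.0, 0.03) == pytest.approx(1.25e-07)
        assert epo_input(17.0, 0.0) == pytest.approx(1.25e-07)
        rate = 0.05
        assert epo_input(1.0 / rate, rate) == pytest.approx(1.25e-07 / np.e)
        with pytest.raises(ValueError):
            epo_input(-1.0, 0.1)

    def test_zero_state_is_stationary(self):
        theta = np.array([REFERENCE_PARAMETERS[n] for n in PARAMETER_NAMES])
        np.testing.assert_allclose(stat5_rhs(3.0, np.zeros(8), theta), 0.0)

    def test_hand_evaluated_phosphorylation(self):
        theta = np.array([REFERENCE_PARAMETERS[n] for n in PARAMETER_NAMES])
        kph = REFERENCE_PARAMETERS["k_phos"]
        E = float(epo_input(2.0, REFERENCE_PARAMETERS["Epo_degradation_BaF3"]))
        x = np.zeros(8)
        x[0] = 1.0
        dx = stat5_rhs(2.0, x, theta)
        assert dx[0] == pytest.approx(-2.0 * E * kph)
        assert dx[2] == pytest.approx(E * kph)

    def test_monomer_mass_conservation_along_trajectory(self):
        prob = build_stat5_ode()
        times = np.linspace(0, 240, 49)
        traj = integrate(prob, times, rtol=1e-10, atol=1e-14)
        assert traj.success
        x = traj.states
        total = V_CYT * (
            x[:, 0] + x[:, 1] + 2 * (x[:, 2] + x[:, 3] + x[:, 4])
        ) + V_NUC * 2 * (x[:, 5] + x[:, 6] + x[:, 7])
        np.testing.assert_allclose(total, total[0], rtol=1e-7)

    def test_observables_hand_values(self):
        # pApB=0, pApA=1, STAT5A=1 -> pSTAT5A_rel = 200c/(3c) = 200/3
        x = np.zeros(8)
        x[0], x[2] = 1.0, 1.0
        x[1] = 1.0  # keeps the (unasserted) B-observable denominators nonzero
        y = stat5_observables(x)[0]
        assert y[0] == pytest.approx(200.0 / 3.0)
        # no phospho-dimers at all -> zero numerator
        x2 = np.zeros(8)
        x2[0], x2[1] = 1.0, 1.0
        y2 = stat5_observables(x2)[0]
        assert y2[0] == pytest.approx(0.0)
        # rSTAT5A_rel = 100c / (c - (c-1)) = 10.7
        assert y2[2] == pytest.approx(10.7)


class TestScenarios:
    def test_dimension_checks(self):
        for n, io in [(1, (8, 1)), (2, (9, 1)), (3, (6, 6)), (4, (8, 1))]:
            build_stat5_scenario(n, ANNSpec(*io))
            with pytest.raises(ValueError):
                build_stat5_scenario(n, ANNSpec(io[0] + 1, io[1]))
        with pytest.raises(ValueError):
            build_stat5_scenario(5, ANNSpec(8, 1))

    def test_scenario1_flux_conserves_monomers(self):
        prob = build_stat5_scenario(1, ANNSpec(8, 1))
        B = prob.ann_state_matrix
        # the network flux moves monomers between compartments without loss:
        # V_cyt * dSTAT5A + 2 V_nuc * dnucpApA = 0 for any output value
        assert V_CYT * B[0, 0] + 2.0 * V_NUC * B[5, 0] == pytest.approx(0.0)
        assert np.count_nonzero(B) == 2

    def test_scenario1_zero_network_drops_only_replaced_terms(self):
        prob = build_stat5_scenario(1, ANNSpec(8, 1))
        theta = prob.parameters.values
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, size=8)
        d_scen = prob.rhs_mechanistic(0.0, x, theta)
        d_full = stat5_rhs(0.0, x, theta)
        k_exp_homo = theta[PARAMETER_NAMES.index("k_exp_homo")]
        assert d_full[0] - d_scen[0] == pytest.approx(
            2.0 * V_NUC / V_CYT * k_exp_homo * x[5]
        )
        assert d_full[5] - d_scen[5] == pytest.approx(-k_exp_homo * x[5])
        np.testing.assert_allclose(np.delete(d_scen, [0, 5]), np.delete(d_full, [0, 5]))

    def test_scenario2_oracle_substitution_matches_reference(self):
        prob = build_stat5_scenario(2, ANNSpec(9, 1))
        theta = prob.parameters.values
        kph = theta[PARAMETER_NAMES.index("k_phos")]
        kih = theta[PARAMETER_NAMES.index("k_imp_hetero")]

        def oracle(u):
            # exact mechanistic hetero-dimer balance from the inputs
            A, B, pApB, E = u[0], u[1], u[4], u[8]
            return np.array([E * A * B * kph - kih * pApB])

        times = np.linspace(0, 240, 25)
        ref = integrate(build_stat5_ode(), times, rtol=1e-10, atol=1e-14)
        hybrid = integrate(prob, times, ann_override=oracle, rtol=1e-10, atol=1e-14)
        assert hybrid.success
        np.testing.assert_allclose(
            hybrid.states[:, 4], ref.states[:, 4], rtol=1e-5, atol=1e-12
        )

    def test_scenario3_zero_network_reduces_to_reference(self):
        prob = build_stat5_scenario(3, ANNSpec(6, 6))
        assert prob.n_states == 11
        assert np.allclose(prob.x0[8:], 0.0)
        assert len(prob.parameters) == 9
        times = np.linspace(0, 240, 25)
        from udekit.nn import ann_init

        hybrid = integrate(
            prob, times, ann_params=ann_init(prob.ann_spec, 0), rtol=1e-10, atol=1e-14
        )
        ref = integrate(build_stat5_ode(), times, rtol=1e-10, atol=1e-14)
        assert hybrid.success
        np.testing.assert_allclose(
            hybrid.states[:, :8], ref.states, rtol=1e-6, atol=1e-12
        )
        np.testing.assert_allclose(hybrid.states[:, 8:], 0.0, atol=1e-12)

    def test_scenario4_network_replaces_third_observable(self):
        prob = build_stat5_scenario(4, ANNSpec(8, 1))
        assert prob.ann_state_matrix is None  # dynamics fully mechanistic
        assert prob.ann_observable_index == 2
        from udekit.nn import ann_init, ann_parameter_count

        times = np.linspace(0, 240, 10)
        traj = integrate(prob, times, rtol=1e-8, atol=1e-12)
        params = ann_init(prob.ann_spec, 0)
        params.values[-1] = 7.5  # output bias: constant observable
        y = prob.observe(times, traj.states, prob.parameters.values, params)
        ref = stat5_observables(traj.states)
        np.testing.assert_allclose(y[:, :2], ref[:, :2])
        np.testing.assert_allclose(y[:, 2], 7.5)

    def test_registry_round_trip(self):
        assert get_problem("glycolysis").name == "glycolysis"
        assert (
            get_problem("stat5_scenario2", ANNSpec(9, 1)).name == "stat5_scenario2"
        )
        with pytest.raises(KeyError):
            get_problem("lorenz")


def test_zero_network_reduces_every_scenario_to_its_mechanistic_core():
    """With a zero network, hybrid trajectories equal an independent
    integration of the printed mechanistic equations."""
    from udekit.nn import ann_init
    from scipy.integrate import solve_ivp

    ude = build_glycolysis_ude(ANNSpec(7, 1, 2, 3, "relu"))
    times = np.linspace(0, 1.5, 16)
    hybrid = integrate(
        ude, times, ann_params=ann_init(ude.ann_spec, 5), rtol=1e-10, atol=1e-12
    )
    theta = ude.parameters.values
    oracle = solve_ivp(
        lambda t, x: ude.rhs_mechanistic(t, x, theta),
        (0, 1.5),
        ude.x0,
        t_eval=times,
        rtol=1e-10,
        atol=1e-12,
    )
    np.testing.assert_allclose(hybrid.states, oracle.y.T, rtol=1e-6)
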