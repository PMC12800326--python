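import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.special import expit

from wcseizure import (DomainError, ModelParameters, ParameterError,
                       SeizureModel, State, activation, jacobian,
                       perceived_inputs, vector_field)


class TestActivation:
    def test_median(self):
        """The sigmoid reaches its median value 0.5 at x = mu."""
        for theta, mu in [(3.0, 1.5), (5.0, 2.7), (0.7, -4.0)]:
            assert activation(mu, theta, mu) == pytest.approx(0.5, abs=1e-15)

    def test_asymptotes(self):
        assert activation(1e6, 3.0, 1.5) == pytest.approx(1.0)
        assert activation(-1e6, 3.0, 1.5) == pytest.approx(0.0)

    def test_no_overflow_at_extreme_arguments(self):
        # |theta*(x - mu)| up to ~700 must not overflow
        with np.errstate(over="raise"):
            assert activation(-230.0, 3.0, 1.5) >= 0.0
            assert activation(235.0, 3.0, 1.5) <= 1.0

    @settings(derandomize=True, max_examples=200)
    @given(x1=st.floats(-50, 50), x2=st.floats(-50, 50),
           theta=st.floats(0.1, 10), mu=st.floats(-5, 5))
    def test_strictly_increasing(self, x1, x2, theta, mu):
        if abs(x1 - x2) < 1e-9:   # below sigmoid resolution in float64
            return
        lo, hi = sorted([x1, x2])
        a_lo, a_hi = activation(lo, theta, mu), activation(hi, theta, mu)
        assert a_lo <= a_hi
        if 1e-12 < a_lo and a_hi < 1 - 1e-12:   # outside float saturation
            assert a_lo < a_hi

    def test_rejects_invalid_input(self):
        with pytest.raises(ParameterError):
            activation(np.nan, 3.0, 1.5)
        with pytest.raises(ParameterError):
            activation(1.0, -3.0, 1.5)


class TestPerceivedInputs:
    @pytest.mark.parametrize("E,I,xE,xI", [
        (0.0, 0.0, 0.25, 0.0),        # only the drives remain
        (1.0, 0.0, 10.25, 12.0),
        (0.5, 0.5, 0.25, 5.5),
    ])
    def test_baseline_values(self, baseline_params, E, I, xE, xI):
        got = perceived_inputs(State(E, I), baseline_params)
        assert got == pytest.approx((xE, xI), abs=1e-12)

    def test_outside_domain_rejected(self, baseline_params):
        with pytest.raises(Exception):
            State(1.2, float("nan"))
        with pytest.raises(DomainError):
            perceived_inputs(State(1.5, 0.5), baseline_params)


class TestVectorField:
    def test_zero_sustenance_recovers_classic_rates(self, baseline_params):
        """q_E = q_I = 0 must reproduce the classic Wilson-Cowan decay
        bit-for-bit."""
        p = baseline_params.replace(q_E=0.0, q_I=0.0)
        model = SeizureModel(p)
        rng = np.random.default_rng(1)
        E, I = rng.uniform(0, 1, 200), rng.uniform(0, 1, 200)
        dE, dI = model.vector_field(E, I)
        A_E = expit(p.theta_E * (p.a_EE * E - p.a_EI * I + p.D_E - p.mu_E))
        A_I = expit(p.theta_I * (p.a_IE * E - p.a_II * I + p.D_I - p.mu_I))
        classic_dE = p.tau_E * (A_E * (1.0 - E) - E * (1.0 - 0.0 * E))
        classic_dI = p.tau_I * (A_I * (1.0 - I) - I * (1.0 - 0.0 * E))
        assert np.array_equal(dE, classic_dE)
        assert np.array_equal(dI, classic_dI)

    def test_boundary_rates(self, baseline_params):
        # at E=1 recruitment vanishes: dE/dt = -tau_E*(1 - q_E)
        for I in (0.0, 0.3, 1.0):
            dE, _ = vector_field(State(1.0, I), baseline_params)
            assert dE == pytest.approx(-0.25, abs=1e-12)
        dE, _ = vector_field(State(0.0, 0.5), baseline_params)
        assert dE >= 0.0

    def test_outside_domain_rejected(self, baseline_model):
        with pytest.raises(DomainError):
            baseline_model.vector_field(1.5, 0.5)


class TestJacobian:
    def test_matches_central_differences(self):
        """Analytic partials agree with finite differences at random states
        for every layer combination."""
        base = ModelParameters.baseline()
        from wcseizure import DysfunctionConfig, InterventionConfig
        models = [
            SeizureModel(base),
            SeizureModel(base, DysfunctionConfig(rho=0.7)),
            SeizureModel(base, DysfunctionConfig(kappa=1.8, a_PI=5.0)),
            SeizureModel(base, DysfunctionConfig(rho=0.5),
                         InterventionConfig(sigma_GABA=1.6, sigma_RS=0.9)),
        ]
        rng = np.random.default_rng(7)
        E = rng.uniform(0.01, 0.99, 100)
        I = rng.uniform(0.01, 0.99, 100)
        h = 1e-6
        for model in models:
            J = model.jacobian(E, I)
            kw = dict(check_domain=False)
            dfE = model.vector_field(E + h, I, **kw)
            dbE = model.vector_field(E - h, I, **kw)
            dfI = model.vector_field(E, I + h, **kw)
            dbI = model.vector_field(E, I - h, **kw)
            num = np.stack([
                np.stack([(dfE[0] - dbE[0]) / (2 * h),
                          (dfI[0] - dbI[0]) / (2 * h)], -1),
                np.stack([(dfE[1] - dbE[1]) / (2 * h),
                          (dfI[1] - dbI[1]) / (2 * h)], -1)], -2)
            assert np.max(np.abs(J - num)) < 1e-5

    def test_decoupled_linear_decay(self):
        # no coupling, no sustenance, recruitment pushed to ~0 (mu >> drive):
        # the linearization reduces to pure decay at the rate constants
        p = ModelParameters.baseline().replace(
            a_EE=0.0, a_EI=0.0, a_IE=0.0, a_II=0.0, q_E=0.0, q_I=0.0,
            mu_E=60.0, mu_I=60.0, tau_E=1.3, tau_I=0.6)
        J = jacobian(State(0.4, 0.6), p)
        assert J[0, 1] == 0.0 and J[1, 0] == 0.0
        assert J[0, 0] == pytest.approx(-1.3)
        assert J[1, 1] == pytest.approx(-0.6)

    def test_baseline_fixed_point_is_repelling(self, baseline_model):
        """The inner fixed point of the baseline model repels: positive
        trace with positive determinant."""
        from wcseizure import find_equilibria
        (eq,) = find_equilibria(baseline_model)
        J = baseline_model.jacobian(eq.E, eq.I)
        assert J[0, 0] + J[1, 1] > 0
        assert J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0] > 0
        assert eq.stability == "repeller"


class TestForwardInvariance:
    @pytest.mark.parametrize("layer", ["baseline", "depletion",
                                       "depolarizing", "suppressed"])
    def test_trajectories_stay_in_domain(self, layer):
        """Trajectories from a 10x10 lattice remain inside the unit square
        for t in [0, 200] (within solver tolerance)."""
        from wcseizure import DysfunctionConfig, InterventionConfig
        base = ModelParameters.baseline()
        model = {
            "baseline": SeizureModel(base),
            "depletion": SeizureModel(base, DysfunctionConfig(rho=1.0)),
            "depolarizing": SeizureModel(
                base, DysfunctionConfig(kappa=1.8, a_PI=5.0)),
            "suppressed": SeizureModel(
                base, intervention=InterventionConfig(sigma_RS=1.5)),
        }[layer]
        g = np.linspace(0, 1, 10)
        E0, I0 = map(np.ravel, np.meshgrid(g, g))
        y0 = np.concatenate([E0, I0])
        sol = solve_ivp(model.rhs(), (0, 200), y0, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        assert sol.success
        assert np.all(sol.y >= -1e-6)
        assert np.all(sol.y <= 1 + 1e-6)
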