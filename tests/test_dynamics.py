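import numpy as np
import pytest

from wcseizure import (AmbiguousRegimeError, ParameterError, RampProtocol,
                       classify_regime, find_equilibria, find_limit_cycle,
                       simulate)


class TestRampProtocol:
    def test_piecewise_linear_interpolation(self):
        proto = RampProtocol("D_E", ((40.0, 0.25), (90.0, 2.75)))
        assert proto.value(0.0) == 0.25        # constant before first knot
        assert proto.value(65.0) == pytest.approx(1.5)
        assert proto.value(120.0) == 2.75      # constant after last knot

    @pytest.mark.parametrize("bad", [
        {"parameter": "nonsense", "schedule": ((0.0, 1.0),)},
        {"parameter": "D_E", "schedule": ((10.0, 1.0), (5.0, 2.0))},
        {"parameter": "D_E", "schedule": ((0.0, float("nan")),)},
        {"parameter": "D_E", "schedule": ()},
    ])
    def test_validation(self, bad):
        with pytest.raises(ParameterError):
            RampProtocol(**bad)


class TestFindLimitCycle:
    def test_baseline_cycle_is_sole_attractor(self, baseline_model,
                                              baseline_cycle):
        cyc = baseline_cycle
        assert cyc.period > 0
        assert 0 <= cyc.E_min < cyc.E_max <= 1
        assert cyc.closure_error < 1e-6
        assert classify_regime(baseline_model, cyc) == "normal"

    def test_bistable_cycle_coexists_with_seizure(self, baseline_model):
        m = baseline_model.with_param("D_E", 1.65)
        cyc = find_limit_cycle(m)
        assert cyc is not None
        roles = {e.role for e in find_equilibria(m)
                 if e.stability == "attractor"}
        assert roles == {"seizure"}

    def test_no_cycle_when_seizure_is_sole_attractor(self, baseline_model):
        assert find_limit_cycle(baseline_model.with_param("D_E", 2.0)) is None

    def test_invariant_under_tolerance_halving(self, baseline_model,
                                               baseline_cycle):
        tight = find_limit_cycle(baseline_model, rtol=0.5e-8, atol=0.5e-10)
        assert tight.period == pytest.approx(baseline_cycle.period,
                                             rel=1e-3)
        for attr in ("E_min", "E_max", "I_min", "I_max"):
            assert getattr(tight, attr) == pytest.approx(
                getattr(baseline_cycle, attr), rel=1e-3, abs=1e-4)


class TestClassifyRegime:
    def test_seizure_fixed_point(self, baseline_model):
        m = baseline_model.with_param("D_E", 4.0)
        (eq,) = find_equilibria(m)
        assert classify_regime(m, eq) == "seizure"

    def test_repeller_is_never_a_regime(self, baseline_model):
        (eq,) = find_equilibria(baseline_model)
        assert eq.stability == "repeller"
        assert classify_regime(baseline_model, eq) == "other"

    def test_borderline_raises_ambiguous(self, baseline_model):
        from wcseizure.dynamics import LimitCycle
        # a synthetic orbit pinned exactly onto the segment boundary
        m = baseline_model
        # find (E, I) with A_E ~ 0.95: x s.t. expit(3(x-1.5)) = 0.95
        x = 1.5 + np.log(0.95 / 0.05) / 3.0
        E = 0.5
        I = (m.params.a_EE * E + m.params.D_E - x) / m.params.a_EI
        orbit = np.tile([E, I], (10, 1))
        cyc = LimitCycle(1.0, E, E, I, I, orbit, 0.0)
        with pytest.raises(AmbiguousRegimeError):
            classify_regime(m, cyc)

    def test_agrees_with_long_run_integration(self, baseline_model):
        """The label assigned to each attractor matches where trajectories
        from random starts actually end up."""
        m = baseline_model.with_param("D_E", 1.65)     # bistable
        eqs = find_equilibria(m)
        seizure = [e for e in eqs if e.role == "seizure"][0]
        cyc = find_limit_cycle(m, equilibria=eqs)
        rng = np.random.default_rng(5)
        outcomes = set()
        for _ in range(20):
            start = rng.uniform(0.02, 0.98, 2)
            res = simulate(m, start, (0.0, 300.0), dt=0.5)
            end = np.array([res.E[-1], res.I[-1]])
            if np.hypot(end[0] - seizure.E, end[1] - seizure.I) < 1e-3:
                outcomes.add("seizure")
            else:
                # still cycling: end state must lie within the cycle's box
                assert cyc.E_min - 1e-3 <= end[0] <= cyc.E_max + 1e-3
                outcomes.add("normal")
        assert outcomes == {"normal", "seizure"}


class TestSimulate:
    def test_constant_parameters_reach_the_cycle(self, baseline_model,
                                                 baseline_cycle):
        res = simulate(baseline_model, (0.9, 0.9), (0.0, 120.0))
        tail = slice(-400, None)
        assert res.E[tail].max() == pytest.approx(baseline_cycle.E_max,
                                                  abs=5e-3)
        assert res.E[tail].min() == pytest.approx(baseline_cycle.E_min,
                                                  abs=5e-3)
        assert not res.events

    def test_ramp_crosses_homoclinic_near_static_value(self, baseline_model):
        """The seizure jump under the drive ramp maps back to a D_E value
        within 2% of the statically computed homoclinic point; the escape
        window (last completed oscillation to saddle crossing) brackets it
        and its width measures the ramp-rate-induced lag."""
        SH = 1.77749          # D_E homoclinic localized by the split method
        proto = RampProtocol.hold_ramp_hold("D_E", 0.25, 2.75, 40.0, 90.0)
        res = simulate(baseline_model, (0.1, 0.1), (0.0, 140.0), [proto])
        assert res.events and res.events[-1]["to"] == "seizure-like"
        t, E, D = res.t, res.E, res.parameters["D_E"]
        jump = next(k for k in range(len(E)) if E[k] > 0.6)
        mins = [k for k in range(1, jump)
                if E[k] < E[k - 1] and E[k] <= E[k + 1]]
        last_min = mins[-1]
        cross = next(
            k for k in range(last_min, len(E))
            if E[k] > _saddle_E(baseline_model, float(D[k])))
        window = (float(D[last_min]), float(D[cross]))
        assert window[0] <= SH <= window[1]
        mid = 0.5 * (window[0] + window[1])
        assert abs(mid - SH) / SH < 0.02
        lag = window[1] - window[0]
        assert lag < 0.2    # the measured lag at this ramp rate

    def test_gaba_ramp_terminates_hyperexcitation_seizure(self,
                                                          baseline_model):
        """From a seizure at D_E=3, ramping sigma_GABA to 2 restores a
        normal-activity oscillation."""
        m = baseline_model.with_param("D_E", 3.0)
        seiz = [e for e in find_equilibria(m) if e.role == "seizure"][0]
        proto = RampProtocol.hold_ramp_hold("sigma_GABA", 1.0, 2.0,
                                            20.0, 70.0)
        res = simulate(m, (seiz.E, seiz.I), (0.0, 140.0), [proto])
        tail = res.E[-1000:]
        assert tail.max() - tail.min() > 0.05      # oscillating again
        assert tail.max() < 0.5                    # far below seizure level

    def test_rejects_start_outside_domain(self, baseline_model):
        with pytest.raises(ParameterError):
            simulate(baseline_model, (1.4, 0.5), (0.0, 10.0))


def _saddle_E(model, D_E: float) -> float:
    eqs = find_equilibria(model.with_param("D_E", D_E), grid=25)
    saddles = [e for e in eqs if e.stability == "saddle"]
    return saddles[0].E if saddles else np.inf
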