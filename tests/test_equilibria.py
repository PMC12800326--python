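import numpy as np
import pytest
from wcseizure import (DysfunctionConfig, InterventionConfig, SeizureModel,
                       find_equilibria, trace_nullclines)

from oracles import grid_scan_count


class TestFindEquilibria:
    @pytest.mark.parametrize("D_E,expected", [
        (0.25, [("repeller", "other")]),
        # just past the fold the newborn attractor's excitatory activation
        # (0.915) has not yet reached the 5% upper-asymptote band, so the
        # seizure role label only attaches once the branch matures
        (1.36, [("repeller", "other"), ("saddle", "other"),
                ("attractor", "other")]),
        (1.65, [("repeller", "other"), ("saddle", "other"),
                ("attractor", "seizure")]),
        (2.0, [("repeller", "other"), ("saddle", "other"),
               ("attractor", "seizure")]),
        (4.0, [("attractor", "seizure")]),
    ])
    def test_hyperexcitation_sequence(self, baseline_model, D_E, expected):
        """Equilibrium count and classes through the drive sweep: one
        repeller, then bistability with a seizure attractor and saddle,
        then the seizure fixed point alone."""
        eqs = find_equilibria(baseline_model.with_param("D_E", D_E))
        assert [(e.stability, e.role) for e in eqs] == expected

    def test_residuals_below_tolerance(self, baseline_model):
        for D_E in (0.25, 1.65, 2.0, 4.0):
            m = baseline_model.with_param("D_E", D_E)
            for eq in find_equilibria(m):
                dE, dI = m.vector_field(eq.E, eq.I)
                assert max(abs(float(dE)), abs(float(dI))) < 1e-10

    def test_eigenvalue_class_consistency(self, baseline_model):
        for D_E in (0.25, 1.65, 4.0):
            for eq in find_equilibria(baseline_model.with_param("D_E", D_E)):
                re = [ev.real for ev in eq.eigenvalues]
                if eq.stability == "attractor":
                    assert all(r < 0 for r in re)
                elif eq.stability == "repeller":
                    assert all(r > 0 for r in re)
                elif eq.stability == "saddle":
                    assert re[0] * re[1] < 0


@pytest.mark.parametrize("sweep,layer", [
    ("D_E", None),
    ("rho", "depletion"),
    ("kappa", "depolarizing"),
])
def test_equilibrium_count_matches_grid_scan_oracle(sweep, layer):
    """At 20 values per sweep the multistart-Newton count equals a
    brute-force 400x400 sign-change scan with local refinement."""
    base = SeizureModel.baseline()
    if layer == "depletion":
        values = np.linspace(0.0, 1.0, 20)
    elif layer == "depolarizing":
        base = SeizureModel(base.params, DysfunctionConfig(a_PI=5.0))
        values = np.linspace(0.0, 2.0, 20)
    else:
        values = np.linspace(0.25, 4.0, 20)
    for v in values:
        m = base.with_param(sweep, float(v))
        assert len(find_equilibria(m)) == grid_scan_count(m), \
            f"count mismatch at {sweep}={v}"


class TestNullclines:
    def test_defining_residuals(self, baseline_model):
        ncE, ncI = trace_nullclines(baseline_model, 150)
        assert len(ncE.points) >= 150 and len(ncI.points) >= 150
        assert ncE.residual < 1e-8
        assert ncI.residual < 1e-8

    def test_rejects_coarse_resolution(self, baseline_model):
        with pytest.raises(ValueError):
            trace_nullclines(baseline_model, 50)

    def test_single_intersection_matches_equilibrium(self, baseline_model):
        """At baseline the nullclines intersect once, at the fixed point."""
        ncE, ncI = trace_nullclines(baseline_model, 150)
        (eq,) = find_equilibria(baseline_model)
        dE = np.hypot(ncE.points[:, 0] - eq.E, ncE.points[:, 1] - eq.I)
        dI = np.hypot(ncI.points[:, 0] - eq.E, ncI.points[:, 1] - eq.I)
        assert dE.min() < 5e-3 and dI.min() < 5e-3
        # crossings of the two point sets cluster only around the equilibrium
        from scipy.spatial import cKDTree
        tree = cKDTree(ncI.points)
        close = ncE.points[tree.query(ncE.points)[0] < 2e-3]
        if len(close):
            assert np.all(np.hypot(close[:, 0] - eq.E,
                                   close[:, 1] - eq.I) < 0.05)

    def test_segments_labelled_by_activation(self, baseline_model):
        m = baseline_model.with_param("D_E", 2.0)
        ncE, _ = trace_nullclines(m, 150)
        A_E, _ = m.activations(ncE.points[:, 0], ncE.points[:, 1])
        for a, seg in zip(np.atleast_1d(A_E), ncE.segments):
            expected = ("lower" if a < 0.05
                        else "upper" if a > 0.95 else "transition")
            assert seg == expected

    def test_suppression_moves_E_nullcline_toward_I_axis(self):
        """With sigma_RS > 0 the upper segment of the E-nullcline sits at
        smaller E for matched I than without suppression."""
        base = SeizureModel(SeizureModel.baseline().params,
                            DysfunctionConfig(kappa=1.8, a_PI=5.0))
        sup = SeizureModel(base.params, base.dysfunction,
                           InterventionConfig(sigma_RS=1.0))

        def upper_E_at(model, I_value):
            from scipy.optimize import brentq
            f = lambda E: float(model.vector_field(
                E, I_value, check_domain=False)[0])
            grid = np.linspace(0.0, 1.0, 800)
            vals = np.array([f(E) for E in grid])
            idx = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
            assert len(idx), "no E-nullcline point at this I"
            i = idx[-1]          # largest-E (upper-segment) root
            return brentq(f, grid[i], grid[i + 1])

        for I_value in (0.3, 0.4, 0.5):
            assert upper_E_at(sup, I_value) < upper_E_at(base, I_value)
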