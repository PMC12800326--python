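"""Core vector field of the sustenance-extended Wilson-Cowan model.

The state (E, I) holds the proportions of excitatory and inhibitory neurons
firing; dynamics are restricted to the unit square Omega. Quiescent neurons
perceive weighted inputs

    x_E = a_EE*E - a_EI*I + D_E,      x_I = a_IE*E - a_II*I + D_I,

are recruited through sigmoidal activations A = expit(theta*(x - mu)), and
active neurons decay with a second-order term controlled by the sustenance
coefficients:

    dE/dt = tau_E * (A_E*(1 - E) - E*(1 - q_E*E))
    dI/dt = tau_I * (A_I*(1 - I) - I*(1 - q_I*E))

Note the cross-term in the inhibitory decay: inhibitory sustenance is driven
by *excitatory* activity. Dysfunction and intervention layers reshape the
perceived inputs (never the activation shape): depletion substitutes
I -> I(1 - rho*I) in both inputs, depolarizing GABA blends in a subpopulation
that perceives GABA with positive sign, GABAergic enhancement scales the
a_EI term, and rhythmic suppression shifts both q coefficients down.

All state-dependent methods are vectorized over numpy arrays of E and I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .params import (DysfunctionConfig, InterventionConfig, ModelParameters,
                     ParameterError, State)

__all__ = ["SeizureModel", "activation", "perceived_inputs", "vector_field",
           "jacobian", "DomainError", "SWEEPABLE"]

logger = logging.getLogger(__name__)

#: Parameter names accepted by :meth:`SeizureModel.with_param` sweeps.
SWEEPABLE = set(ModelParameters.field_names()) | {
    "rho", "kappa", "a_PI", "sigma_GABA", "sigma_RS"}


class DomainError(ValueError):
    """A state was queried outside the closed unit square Omega."""


def activation(x, theta: float, mu: float):
    """Sigmoid recruitment function ``(1 + exp(-theta*(x - mu)))**-1``.

    Strictly increasing with range (0, 1); reaches 0.5 at ``x = mu``.
    Computed through ``expit`` so arguments of any magnitude are safe.
    """
    if theta <= 0:
        raise ParameterError(f"theta must be > 0, got {theta}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("perceived input must be finite")
    out = expit(theta * (x - mu))
    return float(out) if out.ndim == 0 else out


def _check_domain(E, I, tol: float) -> None:
    if (np.any(np.asarray(E) < -tol) or np.any(np.asarray(E) > 1 + tol)
            or np.any(np.asarray(I) < -tol) or np.any(np.asarray(I) > 1 + tol)):
        raise DomainError("state outside Omega = [0,1] x [0,1]")


@dataclass(frozen=True)
class SeizureModel:
    """A parameterized model instance: core + dysfunction + intervention.

    The composition order is fixed: the dysfunction defines the perception
    (depletion substitutes ``I_eff``; depolarizing GABA substitutes ``x_R``),
    and the intervention rescales terms within it (``sigma_GABA`` scales the
    ``a_EI`` inhibition, ``sigma_RS`` shifts the sustenance coefficients).
    """

    params: ModelParameters
    dysfunction: DysfunctionConfig = DysfunctionConfig()
    intervention: InterventionConfig = InterventionConfig()
    _flags: dict = field(default_factory=dict, compare=False, repr=False)

    @classmethod
    def baseline(cls) -> "SeizureModel":
        return cls(ModelParameters.baseline())

    # -- parameter plumbing -------------------------------------------------

    def with_param(self, name: str, value: float) -> "SeizureModel":
        """Return a copy with one named parameter replaced (sweep support)."""
        if name in ModelParameters.field_names():
            return SeizureModel(self.params.replace(**{name: value}),
                                self.dysfunction, self.intervention)
        if name in ("rho", "kappa", "a_PI"):
            return SeizureModel(self.params,
                                self.dysfunction.replace(**{name: value}),
                                self.intervention)
        if name in ("sigma_GABA", "sigma_RS"):
            return SeizureModel(self.params, self.dysfunction,
                                self.intervention.replace(**{name: value}))
        raise ParameterError(f"unknown sweep parameter {name!r}")

    def get_param(self, name: str) -> float:
        for layer in (self.params, self.dysfunction, self.intervention):
            if hasattr(layer, name):
                return float(getattr(layer, name))
        raise ParameterError(f"unknown parameter {name!r}")

    def effective_sustenance(self) -> tuple[float, float]:
        """(q_E, q_I) after rhythmic suppression; may be negative."""
        sE, sI = self.intervention.suppressions()
        return self.params.q_E - sE, self.params.q_I - sI

    # -- model evaluation ---------------------------------------------------

    def perceived_inputs(self, E, I):
        """Arguments fed to the two activation functions.

        Returns ``(x_exc, x_I)`` where ``x_exc`` is the excitatory activation
        argument after all layer substitutions (``x_E``, depletion-modified
        ``x_E``, or the blended ``x_R``) and ``x_I`` the inhibitory one.
        """
        p, d, v = self.params, self.dysfunction, self.intervention
        E = np.asarray(E, dtype=float)
        I = np.asarray(I, dtype=float)
        I_used = I * (1.0 - d.rho * I) if d.rho > 0 else I
        x_exc = p.a_EE * E - v.sigma_GABA * p.a_EI * I_used + p.D_E
        x_inh = p.a_IE * E - p.a_II * I_used + p.D_I
        if d.kappa > 0:
            frac = d.kappa * E * I
            if np.any(frac > 1.0) and not self._flags.get("p_gt_1"):
                self._flags["p_gt_1"] = True
                logger.warning(
                    "chloride-loaded fraction p = kappa*E*I exceeded 1 "
                    "(max %.3f); the subpopulation blend is extrapolating",
                    float(np.max(frac)))
            x_pos = p.a_EE * E + d.a_PI * I + p.D_E
            x_exc = frac * x_pos + (1.0 - frac) * x_exc
        return x_exc, x_inh

    def activations(self, E, I):
        p = self.params
        x_exc, x_inh = self.perceived_inputs(E, I)
        return (expit(p.theta_E * (x_exc - p.mu_E)),
                expit(p.theta_I * (x_inh - p.mu_I)))

    def vector_field(self, E, I, check_domain: bool = True,
                     domain_tol: float = 1e-6):
        """Time derivatives (dE/dt, dI/dt)."""
        if check_domain:
            _check_domain(E, I, domain_tol)
        p = self.params
        E = np.asarray(E, dtype=float)
        I = np.asarray(I, dtype=float)
        qE, qI = self.effective_sustenance()
        A_E, A_I = self.activations(E, I)
        dE = p.tau_E * (A_E * (1.0 - E) - E * (1.0 - qE * E))
        dI = p.tau_I * (A_I * (1.0 - I) - I * (1.0 - qI * E))
        return dE, dI

    def jacobian(self, E, I):
        """Exact partial derivatives of the vector field, shape (..., 2, 2)."""
        p, d, v = self.params, self.dysfunction, self.intervention
        E = np.asarray(E, dtype=float)
        I = np.asarray(I, dtype=float)
        qE, qI = self.effective_sustenance()

        if d.rho > 0:
            dIu = 1.0 - 2.0 * d.rho * I
        else:
            dIu = np.ones_like(I)
        dxe_dE = p.a_EE * np.ones_like(E)
        dxe_dI = -v.sigma_GABA * p.a_EI * dIu
        if d.kappa > 0:
            delta = (d.a_PI + v.sigma_GABA * p.a_EI) * I
            dxe_dE = dxe_dE + d.kappa * I * delta
            dxe_dI = dxe_dI + 2.0 * d.kappa * E * delta
        dxi_dE = p.a_IE * np.ones_like(E)
        dxi_dI = -p.a_II * dIu

        A_E, A_I = self.activations(E, I)
        gE = p.theta_E * A_E * (1.0 - A_E)   # dA_E/dx
        gI = p.theta_I * A_I * (1.0 - A_I)

        j11 = p.tau_E * (gE * dxe_dE * (1.0 - E) - A_E - 1.0 + 2.0 * qE * E)
        j12 = p.tau_E * (gE * dxe_dI * (1.0 - E))
        j21 = p.tau_I * (gI * dxi_dE * (1.0 - I) + qI * I)
        j22 = p.tau_I * (gI * dxi_dI * (1.0 - I) - A_I - 1.0 + qI * E)
        J = np.stack([np.stack([j11, j12], axis=-1),
                      np.stack([j21, j22], axis=-1)], axis=-2)
        return J

    def rhs(self):
        """Autonomous right-hand side ``f(t, y)`` for ODE solvers.

        No domain check: adaptive solvers may probe marginally outside Omega;
        forward invariance of the flow keeps accepted steps inside.
        """
        def f(t, y):
            n = y.shape[0] // 2
            dE, dI = self.vector_field(y[:n], y[n:], check_domain=False)
            return np.concatenate([np.atleast_1d(dE), np.atleast_1d(dI)])
        return f


# -- module-level operations on the plain core model ------------------------

def perceived_inputs(state: State, params: ModelParameters):
    """Core perceived inputs (x_E, x_I) at a state, without any layers."""
    if not state.in_domain():
        raise DomainError("state outside Omega")
    x_E = params.a_EE * state.E - params.a_EI * state.I + params.D_E
    x_I = params.a_IE * state.E - params.a_II * state.I + params.D_I
    return x_E, x_I


def vector_field(state: State, params: ModelParameters):
    """Core vector field (dE/dt, dI/dt) at a state, without any layers."""
    if not state.in_domain():
        raise DomainError("state outside Omega")
    model = SeizureModel(params)
    dE, dI = model.vector_field(state.E, state.I)
    return float(dE), float(dI)


def jacobian(state: State, params: ModelParameters) -> np.ndarray:
    """Analytic 2x2 Jacobian of the core vector field at a state."""
    if not state.in_domain():
        raise DomainError("state outside Omega")
    return SeizureModel(params).jacobian(state.E, state.I)
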