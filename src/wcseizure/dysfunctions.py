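"""Seizure-generating dysfunction operations.

Three mechanisms are modelled, all acting on the perceived inputs:

* hyperexcitation — an elevated net drive ``D_E`` (no separate code path;
  simply set ``D_E`` in :class:`~wcseizure.params.ModelParameters`);
* depletion of inhibitory neurotransmitter — postsynaptic inhibition is
  reduced to an effective level ``I_eff = I(1 - rho*I)``, substituted for
  ``I`` in both perceived inputs;
* depolarizing GABAergic transmission — a fraction ``p = kappa*E*I`` of the
  quiescent excitatory population has accumulated chloride and perceives
  GABA with positive sign; the excitatory activation argument becomes the
  blend ``x_R = p*x_P + (1-p)*x_E``.
"""

from __future__ import annotations

import numpy as np

from .model import SeizureModel
from .params import (DysfunctionConfig, ModelParameters, ParameterError,
                     State)

__all__ = ["effective_inhibition", "apply_depletion", "chloride_fraction",
           "depolarizing_perception"]


def effective_inhibition(I, rho: float):
    """Effective inhibitory activity ``I(1 - rho*I)`` under depletion.

    ``rho = 0`` is the identity; ``rho = 1`` with full inhibitory activity
    depletes inhibition entirely. The result always lies in [0, I].
    """
    if not 0.0 <= rho <= 1.0:
        raise ParameterError(f"rho must lie in [0, 1], got {rho}")
    I = np.asarray(I, dtype=float)
    out = I * (1.0 - rho * I)
    return float(out) if out.ndim == 0 else out


def apply_depletion(state: State, params: ModelParameters, rho: float):
    """Perceived inputs with ``I`` replaced by its depleted effective value
    in both the excitatory and the inhibitory input."""
    model = SeizureModel(params, DysfunctionConfig(rho=rho))
    x_exc, x_inh = model.perceived_inputs(state.E, state.I)
    return float(x_exc), float(x_inh)


def chloride_fraction(state: State, kappa: float):
    """Fraction ``p = kappa*E*I`` of quiescent excitatory neurons with
    excessive chloride accumulation.

    Returned without clamping: the product can exceed 1 for large ``kappa``,
    in which case the subpopulation blend extrapolates (a warning is logged
    by the model when that regime is entered).
    """
    if kappa < 0:
        raise ParameterError(f"kappa must be >= 0, got {kappa}")
    return float(kappa * state.E * state.I)


def depolarizing_perception(state: State, params: ModelParameters,
                            kappa: float, a_PI: float):
    """Resultant excitatory perceived input ``x_R`` under depolarizing GABA.

    The chloride-loaded subpopulation perceives
    ``x_P = a_EE*E + a_PI*I + D_E`` (GABA enters with positive sign); the
    rest perceives the standard ``x_E``. Only the excitatory activation
    argument is replaced; the inhibitory input is untouched.
    """
    model = SeizureModel(params, DysfunctionConfig(kappa=kappa, a_PI=a_PI))
    x_exc, _ = model.perceived_inputs(state.E, state.I)
    return float(x_exc)
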