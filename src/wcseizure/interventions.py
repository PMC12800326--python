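"""Treatment models composed on top of any dysfunction.

GABAergic enhancement (benzodiazepines) multiplies the inhibitory term of
the excitatory activation argument by ``sigma_GABA``; when depletion is
active the amplified term is ``sigma_GABA * a_EI * I_eff``, and when GABA is
depolarizing only the ``a_EI`` term inside ``x_E`` is scaled — the ``a_PI``
term of the chloride-loaded subpopulation is not (the enhanced receptor
effect is excitatory there, and the blend keeps it separate).

Rhythmic suppression (levetiracetam/phenytoin) counteracts sustenance:
``q_E`` and ``q_I`` become ``q_E - sigma_RS`` and ``q_I - sigma_RS``.
Negative effective coefficients are allowed and meaningful: the net
second-order decay (sustenance minus suppression) then reduces firing during
seizure while barely touching normal activity.
"""

from __future__ import annotations

from .model import SeizureModel
from .params import (InterventionConfig, ModelParameters, ParameterError,
                     State)

__all__ = ["gaba_enhanced_input", "effective_sustenance"]


def gaba_enhanced_input(state: State, params: ModelParameters,
                        sigma_GABA: float):
    """Excitatory perceived input with amplified inhibition:
    ``x_E = a_EE*E - sigma_GABA*a_EI*I + D_E``."""
    if sigma_GABA < 0:
        raise ParameterError(f"sigma_GABA must be >= 0, got {sigma_GABA}")
    model = SeizureModel(params,
                         intervention=InterventionConfig(sigma_GABA=sigma_GABA))
    x_exc, _ = model.perceived_inputs(state.E, state.I)
    return float(x_exc)


def effective_sustenance(params: ModelParameters, sigma_RS: float):
    """Sustenance coefficients after rhythmic suppression:
    ``(q_E - sigma_RS, q_I - sigma_RS)``; values may be negative."""
    if sigma_RS < 0:
        raise ParameterError(f"sigma_RS must be >= 0, got {sigma_RS}")
    return params.q_E - sigma_RS, params.q_I - sigma_RS
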