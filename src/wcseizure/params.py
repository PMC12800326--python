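"""Parameter containers and flat-config serialization.

Every quantity in the model is dimensionless, including time. Parameters are
named after the standard Wilson-Cowan symbols: connection weights ``a_ij``
(effect of population *j* on population *i*), sigmoid slopes/medians
``theta``/``mu``, rate constants ``tau``, net drives ``D`` and the
second-order-decay (sustenance) coefficients ``q_E``, ``q_I`` that encode a
population's propensity for self-perpetuating firing.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "DysfunctionConfig",
    "InterventionConfig",
    "State",
    "ParameterError",
    "load_config",
    "save_config",
]


class ParameterError(ValueError):
    """A parameter violates its documented domain."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the sustenance-extended two-population model.

    ``q_E`` and ``q_I`` replace the classic linear decay ``-E`` (resp. ``-I``)
    with the second-order decay ``-E(1 - q_E E)`` (resp. ``-I(1 - q_I E)``);
    setting both to zero recovers the classic Wilson-Cowan rates.
    """

    a_EE: float
    a_EI: float
    a_IE: float
    a_II: float
    theta_E: float
    mu_E: float
    theta_I: float
    mu_I: float
    tau_E: float
    tau_I: float
    D_E: float
    D_I: float
    q_E: float
    q_I: float

    def __post_init__(self) -> None:
        for name in self.field_names():
            _require_finite(name, getattr(self, name))
        for name in ("theta_E", "theta_I", "tau_E", "tau_I"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("a_EE", "a_EI", "a_IE", "a_II"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("q_E", "q_I"):
            q = getattr(self, name)
            if not 0.0 <= q <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {q}")

    @classmethod
    def baseline(cls) -> "ModelParameters":
        """The reference parameter set: a normal-activity limit cycle is the
        system's only attractor."""
        return cls(
            a_EE=10.0, a_EI=10.0, a_IE=12.0, a_II=1.0,
            theta_E=3.0, mu_E=1.5, theta_I=5.0, mu_I=2.7,
            tau_E=1.0, tau_I=1.0, D_E=0.25, D_I=0.0,
            q_E=0.75, q_I=0.25,
        )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f: float(getattr(self, f)) for f in self.field_names()}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        unknown = set(data) - set(cls.field_names())
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        base = cls.baseline().to_dict()
        base.update({k: float(v) for k, v in data.items()})
        return cls(**base)


@dataclass(frozen=True)
class DysfunctionConfig:
    """Seizure-generating dysfunction layer.

    rho
        Inhibitory-neurotransmitter depletion level in [0, 1]; the effective
        inhibition perceived postsynaptically becomes ``I(1 - rho*I)``.
    kappa
        Chloride-transporter impairment (>= 0); the fraction of quiescent
        excitatory neurons with excessive chloride load is ``p = kappa*E*I``.
    a_PI
        Sensitivity of chloride-loaded neurons to GABA's depolarizing
        (excitatory) action; enters their perceived input with positive sign.

    Hyperexcitation is not a separate layer: it is an elevated ``D_E`` in
    :class:`ModelParameters`. Depletion and depolarizing GABA each substitute
    the excitatory perception and are mutually exclusive.
    """

    rho: float = 0.0
    kappa: float = 0.0
    a_PI: float = 5.0

    def __post_init__(self) -> None:
        _require_finite("rho", self.rho)
        _require_finite("kappa", self.kappa)
        _require_finite("a_PI", self.a_PI)
        if not 0.0 <= self.rho <= 1.0:
            raise ParameterError(f"rho must lie in [0, 1], got {self.rho}")
        if self.kappa < 0:
            raise ParameterError(f"kappa must be >= 0, got {self.kappa}")
        if self.a_PI < 0:
            raise ParameterError(f"a_PI must be >= 0, got {self.a_PI}")
        if self.rho > 0 and self.kappa > 0:
            raise ParameterError(
                "depletion (rho > 0) and depolarizing GABA (kappa > 0) both "
                "substitute the excitatory perception and cannot be combined"
            )

    @property
    def neutral(self) -> bool:
        return self.rho == 0.0 and self.kappa == 0.0

    def replace(self, **changes: float) -> "DysfunctionConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {"rho": self.rho, "kappa": self.kappa, "a_PI": self.a_PI}


@dataclass(frozen=True)
class InterventionConfig:
    """Treatment layer composed on top of any dysfunction.

    sigma_GABA
        Multiplicative enhancement of GABAergic inhibition in the excitatory
        activation argument (benzodiazepine model); neutral value 1.
    sigma_RS
        Rhythmic suppression: both sustenance coefficients are reduced to
        ``q - sigma_RS`` (levetiracetam/phenytoin model); neutral value 0.
        Negative effective coefficients are deliberate and allowed.
    q_E_suppression / q_I_suppression
        Optional per-population suppression overrides; when set they take the
        place of the shared ``sigma_RS`` scalar for that population.
    """

    sigma_GABA: float = 1.0
    sigma_RS: float = 0.0
    q_E_suppression: float | None = None
    q_I_suppression: float | None = None

    def __post_init__(self) -> None:
        _require_finite("sigma_GABA", self.sigma_GABA)
        _require_finite("sigma_RS", self.sigma_RS)
        if self.sigma_GABA < 0:
            raise ParameterError(
                f"sigma_GABA must be >= 0, got {self.sigma_GABA}")
        if self.sigma_RS < 0:
            raise ParameterError(f"sigma_RS must be >= 0, got {self.sigma_RS}")

    @property
    def neutral(self) -> bool:
        return (self.sigma_GABA == 1.0 and self.sigma_RS == 0.0
                and self.q_E_suppression is None
                and self.q_I_suppression is None)

    def suppressions(self) -> tuple[float, float]:
        sE = self.sigma_RS if self.q_E_suppression is None else self.q_E_suppression
        sI = self.sigma_RS if self.q_I_suppression is None else self.q_I_suppression
        return float(sE), float(sI)

    def replace(self, **changes: float) -> "InterventionConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {"sigma_GABA": self.sigma_GABA, "sigma_RS": self.sigma_RS}


@dataclass(frozen=True)
class State:
    """A point of the phase square Omega = [0,1] x [0,1] at time ``t``."""

    E: float
    I: float
    t: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("E", self.E)
        _require_finite("I", self.I)
        _require_finite("t", self.t)

    def in_domain(self, tol: float = 0.0) -> bool:
        return (-tol <= self.E <= 1 + tol) and (-tol <= self.I <= 1 + tol)


_CONFIG_KEYS = set(ModelParameters.field_names()) | {
    "rho", "kappa", "a_PI", "sigma_GABA", "sigma_RS"}


def split_config(data: Mapping[str, Any]) -> tuple[
        ModelParameters, DysfunctionConfig, InterventionConfig]:
    """Split a flat symbol-keyed mapping into the three parameter layers."""
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    params = ModelParameters.from_dict(
        {k: v for k, v in data.items() if k in ModelParameters.field_names()})
    dys = DysfunctionConfig(**{k: float(v) for k, v in data.items()
                               if k in ("rho", "kappa", "a_PI")})
    itv = InterventionConfig(**{k: float(v) for k, v in data.items()
                                if k in ("sigma_GABA", "sigma_RS")})
    return params, dys, itv


def load_config(path: str | Path) -> tuple[
        ModelParameters, DysfunctionConfig, InterventionConfig]:
    """Read a flat YAML/JSON config keyed by the model symbols."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} must be a flat mapping")
    return split_config(data)


def save_config(path: str | Path,
                params: ModelParameters,
                dysfunction: DysfunctionConfig | None = None,
                intervention: InterventionConfig | None = None) -> None:
    path = Path(path)
    flat: dict[str, float] = params.to_dict()
    if dysfunction is not None:
        flat.update(dysfunction.to_dict())
    if intervention is not None:
        flat.update(intervention.to_dict())
    if path.suffix == ".json":
        path.write_text(json.dumps(flat, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(flat, sort_keys=True))
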