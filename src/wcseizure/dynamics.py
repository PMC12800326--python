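"""Trajectory integration, ramp protocols, limit cycles and regime labels.

Normal activity in this model is usually an attracting limit cycle around a
repelling fixed point at the first transition-segment nullcline
intersection; a seizure is the attractor at the upper-asymptote
intersection. Trajectories are integrated with an adaptive, stiff-capable
solver (LSODA, rtol 1e-8, atol 1e-10 by default). Ramp protocols make the
system non-autonomous by interpolating named parameters piecewise-linearly
in time, mirroring the hold / linear ramp / hold pattern of the sweep
experiments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibria import (Equilibrium, UPPER_ASYMPTOTE_MIN, find_equilibria,
                         segment_label)
from .model import SWEEPABLE, SeizureModel
from .params import ParameterError

__all__ = ["RampProtocol", "SimulationResult", "LimitCycle", "simulate",
           "find_limit_cycle", "classify_regime", "AmbiguousRegimeError",
           "RTOL", "ATOL"]

logger = logging.getLogger(__name__)

RTOL = 1e-8
ATOL = 1e-10


class AmbiguousRegimeError(ValueError):
    """An attractor's activations sit too close to a segment boundary to
    assign a physiological regime."""


@dataclass(frozen=True)
class RampProtocol:
    """Piecewise-linear schedule for one named parameter.

    The value is constant before the first and after the last knot and
    linearly interpolated between knots.
    """

    parameter: str
    schedule: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ParameterError(f"unknown ramp parameter {self.parameter!r}")
        times = [t for t, _ in self.schedule]
        vals = [v for _, v in self.schedule]
        if len(times) == 0:
            raise ParameterError("ramp schedule needs at least one knot")
        if not all(np.isfinite(times)) or not all(np.isfinite(vals)):
            raise ParameterError("ramp knots must be finite")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("knot times must be strictly increasing")
        object.__setattr__(self, "schedule",
                           tuple((float(t), float(v)) for t, v in self.schedule))

    def value(self, t):
        times = np.array([k[0] for k in self.schedule])
        vals = np.array([k[1] for k in self.schedule])
        return np.interp(t, times, vals)

    @classmethod
    def hold_ramp_hold(cls, parameter: str, start: float, stop: float,
                       t_on: float = 20.0, t_off: float = 70.0
                       ) -> "RampProtocol":
        """The standard window pattern: hold at ``start``, ramp linearly on
        [t_on, t_off], hold at ``stop``."""
        return cls(parameter, ((t_on, start), (t_off, stop)))


@dataclass
class SimulationResult:
    """Integrated trajectory with realized parameter traces and an event log
    of regime-label changes."""

    t: np.ndarray
    E: np.ndarray
    I: np.ndarray
    parameters: dict[str, np.ndarray] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "E": self.E, "I": self.I}
        data.update(self.parameters)
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        meta = {
            "n_samples": int(len(self.t)),
            "t_span": [float(self.t[0]), float(self.t[-1])],
            "ramped_parameters": sorted(self.parameters),
            "events": self.events,
        }
        Path(path).write_text(json.dumps(meta, indent=2))


@dataclass(frozen=True)
class LimitCycle:
    """A periodic attractor: period, state extrema and one sampled orbit."""

    period: float
    E_min: float
    E_max: float
    I_min: float
    I_max: float
    orbit: np.ndarray        # (N, 2) closed polyline in Omega
    closure_error: float

    @property
    def amplitude_E(self) -> float:
        return self.E_max - self.E_min

    def mean_state(self) -> tuple[float, float]:
        return float(np.mean(self.orbit[:, 0])), float(np.mean(self.orbit[:, 1]))


def _instantaneous_labels(model_at, t: np.ndarray, E: np.ndarray,
                          I: np.ndarray) -> np.ndarray:
    """Seizure-like when both activations sit on the upper asymptote."""
    labels = np.empty(len(t), dtype=object)
    for k in range(len(t)):
        A_E, A_I = model_at(t[k]).activations(E[k], I[k])
        labels[k] = ("seizure-like"
                     if A_E > UPPER_ASYMPTOTE_MIN and A_I > UPPER_ASYMPTOTE_MIN
                     else "normal-like")
    return labels


def simulate(model: SeizureModel, initial_state, t_span: tuple[float, float],
             protocols: list[RampProtocol] | None = None,
             dt: float = 0.05, rtol: float = RTOL, atol: float = ATOL
             ) -> SimulationResult:
    """Integrate the (possibly ramped) system and log regime transitions.

    ``initial_state`` is an (E, I) pair inside Omega. Events record the times
    at which the instantaneous regime label (both activations on the upper
    asymptote = seizure-like) changes.
    """
    E0, I0 = float(initial_state[0]), float(initial_state[1])
    if not (0 <= E0 <= 1 and 0 <= I0 <= 1):
        raise ParameterError("initial state outside Omega")
    protocols = list(protocols or [])
    names = [p.parameter for p in protocols]
    if len(set(names)) != len(names):
        raise ParameterError("duplicate ramp parameters")

    base = model

    def model_at(t: float) -> SeizureModel:
        m = base
        for p in protocols:
            m = m.with_param(p.parameter, float(p.value(t)))
        return m

    if protocols:
        def rhs(t, y):
            dE, dI = model_at(t).vector_field(y[0], y[1], check_domain=False)
            return [float(dE), float(dI)]
    else:
        f = base.rhs()
        def rhs(t, y):
            return f(t, y)

    t_eval = np.arange(t_span[0], t_span[1] + 0.5 * dt, dt)
    sol = solve_ivp(rhs, t_span, [E0, I0], method="LSODA", rtol=rtol,
                    atol=atol, t_eval=t_eval, max_step=5.0)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else t_span[0]}:"
            f" {sol.message}; last state {sol.y[:, -1] if sol.y.size else None}")
    E, I = sol.y
    params = {p.parameter: np.asarray(p.value(sol.t)) for p in protocols}

    labels = _instantaneous_labels(model_at, sol.t, E, I)
    events = []
    for k in range(1, len(labels)):
        if labels[k] != labels[k - 1]:
            events.append({"t": float(sol.t[k]), "from": str(labels[k - 1]),
                           "to": str(labels[k])})
            for p in protocols:
                events[-1][p.parameter] = float(p.value(sol.t[k]))
    return SimulationResult(sol.t, E, I, params, events)


def find_limit_cycle(model: SeizureModel, seed_state=None,
                     transient: float = 100.0, tolerance: float = 1e-6,
                     max_time: float = 2000.0, rtol: float = RTOL,
                     atol: float = ATOL,
                     equilibria: list[Equilibrium] | None = None
                     ) -> LimitCycle | None:
    """Detect the normal-activity limit cycle of an autonomous model.

    Integrates past ``transient``, then watches upward crossings of the
    Poincare section E = E* (the vertical line through the inner fixed
    point). The cycle is accepted when successive section returns agree
    within ``tolerance`` in state space; the period is the median of the
    last (up to 5) return intervals. Returns ``None`` — with a logged
    reason — if the trajectory is captured by an attracting fixed point or
    no periodicity is established within ``max_time``.
    """
    eqs = equilibria if equilibria is not None else find_equilibria(model)
    if not eqs:
        logger.info("no equilibria found; cannot anchor a Poincare section")
        return None
    inner = eqs[0]
    attractors = [e for e in eqs if e.stability == "attractor"]
    if seed_state is None:
        seed_state = (inner.E + 1e-3, inner.I)
    y0 = [float(seed_state[0]), float(seed_state[1])]

    rhs_flat = model.rhs()

    def rhs(t, y):
        return rhs_flat(t, y)

    events = []

    def section(t, y):
        return y[0] - inner.E
    section.direction = 1.0
    events.append(section)

    for eq in attractors:
        def near(t, y, eq=eq):
            return np.hypot(y[0] - eq.E, y[1] - eq.I) - 1e-4
        near.terminal = True
        events.append(near)

    t0 = 0.0
    cross_t: list[float] = []
    cross_y: list[np.ndarray] = []
    converged_at = None
    while t0 < max_time:
        t1 = min(t0 + max(transient, 200.0), max_time)
        sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", rtol=rtol,
                        atol=atol, events=events, max_step=5.0)
        for te, ye in zip(sol.t_events[0], sol.y_events[0]):
            if te < transient:
                continue
            cross_t.append(float(te))
            cross_y.append(ye.copy())
            if (len(cross_y) >= 2
                    and np.hypot(*(cross_y[-1] - cross_y[-2])) < tolerance
                    and len(cross_t) >= 3):
                converged_at = cross_y[-1]
                break
        if any(ev.size for ev in sol.t_events[1:]):
            logger.info("trajectory captured by a fixed-point attractor; "
                        "no limit cycle from this seed")
            return None
        if converged_at is not None:
            break
        y0 = sol.y[:, -1]
        t0 = sol.t[-1]
        if sol.status == 1:
            break
    if converged_at is None:
        logger.info("no periodic return within max_time=%.0f "
                    "(%d section crossings)", max_time, len(cross_t))
        return None

    returns = np.diff(cross_t[-6:])
    period = float(np.median(returns[-5:]))
    closure = float(np.hypot(*(cross_y[-1] - cross_y[-2])))
    # sample one full orbit from the converged section state
    orbit_sol = solve_ivp(rhs, (0.0, period), converged_at, method="LSODA",
                          rtol=rtol, atol=atol,
                          t_eval=np.linspace(0, period, 400), max_step=5.0)
    orbit = orbit_sol.y.T
    return LimitCycle(
        period=period,
        E_min=float(orbit[:, 0].min()), E_max=float(orbit[:, 0].max()),
        I_min=float(orbit[:, 1].min()), I_max=float(orbit[:, 1].max()),
        orbit=orbit, closure_error=closure)


def classify_regime(model: SeizureModel, attractor,
                    boundary_tol: float = 1e-3) -> str:
    """Physiological role of a verified attractor: normal / seizure / other.

    A seizure has both activations on the upper asymptote (at the fixed
    point, or at the orbit mean for a cycle); normal activity has both on
    the transition segment with minimal non-zero activity. Activations
    within ``boundary_tol`` of a segment boundary raise
    :class:`AmbiguousRegimeError` instead of guessing.
    """
    if isinstance(attractor, Equilibrium):
        if attractor.stability != "attractor":
            return "other"
        A_E, A_I = model.activations(attractor.E, attractor.I)
    elif isinstance(attractor, LimitCycle):
        # time-mean of the activations along the (uniformly sampled) orbit
        aE, aI = model.activations(attractor.orbit[:, 0],
                                   attractor.orbit[:, 1])
        A_E, A_I = float(np.mean(aE)), float(np.mean(aI))
    else:
        raise TypeError("attractor must be an Equilibrium or LimitCycle")
    for a in (float(A_E), float(A_I)):
        if (abs(a - UPPER_ASYMPTOTE_MIN) < boundary_tol
                or abs(a - 0.05) < boundary_tol):
            raise AmbiguousRegimeError(
                f"activation {a:.4f} within {boundary_tol} of a segment "
                "boundary")
    seg_E, seg_I = segment_label(A_E), segment_label(A_I)
    if seg_E == "upper" and seg_I == "upper":
        return "seizure"
    if seg_E == "transition" and seg_I == "transition":
        return "normal"
    return "other"
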