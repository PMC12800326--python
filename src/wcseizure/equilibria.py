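"""Equilibria: location, stability, physiological role, and nullclines.

Fixed points are the intersections of the E-nullcline
``A_E(1-E) - E(1-q_E E) = 0`` and the I-nullcline
``A_I(1-I) - I(1-q_I E) = 0``. Their physiological reading follows the
segment of the activation function each coordinate sits on: the attractor on
the transition segments with minimal non-zero activity is normal brain
activity; the attractor where both activations sit on the upper asymptote is
a seizure — runaway excitation that full inhibitory activation cannot
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import SeizureModel

__all__ = ["Equilibrium", "find_equilibria", "trace_nullclines", "Nullcline",
           "segment_label", "DegenerateStabilityError",
           "LOWER_ASYMPTOTE_MAX", "UPPER_ASYMPTOTE_MIN"]

logger = logging.getLogger(__name__)

#: Activation below this sits on the lower asymptote; above
#: :data:`UPPER_ASYMPTOTE_MIN` on the upper asymptote; else in transition.
LOWER_ASYMPTOTE_MAX = 0.05
UPPER_ASYMPTOTE_MIN = 0.95

#: Eigenvalue real parts closer to zero than this are treated as degenerate.
DEGENERACY_TOL = 1e-8


class DegenerateStabilityError(ValueError):
    """Stability cannot be classified: an eigenvalue real part is ~zero."""


def segment_label(a) -> np.ndarray:
    """Map activation values onto lower / transition / upper segments."""
    a = np.asarray(a, dtype=float)
    out = np.full(a.shape, "transition", dtype=object)
    out[a < LOWER_ASYMPTOTE_MAX] = "lower"
    out[a > UPPER_ASYMPTOTE_MIN] = "upper"
    return out


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with its linearization and physiological role."""

    E: float
    I: float
    eigenvalues: tuple[complex, complex]
    stability: str      # attractor | repeller | saddle | degenerate
    role: str           # normal | seizure | other

    @property
    def location(self) -> tuple[float, float]:
        return self.E, self.I


def _stability(eigs: np.ndarray, strict: bool) -> str:
    re = np.real(eigs)
    if np.any(np.abs(re) < DEGENERACY_TOL):
        if strict:
            raise DegenerateStabilityError(
                f"eigenvalue real part within {DEGENERACY_TOL} of zero: {eigs}")
        return "degenerate"
    if np.all(re < 0):
        return "attractor"
    if np.all(re > 0):
        return "repeller"
    return "saddle"


def _roles(model: SeizureModel, points: np.ndarray,
           stabilities: list[str]) -> list[str]:
    """Assign normal/seizure/other from the activation segments.

    Seizure: an attractor with both activations on the upper asymptote.
    Normal: the attractor (or, if the first transition-segment intersection
    is repelling, that fixed point stands in for the surrounding limit
    cycle's centre and is still labelled 'other') on the transition segments
    with minimal activity.
    """
    roles = []
    for (E, I), stab in zip(points, stabilities):
        A_E, A_I = model.activations(E, I)
        seg_E, seg_I = segment_label(A_E), segment_label(A_I)
        if stab == "attractor" and seg_E == "upper" and seg_I == "upper":
            roles.append("seizure")
        elif (stab == "attractor" and seg_E == "transition"
              and seg_I == "transition"):
            roles.append("normal")
        else:
            roles.append("other")
    # 'normal' must be the minimal-activity transition intersection: if
    # several qualify keep only the one with the smallest E
    normals = [i for i, r in enumerate(roles) if r == "normal"]
    if len(normals) > 1:
        keep = min(normals, key=lambda i: points[i][0])
        for i in normals:
            if i != keep:
                roles[i] = "other"
    return roles


def find_equilibria(model: SeizureModel, grid: int = 50,
                    residual_tol: float = 1e-11, dedup_tol: float = 1e-6,
                    strict: bool = False) -> list[Equilibrium]:
    """All fixed points in Omega via damped Newton from a uniform multistart.

    A ``grid x grid`` lattice of starts is iterated simultaneously with the
    analytic Jacobian; converged iterates are deduplicated within
    ``dedup_tol`` and classified through their eigenvalues. An empty list
    (with a logged diagnostic) means Newton converged from no start.
    """
    g = np.linspace(0.0, 1.0, grid)
    E, I = map(np.ravel, np.meshgrid(g, g))
    E, I = E.copy(), I.copy()
    for _ in range(60):
        fE, fI = model.vector_field(E, I, check_domain=False)
        J = model.jacobian(E, I)
        a, b = J[..., 0, 0], J[..., 0, 1]
        c, d = J[..., 1, 0], J[..., 1, 1]
        det = a * d - b * c
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dE = (d * fE - b * fI) / det
        dI = (a * fI - c * fE) / det
        # damping: cap the step length so iterates cannot overshoot wildly
        step = np.hypot(dE, dI)
        scale = np.minimum(1.0, 0.2 / np.maximum(step, 1e-300))
        E = np.clip(E - dE * scale, -0.2, 1.2)
        I = np.clip(I - dI * scale, -0.2, 1.2)
    fE, fI = model.vector_field(E, I, check_domain=False)
    ok = ((np.abs(fE) < residual_tol) & (np.abs(fI) < residual_tol)
          & (E > -1e-9) & (E < 1 + 1e-9) & (I > -1e-9) & (I < 1 + 1e-9))
    if not np.any(ok):
        logger.warning("Newton converged from no start (grid=%d); residual "
                       "min %.2e", grid, float(np.min(np.hypot(fE, fI))))
        return []
    pts = np.c_[E[ok], I[ok]]
    uniq: list[np.ndarray] = []
    for pt in pts[np.lexsort((pts[:, 1], pts[:, 0]))]:
        if not any(np.hypot(*(pt - u)) < dedup_tol for u in uniq):
            uniq.append(pt)
    points = np.array(uniq)
    points = points[np.argsort(points[:, 0])]
    stabilities, eigs_all = [], []
    for E0, I0 in points:
        eigs = np.linalg.eigvals(model.jacobian(E0, I0))
        eigs_all.append(eigs)
        stabilities.append(_stability(eigs, strict))
    roles = _roles(model, points, stabilities)
    return [Equilibrium(float(E0), float(I0),
                        (complex(e[0]), complex(e[1])), stab, role)
            for (E0, I0), e, stab, role in zip(points, eigs_all,
                                               stabilities, roles)]


# -- nullclines --------------------------------------------------------------

@dataclass(frozen=True)
class Nullcline:
    """Zero-level set of one time derivative, sampled inside Omega.

    ``points`` is an (N, 2) array of (E, I) pairs (not ordered into a single
    polyline: the curve may have several branches), ``segments`` labels each
    point by the activation-function segment it sits on, and ``residual`` is
    the sup-norm of the defining equation over the returned points.
    """

    variable: str            # "E" or "I"
    points: np.ndarray
    segments: np.ndarray
    residual: float


def _nullcline_points(model: SeizureModel, which: str,
                      resolution: int) -> np.ndarray:
    """Scan lines in both axis directions and polish roots with brentq."""
    if which == "E":
        f = lambda E, I: model.vector_field(E, I, check_domain=False)[0]
    else:
        f = lambda E, I: model.vector_field(E, I, check_domain=False)[1]
    grid = np.linspace(0.0, 1.0, resolution)
    fine = np.linspace(0.0, 1.0, 4 * resolution)
    pts = []
    for fixed in grid:
        for scan_E in (True, False):
            vals = f(fine, fixed) if scan_E else f(fixed, fine)
            sgn = np.sign(vals)
            idx = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
            for i in idx:
                if scan_E:
                    root = brentq(lambda x: float(f(x, fixed)),
                                  fine[i], fine[i + 1], xtol=1e-13)
                    pts.append((root, fixed))
                else:
                    root = brentq(lambda x: float(f(fixed, x)),
                                  fine[i], fine[i + 1], xtol=1e-13)
                    pts.append((fixed, root))
            zero = np.nonzero(vals == 0.0)[0]
            for i in zero:
                pts.append((fine[i], fixed) if scan_E else (fixed, fine[i]))
    return np.array(sorted(set(pts))) if pts else np.empty((0, 2))


def trace_nullclines(model: SeizureModel, resolution: int = 200
                     ) -> tuple[Nullcline, Nullcline]:
    """The E- and I-nullclines sampled on at least ``resolution`` lines per
    axis, each point labelled by its activation segment."""
    if resolution < 100:
        raise ValueError("resolution must be >= 100 points per axis")
    out = []
    for which in ("E", "I"):
        pts = _nullcline_points(model, which, resolution)
        if len(pts):
            A_E, A_I = model.activations(pts[:, 0], pts[:, 1])
            act = A_E if which == "E" else A_I
            fE, fI = model.vector_field(pts[:, 0], pts[:, 1],
                                        check_domain=False)
            res = float(np.max(np.abs(fE if which == "E" else fI)))
            segs = segment_label(act)
        else:
            res, segs = 0.0, np.empty(0, dtype=object)
        out.append(Nullcline(which, pts, segs, res))
    return out[0], out[1]
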