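"""One-parameter continuation and bifurcation localization.

Two transition types organize seizure onset and termination here:

* saddle-node (fold): a stable/unstable equilibrium pair is created or
  annihilated; ``det J = 0`` at the fold. Folds are first bracketed by
  bisection on the equilibrium count and then polished on the extended
  system ``(f(E,I;lam) = 0, det J(E,I;lam) = 0)``, so the reported point
  carries ``|det J|`` at numerical zero.
* saddle-homoclinic: the normal-activity limit cycle collides with the
  saddle and disappears; its period diverges on approach. Localization is
  two-stage: bisection on a robust cycle-existence predicate (long
  integration seeded near the inner repeller, Poincare-return convergence),
  then a split-function refinement that shoots the saddle's unstable
  manifold forward and its stable manifold backward onto a mid-loop section
  through the repeller and bisects on the signed gap between the two hits,
  which vanishes exactly at the homoclinic connection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .dynamics import find_limit_cycle
from .equilibria import Equilibrium, find_equilibria
from .model import SeizureModel

__all__ = ["BifurcationPoint", "BifurcationDiagram", "ContinuationError",
           "continue_equilibria", "locate_saddle_homoclinic",
           "termination_threshold", "TerminationScan", "refine_fold",
           "cycle_exists", "homoclinic_evidence"]

logger = logging.getLogger(__name__)


class ContinuationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BifurcationPoint:
    """A localized codimension-one transition in one swept parameter."""

    type: str                 # "saddle_node" | "saddle_homoclinic"
    parameter: str
    value: float
    bracket: tuple[float, float]
    invariant_sets: tuple[str, ...] = ()
    location: tuple[float, float] | None = None   # (E, I) for folds
    det_J: float | None = None

    @property
    def bracket_width(self) -> float:
        return self.bracket[1] - self.bracket[0]


@dataclass
class BifurcationDiagram:
    """Equilibrium branches, optional cycle-extrema branch, and the
    localized bifurcation points of a one-parameter sweep."""

    parameter: str
    grid: np.ndarray
    branches: pd.DataFrame           # parameter, branch_id, E, I, stability, role
    cycle: pd.DataFrame | None
    points: list[BifurcationPoint] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.branches.to_csv(path, index=False)

    def points_summary(self) -> list[dict]:
        return [{
            "type": p.type, "parameter": p.parameter, "value": p.value,
            "bracket": list(p.bracket), "bracket_width": p.bracket_width,
            "invariant_sets": list(p.invariant_sets),
            "det_J": p.det_J,
        } for p in self.points]


# -- fold machinery ----------------------------------------------------------

def _det_J(model: SeizureModel, E: float, I: float) -> float:
    J = model.jacobian(E, I)
    return float(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0])


def refine_fold(model: SeizureModel, parameter: str,
                guess: tuple[float, float, float]
                ) -> tuple[float, float, float] | None:
    """Polish a saddle-node on the extended system (f = 0, det J = 0).

    ``guess`` is (E, I, parameter value). Returns the refined triple or
    ``None`` when Newton does not converge.
    """
    def system(v):
        m = model.with_param(parameter, float(v[2]))
        fE, fI = m.vector_field(v[0], v[1], check_domain=False)
        return [float(fE), float(fI), _det_J(m, v[0], v[1])]

    sol, info, ier, _ = fsolve(system, list(guess), full_output=True,
                               xtol=1e-13)
    if ier != 1 or np.max(np.abs(system(sol))) > 1e-9:
        return None
    return float(sol[0]), float(sol[1]), float(sol[2])


def _bisect_predicate(predicate, lo: float, hi: float, tol: float,
                      max_iter: int = 200) -> tuple[float, float]:
    """Shrink [lo, hi] until width <= tol, keeping predicate(lo) != predicate(hi)."""
    p_lo, p_hi = predicate(lo), predicate(hi)
    if p_lo == p_hi:
        raise ContinuationError(
            f"predicate does not change over [{lo}, {hi}]")
    it = 0
    while hi - lo > tol and it < max_iter:
        mid = 0.5 * (lo + hi)
        if predicate(mid) == p_lo:
            lo = mid
        else:
            hi = mid
        it += 1
    return lo, hi


def _closest_pair(eqs: list[Equilibrium]) -> tuple[float, float]:
    """Midpoint of the two mutually closest equilibria (the coalescing pair)."""
    best, pair = np.inf, None
    for i in range(len(eqs)):
        for j in range(i + 1, len(eqs)):
            d = np.hypot(eqs[i].E - eqs[j].E, eqs[i].I - eqs[j].I)
            if d < best:
                best, pair = d, (eqs[i], eqs[j])
    a, b = pair
    return 0.5 * (a.E + b.E), 0.5 * (a.I + b.I)


def _locate_fold(model: SeizureModel, parameter: str, lo: float, hi: float,
                 tol: float = 1e-4) -> BifurcationPoint:
    """Bisect on the equilibrium count over [lo, hi], then polish."""
    def count(v):
        return len(find_equilibria(model.with_param(parameter, v)))

    b_lo, b_hi = _bisect_predicate(count, lo, hi, tol)
    # seed the extended system from the coalescing pair on the richer side
    rich = b_lo if count(b_lo) > count(b_hi) else b_hi
    eqs = find_equilibria(model.with_param(parameter, rich))
    E0, I0 = _closest_pair(eqs)
    refined = refine_fold(model, parameter, (E0, I0, 0.5 * (b_lo + b_hi)))
    if refined is not None and b_lo - tol <= refined[2] <= b_hi + tol:
        E0, I0, value = refined
        det = _det_J(model.with_param(parameter, value), E0, I0)
    else:
        logger.warning("fold polish failed; reporting bisection midpoint")
        value, det = 0.5 * (b_lo + b_hi), None
    logger.info("saddle-node in %s at %.6f (bracket [%.6f, %.6f])",
                parameter, value, b_lo, b_hi)
    return BifurcationPoint("saddle_node", parameter, value, (b_lo, b_hi),
                            invariant_sets=("equilibrium pair",),
                            location=(E0, I0), det_J=det)


# -- cycle existence and the homoclinic --------------------------------------

def cycle_exists(model: SeizureModel, max_time: float = 2000.0) -> bool:
    """Does the normal-activity limit cycle exist? Seeds just off the inner
    repeller and integrates until Poincare returns converge or an attracting
    fixed point captures the trajectory."""
    return find_limit_cycle(model, max_time=max_time) is not None


def _saddle_frame(model: SeizureModel):
    """Saddle location with oriented eigenframe, plus the inner repeller."""
    eqs = find_equilibria(model)
    saddles = [e for e in eqs if e.stability == "saddle"]
    if len(eqs) < 3 or not saddles:
        return None
    saddle = saddles[0]
    inner = eqs[0]
    s = np.array([saddle.E, saddle.I])
    r = np.array([inner.E, inner.I])
    J = model.jacobian(*s)
    w, V = np.linalg.eig(J)
    iu = int(np.argmax(w.real))
    vu = V[:, iu].real
    vs = V[:, 1 - iu].real
    vu /= np.linalg.norm(vu)
    vs /= np.linalg.norm(vs)
    if np.dot(vu, r - s) < 0:
        vu = -vu
    if np.dot(vs, r - s) < 0:
        vs = -vs
    return s, r, vu, vs


def split_function(model: SeizureModel, eps: float = 1e-8) -> float | None:
    """Signed gap between the saddle's unstable and stable manifolds on a
    section through the repeller; zero exactly at the homoclinic.

    Returns ``None`` when the geometry needed for the measurement is absent
    (fewer than three equilibria, or a manifold that leaves the loop region
    before reaching the section) — this happens far from the bifurcation.
    """
    frame = _saddle_frame(model)
    if frame is None:
        return None
    s, r, vu, vs = frame
    axis = s - r
    axis = axis / np.linalg.norm(axis)
    nvec = np.array([-axis[1], axis[0]])

    fwd = model.rhs()
    def bwd(t, y):
        return -fwd(t, y)

    # rotation sense of the flow around the repeller on the +nvec side
    probe = r + 0.05 * nvec
    fp = fwd(0.0, np.array(probe))
    c = np.sign(float(np.dot(fp, axis))) or 1.0

    def first_hit(fun, y0, direction):
        def cross(t, y):
            return float(np.dot(y - r, axis))
        cross.terminal = True
        cross.direction = direction

        def escape(t, y):
            return float(max(np.max(np.abs(y - 0.5)) - 1.0, -1.0))
        escape.terminal = True
        sol = solve_ivp(fun, (0.0, 500.0), y0, method="LSODA", rtol=1e-12,
                        atol=1e-14, events=[cross, escape], max_step=2.0)
        if not sol.t_events[0].size:
            return None
        return sol.y_events[0][0]

    hu = first_hit(fwd, s + eps * vu, 0)
    if hu is None:
        return None
    side = np.sign(float(np.dot(hu - r, nvec))) or 1.0
    hs = first_hit(bwd, s + eps * vs, -c * side)
    if hs is None:
        return None
    return float(side * np.dot(hu - hs, nvec))


def locate_saddle_homoclinic(model: SeizureModel, parameter: str,
                             bracket: tuple[float, float],
                             tol: float = 1e-4,
                             refine_tol: float = 1e-6) -> BifurcationPoint:
    """Localize the parameter value at which the normal-activity cycle dies
    against the saddle.

    Stage 1 bisects the cycle-existence predicate over ``bracket`` down to
    ``tol``. Stage 2 refines with the manifold split function down to
    ``refine_tol`` when the measurement is available on both sides; if not,
    the stage-1 bracket is reported.
    """
    lo, hi = bracket

    def pred(v):
        return cycle_exists(model.with_param(parameter, v))

    try:
        b_lo, b_hi = _bisect_predicate(pred, lo, hi, tol)
    except ContinuationError as exc:
        raise ContinuationError(
            f"cycle-existence predicate is constant on [{lo}, {hi}]; "
            "provide a bracket that straddles cycle existence") from exc

    # stage 2: split-function bisection in a window around the stage-1 value
    width = max(10 * tol, 1e-3)
    s_lo, s_hi = b_lo - width, b_hi + width
    f_lo = split_function(model.with_param(parameter, s_lo))
    f_hi = split_function(model.with_param(parameter, s_hi))
    if (f_lo is not None and f_hi is not None
            and np.sign(f_lo) != np.sign(f_hi)):
        while s_hi - s_lo > refine_tol:
            mid = 0.5 * (s_lo + s_hi)
            fm = split_function(model.with_param(parameter, mid))
            if fm is None:
                logger.warning("split function unavailable at %.6f; "
                               "stopping refinement", mid)
                break
            if np.sign(fm) == np.sign(f_lo):
                s_lo = mid
            else:
                s_hi = mid
        b_lo, b_hi = s_lo, s_hi
        logger.info("saddle-homoclinic in %s refined to %.6f "
                    "(split-function bracket width %.1e)",
                    parameter, 0.5 * (b_lo + b_hi), b_hi - b_lo)
    else:
        logger.info("split-function refinement unavailable; reporting "
                    "predicate bracket [%.6f, %.6f]", b_lo, b_hi)
    return BifurcationPoint(
        "saddle_homoclinic", parameter, 0.5 * (b_lo + b_hi), (b_lo, b_hi),
        invariant_sets=("normal-activity limit cycle", "saddle"))


def homoclinic_evidence(model: SeizureModel, point: BifurcationPoint,
                        n: int = 5, start_offset: float = 0.1
                        ) -> pd.DataFrame:
    """Cycle period and cycle-to-saddle distance on approach to a homoclinic.

    Samples ``n`` parameter values approaching the critical value
    geometrically from the cycle side; the period should increase
    monotonically and the minimum distance between the orbit and the saddle
    should shrink.
    """
    param = point.parameter
    crit = point.value
    probe = crit - start_offset
    side = 1.0 if cycle_exists(model.with_param(param, probe)) else -1.0
    offsets = start_offset * (0.5 ** np.arange(n))
    rows = []
    for off in offsets:
        value = crit - side * off
        m = model.with_param(param, value)
        eqs = find_equilibria(m)
        cyc = find_limit_cycle(m, equilibria=eqs)
        saddles = [e for e in eqs if e.stability == "saddle"]
        if cyc is None or not saddles:
            continue
        s = np.array([saddles[0].E, saddles[0].I])
        dist = float(np.min(np.hypot(cyc.orbit[:, 0] - s[0],
                                     cyc.orbit[:, 1] - s[1])))
        rows.append({param: value, "period": cyc.period,
                     "cycle_saddle_distance": dist})
    return pd.DataFrame(rows)


# -- public sweeps -----------------------------------------------------------

def continue_equilibria(model: SeizureModel, parameter: str,
                        p_range: tuple[float, float], step: float,
                        include_cycle: bool = False,
                        fold_tol: float = 1e-4) -> BifurcationDiagram:
    """Natural-parameter continuation of all equilibria over ``p_range``.

    Equilibria are re-solved from a multistart at each grid value and joined
    into branches by nearest-neighbour matching; every change in the
    equilibrium count is localized by bisection and polished into a
    saddle-node point. With ``include_cycle`` the normal-activity limit
    cycle's extrema are tracked alongside and its disappearance is localized
    as a saddle-homoclinic point.
    """
    lo, hi = p_range
    grid = np.arange(lo, hi + 0.5 * step, step)
    rows = []
    prev: list[Equilibrium] = []
    prev_ids: list[int] = []
    next_id = 0
    counts = []
    for v in grid:
        m = model.with_param(parameter, float(v))
        eqs = find_equilibria(m)
        counts.append(len(eqs))
        ids = []
        used = set()
        for eq in eqs:
            best_d, best_j = np.inf, None
            for j, pe in enumerate(prev):
                if j in used:
                    continue
                d = np.hypot(eq.E - pe.E, eq.I - pe.I)
                if d < best_d:
                    best_d, best_j = d, j
            if best_j is not None and best_d < max(0.25, 10 * step):
                ids.append(prev_ids[best_j])
                used.add(best_j)
            else:
                ids.append(next_id)
                next_id += 1
        for eq, bid in zip(eqs, ids):
            rows.append({parameter: float(v), "branch_id": bid, "E": eq.E,
                         "I": eq.I, "stability": eq.stability,
                         "role": eq.role})
        prev, prev_ids = eqs, ids

    points: list[BifurcationPoint] = []
    for k in range(1, len(grid)):
        if counts[k] != counts[k - 1]:
            points.append(_locate_fold(model, parameter,
                                       float(grid[k - 1]), float(grid[k]),
                                       tol=fold_tol))

    cycle_df = None
    if include_cycle:
        crows = []
        existence = []
        for v in grid:
            m = model.with_param(parameter, float(v))
            cyc = find_limit_cycle(m)
            existence.append(cyc is not None)
            if cyc is not None:
                crows.append({parameter: float(v), "period": cyc.period,
                              "E_min": cyc.E_min, "E_max": cyc.E_max,
                              "I_min": cyc.I_min, "I_max": cyc.I_max})
        cycle_df = pd.DataFrame(crows)
        for k in range(1, len(grid)):
            if existence[k] != existence[k - 1]:
                points.append(locate_saddle_homoclinic(
                    model, parameter,
                    (float(grid[k - 1]), float(grid[k])), tol=fold_tol))
    points.sort(key=lambda p: p.value)
    return BifurcationDiagram(parameter, grid, pd.DataFrame(rows), cycle_df,
                              points)


@dataclass(frozen=True)
class TerminationScan:
    """Outcome of sweeping an intervention against a seizure attractor."""

    found: bool
    parameter: str
    searched: tuple[float, float]
    point: BifurcationPoint | None = None


def termination_threshold(model: SeizureModel, parameter: str,
                          p_range: tuple[float, float], step: float = 0.1,
                          tol: float = 1e-4) -> TerminationScan:
    """Continue the seizure attractor in an intervention parameter and find
    the saddle-node at which it is annihilated.

    Seizure termination is the disappearance of the seizure attractor via a
    fold, not mere restoration of bistability. If the attractor survives the
    whole admissible range the scan reports ``found=False`` (the expected
    outcome for GABAergic enhancement under depolarizing GABA).
    """
    lo, hi = p_range

    def has_attractor(v):
        eqs = find_equilibria(model.with_param(parameter, v))
        return any(e.stability == "attractor" for e in eqs)

    start = find_equilibria(model.with_param(parameter, lo))
    seizure = [e for e in start if e.role == "seizure"]
    if not seizure:
        raise ContinuationError(
            f"no seizure attractor at {parameter}={lo}; nothing to terminate")

    flip = None
    v = lo
    while v < hi - 1e-12:
        v_next = min(v + step, hi)
        if has_attractor(v) != has_attractor(v_next):
            flip = (v, v_next)
            break
        v = v_next
    if flip is None:
        logger.info("seizure attractor persists over the whole %s range "
                    "[%.3f, %.3f]: no termination", parameter, lo, hi)
        return TerminationScan(False, parameter, (lo, hi))

    b_lo, b_hi = _bisect_predicate(has_attractor, flip[0], flip[1], tol)
    rich = b_lo if has_attractor(b_lo) else b_hi
    eqs = find_equilibria(model.with_param(parameter, rich))
    attr = [e for e in eqs if e.stability == "attractor"]
    sad = [e for e in eqs if e.stability == "saddle"]
    if attr and sad:
        a = max(attr, key=lambda e: e.E)
        s = min(sad, key=lambda e: np.hypot(e.E - a.E, e.I - a.I))
        seed = (0.5 * (a.E + s.E), 0.5 * (a.I + s.I), 0.5 * (b_lo + b_hi))
    else:
        seed = (attr[0].E if attr else 0.5, attr[0].I if attr else 0.5,
                0.5 * (b_lo + b_hi))
    refined = refine_fold(model, parameter, seed)
    if refined is not None and b_lo - tol <= refined[2] <= b_hi + tol:
        E0, I0, value = refined
        det = _det_J(model.with_param(parameter, value), E0, I0)
        loc = (E0, I0)
    else:
        value, det, loc = 0.5 * (b_lo + b_hi), None, None
    point = BifurcationPoint("saddle_node", parameter, value, (b_lo, b_hi),
                             invariant_sets=("seizure attractor", "saddle"),
                             location=loc, det_J=det)
    logger.info("termination threshold %s = %.6f", parameter, value)
    return TerminationScan(True, parameter, (lo, hi), point)
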