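"""Named presets reproducing the sweep and intervention experiments
end-to-end, plus a seeded fixture generator for regression testing.

Each scenario bundles a parameter layer stack with either a ramp protocol
(time-series experiments), a one-parameter continuation (bifurcation
diagrams) or a termination scan (intervention thresholds), and carries the
package's own reference values for self-checking. Ramp windows follow the
hold / 50-time-unit linear ramp / hold pattern of the time-series
experiments; where an experiment's exact ramp endpoints are not prescribed,
the preset's knots are an explicit choice exposed in its config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .bifurcation import (BifurcationPoint, continue_equilibria, cycle_exists,
                          locate_saddle_homoclinic, termination_threshold)
from .dynamics import (AmbiguousRegimeError, RampProtocol, classify_regime,
                       find_limit_cycle, simulate)
from .equilibria import find_equilibria
from .model import SeizureModel
from .params import ModelParameters, split_config

__all__ = ["Scenario", "SCENARIOS", "run_scenario", "generate_fixtures",
           "find_homoclinic", "settle_and_classify"]

logger = logging.getLogger(__name__)


def find_homoclinic(model: SeizureModel, parameter: str,
                    p_range: tuple[float, float], coarse_step: float = 0.25,
                    tol: float = 1e-4) -> BifurcationPoint | None:
    """Scan cycle existence coarsely over ``p_range`` and localize the
    saddle-homoclinic in the first interval where it flips."""
    lo, hi = p_range
    grid = np.arange(lo, hi + 0.5 * coarse_step, coarse_step)
    prev = cycle_exists(model.with_param(parameter, float(grid[0])))
    for a, b in zip(grid[:-1], grid[1:]):
        cur = cycle_exists(model.with_param(parameter, float(b)))
        if cur != prev:
            return locate_saddle_homoclinic(model, parameter,
                                            (float(a), float(b)), tol=tol)
        prev = cur
    logger.info("no cycle-existence change in %s over [%.3f, %.3f]",
                parameter, lo, hi)
    return None


def settle_and_classify(model: SeizureModel, start=(0.1, 0.1),
                        settle_time: float = 400.0) -> str:
    """Integrate from ``start``, then classify the attained attractor."""
    res = simulate(model, start, (0.0, settle_time), dt=0.5)
    y_end = (float(res.E[-1]), float(res.I[-1]))
    eqs = find_equilibria(model)
    try:
        for eq in eqs:
            if np.hypot(eq.E - y_end[0], eq.I - y_end[1]) < 1e-3:
                return classify_regime(model, eq)
        cyc = find_limit_cycle(model, seed_state=y_end, equilibria=eqs)
        if cyc is None:
            return "other"
        return classify_regime(model, cyc)
    except AmbiguousRegimeError:
        return "ambiguous"


@dataclass(frozen=True)
class Scenario:
    """A named, self-contained experiment preset."""

    name: str
    description: str
    config: dict[str, float] = field(default_factory=dict)
    kind: str = "sweep"          # ramp | sweep | threshold
    sweep: dict[str, Any] = field(default_factory=dict)
    ramps: tuple[dict[str, Any], ...] = ()
    expected: dict[str, Any] = field(default_factory=dict)

    def model(self) -> SeizureModel:
        params, dys, itv = split_config(self.config)
        return SeizureModel(params, dys, itv)


def _ramp(parameter, start, stop, t_on=20.0, t_off=70.0, t_end=140.0,
          label=None):
    return {"parameter": parameter, "start": start, "stop": stop,
            "t_on": t_on, "t_off": t_off, "t_end": t_end,
            "label": label or f"{parameter}->{stop}"}


SCENARIOS: dict[str, Scenario] = {}


def _register(s: Scenario) -> None:
    SCENARIOS[s.name] = s


_register(Scenario(
    name="hyperexcitation-ramp",
    description="Drive D_E ramped 0.25->2.75 over [40, 90]: normal-activity "
                "cycle persists until the homoclinic value, then excitatory "
                "activity jumps to seizure.",
    kind="ramp",
    ramps=(_ramp("D_E", 0.25, 2.75, t_on=40.0, t_off=90.0),),
    expected={"final_regime": "seizure-like"},
))
_register(Scenario(
    name="depletion-ramp",
    description="Depletion rho ramped 0->1 over [40, 90]: the cycle grows "
                "in amplitude before dying on the saddle.",
    kind="ramp",
    ramps=(_ramp("rho", 0.0, 1.0, t_on=40.0, t_off=90.0),),
    expected={"final_regime": "seizure-like"},
))
_register(Scenario(
    name="depolarizing-gaba-ramp",
    description="Chloride impairment kappa ramped 0->2 over [40, 90] with "
                "a_PI=5: GABA turns excitatory and seizure onsets.",
    config={"a_PI": 5.0},
    kind="ramp",
    ramps=(_ramp("kappa", 0.0, 2.0, t_on=40.0, t_off=90.0),),
    expected={"final_regime": "seizure-like"},
))
_register(Scenario(
    name="hyperexcitation-sweep",
    description="One-parameter sweep of the excitatory drive D_E: "
                "seizure attractor born at a fold, normal activity lost at "
                "a saddle-homoclinic, repeller/saddle pair annihilated at a "
                "second fold.",
    kind="sweep",
    sweep={"parameter": "D_E", "range": (0.25, 4.0), "step": 0.05,
           "homoclinic_range": (1.5, 2.0)},
    expected={"saddle_node": [1.35308, 3.21222], "saddle_homoclinic": 1.77749},
))
_register(Scenario(
    name="depletion-sweep",
    description="Sweep of the depletion level rho with effective inhibition "
                "I(1 - rho I).",
    kind="sweep",
    sweep={"parameter": "rho", "range": (0.0, 1.0), "step": 0.02,
           "homoclinic_range": (0.75, 0.95)},
    expected={"saddle_node": [0.37447], "saddle_homoclinic": 0.87188},
))
_register(Scenario(
    name="depolarizing-gaba-sweep",
    description="Sweep of the chloride-accumulation parameter kappa with "
                "a_PI=5; the excitatory perception is the subpopulation "
                "blend x_R.",
    config={"a_PI": 5.0},
    kind="sweep",
    sweep={"parameter": "kappa", "range": (0.0, 2.0), "step": 0.05,
           "homoclinic_range": (1.4, 1.8)},
    expected={"saddle_homoclinic": 1.60965},
))
_register(Scenario(
    name="gaba-terminates-hyperexcitation",
    description="Hyperexcitation-driven seizure (D_E=3): GABAergic "
                "enhancement destroys the seizure attractor at a fold; "
                "sigma_GABA peaking at 1.25 fails, 1.5 and 2 succeed.",
    config={"D_E": 3.0},
    kind="threshold",
    sweep={"parameter": "sigma_GABA", "range": (1.0, 3.0), "step": 0.1},
    ramps=tuple(_ramp("sigma_GABA", 1.0, peak, label=f"peak-{peak}")
                for peak in (1.25, 1.5, 2.0)),
    expected={"threshold": 1.30349,
              "ramp_outcomes": {"peak-1.25": "seizure-like",
                                "peak-1.5": "normal-like",
                                "peak-2.0": "normal-like"}},
))
_register(Scenario(
    name="gaba-terminates-depletion",
    description="Depletion-driven seizure (rho=1): enhancement scales the "
                "effective inhibition, so a higher sigma_GABA is needed.",
    config={"rho": 1.0},
    kind="threshold",
    sweep={"parameter": "sigma_GABA", "range": (1.0, 3.0), "step": 0.1},
    expected={"threshold": 1.74285},
))
_register(Scenario(
    name="gaba-fails-depolarizing",
    description="Depolarizing GABA (kappa=1.8, a_PI=5): enhancing an "
                "excitatory transmitter cannot destroy the seizure "
                "attractor; the scan finds no termination.",
    config={"kappa": 1.8, "a_PI": 5.0},
    kind="threshold",
    sweep={"parameter": "sigma_GABA", "range": (1.0, 3.0), "step": 0.1},
    expected={"threshold": None},
))
_register(Scenario(
    name="rs-terminates-depolarizing",
    description="Depolarizing GABA (kappa=1.8, a_PI=5): rhythmic "
                "suppression shifts the upper-asymptote nullcline segments "
                "and annihilates the seizure attractor.",
    config={"kappa": 1.8, "a_PI": 5.0},
    kind="threshold",
    sweep={"parameter": "sigma_RS", "range": (0.0, 2.0), "step": 0.1},
    expected={"threshold": 1.35375},
))


def _seizure_start(model: SeizureModel) -> tuple[float, float]:
    eqs = find_equilibria(model)
    seiz = [e for e in eqs if e.role == "seizure"]
    if seiz:
        return seiz[0].E, seiz[0].I
    return 0.65, 0.55


def run_scenario(name_or_path: str, out_dir: str | Path,
                 self_check: bool = False, tol: float = 1e-4) -> dict:
    """Execute a named (or config-file-defined) scenario and write its
    artifacts: time-series CSVs and/or branch CSVs, a JSON summary with the
    detected bifurcation points and regime transitions, and a run log."""
    if name_or_path in SCENARIOS:
        sc = SCENARIOS[name_or_path]
    elif Path(name_or_path).exists():
        data = json.loads(Path(name_or_path).read_text())
        sc = Scenario(**{**data, "ramps": tuple(data.get("ramps", ()))})
    else:
        raise KeyError(
            f"unknown scenario {name_or_path!r}; available: "
            f"{sorted(SCENARIOS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = sc.model()
    summary: dict[str, Any] = {"scenario": sc.name,
                               "description": sc.description,
                               "config": sc.config}

    if sc.kind == "ramp":
        runs = {}
        for r in sc.ramps:
            proto = RampProtocol.hold_ramp_hold(
                r["parameter"], r["start"], r["stop"], r["t_on"], r["t_off"])
            res = simulate(model, (0.1, 0.1), (0.0, r["t_end"]), [proto])
            res.to_csv(out / f"{sc.name}-{r['label']}.csv")
            runs[r["label"]] = {
                "events": res.events,
                "final_regime": ("seizure-like" if res.events and
                                 res.events[-1]["to"] == "seizure-like"
                                 else ("seizure-like" if _is_seizure_like(
                                     model, r, res) else "normal-like")),
            }
        summary["runs"] = runs

    elif sc.kind == "sweep":
        sw = sc.sweep
        diagram = continue_equilibria(model, sw["parameter"],
                                      tuple(sw["range"]), sw["step"],
                                      fold_tol=tol)
        hom = None
        if "homoclinic_range" in sw:
            hom = locate_saddle_homoclinic(model, sw["parameter"],
                                           tuple(sw["homoclinic_range"]),
                                           tol=tol)
            diagram.points.append(hom)
            diagram.points.sort(key=lambda p: p.value)
        diagram.to_csv(out / f"{sc.name}-branches.csv")
        summary["bifurcations"] = diagram.points_summary()

    elif sc.kind == "threshold":
        sw = sc.sweep
        scan = termination_threshold(model, sw["parameter"],
                                     tuple(sw["range"]), sw["step"], tol=tol)
        summary["termination"] = (
            {"found": True, "value": scan.point.value,
             "bracket": list(scan.point.bracket),
             "det_J": scan.point.det_J}
            if scan.found else
            {"found": False, "searched": list(scan.searched),
             "note": "no termination: seizure attractor persists"})
        runs = {}
        for r in sc.ramps:
            proto = RampProtocol.hold_ramp_hold(
                r["parameter"], r["start"], r["stop"], r["t_on"], r["t_off"])
            res = simulate(model, _seizure_start(model), (0.0, r["t_end"]),
                           [proto])
            res.to_csv(out / f"{sc.name}-{r['label']}.csv")
            final = _final_label(model, r, res)
            runs[r["label"]] = {"events": res.events, "final_regime": final}
        if runs:
            summary["runs"] = runs
    else:
        raise ValueError(f"unknown scenario kind {sc.kind!r}")

    if self_check:
        summary["self_check"] = _self_check(sc, summary)
    (out / f"{sc.name}-summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    return summary


def _final_label(model: SeizureModel, ramp: dict, res) -> str:
    final_model = model.with_param(ramp["parameter"], ramp["stop"])
    A_E, A_I = final_model.activations(res.E[-1], res.I[-1])
    return ("seizure-like" if float(A_E) > 0.95 and float(A_I) > 0.95
            else "normal-like")


def _is_seizure_like(model: SeizureModel, ramp: dict, res) -> bool:
    return _final_label(model, ramp, res) == "seizure-like"


def _self_check(sc: Scenario, summary: dict) -> dict:
    checks = {}
    exp = sc.expected
    if "saddle_node" in exp:
        got = sorted(p["value"] for p in summary.get("bifurcations", [])
                     if p["type"] == "saddle_node")
        ok = (len(got) == len(exp["saddle_node"]) and all(
            abs(g - e) < 1e-3 * max(1.0, abs(e))
            for g, e in zip(got, sorted(exp["saddle_node"]))))
        checks["saddle_node"] = {"expected": exp["saddle_node"],
                                 "got": got, "ok": ok}
    if "saddle_homoclinic" in exp:
        got = [p["value"] for p in summary.get("bifurcations", [])
               if p["type"] == "saddle_homoclinic"]
        ok = bool(got) and abs(got[0] - exp["saddle_homoclinic"]) < 1e-3
        checks["saddle_homoclinic"] = {
            "expected": exp["saddle_homoclinic"], "got": got, "ok": ok}
    if "threshold" in exp:
        term = summary.get("termination", {})
        if exp["threshold"] is None:
            ok = not term.get("found", True)
        else:
            ok = term.get("found") and abs(
                term["value"] - exp["threshold"]) < 1e-3
        checks["threshold"] = {"expected": exp["threshold"],
                               "got": term, "ok": bool(ok)}
    if "ramp_outcomes" in exp:
        got = {k: v["final_regime"]
               for k, v in summary.get("runs", {}).items()}
        checks["ramp_outcomes"] = {
            "expected": exp["ramp_outcomes"], "got": got,
            "ok": got == exp["ramp_outcomes"]}
    if "final_regime" in exp:
        got = {k: v["final_regime"]
               for k, v in summary.get("runs", {}).items()}
        checks["final_regime"] = {
            "expected": exp["final_regime"], "got": got,
            "ok": all(v == exp["final_regime"] for v in got.values())}
    checks["ok"] = all(v["ok"] for k, v in checks.items() if k != "ok")
    return checks


# -- fixtures ----------------------------------------------------------------

_PERTURBED = ("a_EE", "a_EI", "a_IE", "a_II", "theta_E", "mu_E", "theta_I",
              "mu_I", "tau_E", "tau_I", "D_E", "q_E", "q_I")


def generate_fixtures(seed: int, n: int, out_path: str | Path | None = None
                      ) -> list[dict]:
    """Deterministic regression corpus: ``n`` multiplicative +/-10%
    perturbations of the baseline parameters, each settled and classified.

    The unperturbed baseline (classified normal) and a D_E=4 variant
    (classified seizure) are always included, so outcome drift after a
    refactor is caught immediately.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base = ModelParameters.baseline()
    entries = [("baseline", base), ("baseline-DE4", base.replace(D_E=4.0))]
    for k in range(n):
        factors = {name: float(rng.uniform(0.9, 1.1)) for name in _PERTURBED}
        values = {name: getattr(base, name) * factors[name]
                  for name in _PERTURBED}
        values["q_E"] = min(values["q_E"], 1.0)
        values["q_I"] = min(values["q_I"], 1.0)
        entries.append((f"perturbed-{k:03d}", base.replace(**values)))
    records = []
    for label, params in entries:
        outcome = settle_and_classify(SeizureModel(params))
        records.append({"label": label, "parameters": params.to_dict(),
                        "outcome": outcome})
    if out_path is not None:
        Path(out_path).write_text(json.dumps(
            {"seed": int(seed), "n": int(n), "fixtures": records}, indent=2))
    return records
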