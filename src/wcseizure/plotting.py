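"""Convenience plots: phase portrait, time series, bifurcation diagram.

Plotting is never load-bearing — every figure draws data produced by the
analysis modules. Matplotlib is imported lazily so the rest of the package
works without it.
"""

from __future__ import annotations

from .bifurcation import BifurcationDiagram
from .dynamics import SimulationResult
from .equilibria import find_equilibria, trace_nullclines
from .model import SeizureModel

__all__ = ["plot_phase_portrait", "plot_time_series",
           "plot_bifurcation_diagram"]

_SEGMENT_COLORS = {"lower": "tab:blue", "transition": "black",
                   "upper": "tab:red"}
_STABILITY_MARKS = {"attractor": ("o", "tab:red"),
                    "repeller": ("^", "tab:green"),
                    "saddle": ("s", "tab:orange"),
                    "degenerate": ("x", "gray")}


def plot_phase_portrait(model: SeizureModel, ax=None, resolution: int = 150,
                        cycle=None):
    """Nullclines coloured by activation segment, equilibria by stability,
    and optionally a limit-cycle orbit."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for nc, marker in zip(trace_nullclines(model, resolution), (".", "x")):
        for seg, color in _SEGMENT_COLORS.items():
            pts = nc.points[nc.segments == seg]
            if len(pts):
                ax.plot(pts[:, 0], pts[:, 1], marker, ms=2, color=color,
                        alpha=0.7)
    for eq in find_equilibria(model):
        mark, color = _STABILITY_MARKS[eq.stability]
        ax.plot(eq.E, eq.I, mark, color=color, ms=9,
                label=f"{eq.stability} ({eq.role})")
    if cycle is not None:
        ax.plot(cycle.orbit[:, 0], cycle.orbit[:, 1], "-",
                color="darkgreen", lw=1.5, label="limit cycle")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("E")
    ax.set_ylabel("I")
    ax.legend(loc="upper left", fontsize=7)
    return ax


def plot_time_series(result: SimulationResult, ax=None):
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(result.t, result.E, label="E", color="tab:red")
    ax.plot(result.t, result.I, label="I", color="tab:blue")
    for name, trace in result.parameters.items():
        ax2 = ax.twinx()
        ax2.plot(result.t, trace, "--", color="gray", lw=1)
        ax2.set_ylabel(name, color="gray")
    for ev in result.events:
        ax.axvline(ev["t"], color="k", ls=":", lw=1)
    ax.set_xlabel("t")
    ax.set_ylabel("activity")
    ax.legend(loc="upper left")
    return ax


def plot_bifurcation_diagram(diagram: BifurcationDiagram, ax=None):
    """Equilibrium E-branches (solid attractors, dashed otherwise), the
    cycle-extrema branch, and markers at the localized bifurcations."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    p = diagram.parameter
    for _, branch in diagram.branches.groupby("branch_id"):
        stable = branch["stability"] == "attractor"
        ax.plot(branch[p][stable], branch["E"][stable], ".",
                color="tab:red", ms=3)
        ax.plot(branch[p][~stable], branch["E"][~stable], ".",
                color="gray", ms=2)
    if diagram.cycle is not None and len(diagram.cycle):
        ax.plot(diagram.cycle[p], diagram.cycle["E_min"], "-",
                color="darkgreen", lw=1.2)
        ax.plot(diagram.cycle[p], diagram.cycle["E_max"], "-",
                color="darkgreen", lw=1.2)
    for pt in diagram.points:
        label = "SN" if pt.type == "saddle_node" else "SH"
        ax.axvline(pt.value, color="k", ls=":", lw=0.8)
        ax.annotate(label, (pt.value, 0.95), fontsize=8, ha="center")
    ax.set_xlabel(p)
    ax.set_ylabel("E")
    ax.set_ylim(0, 1)
    return ax
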