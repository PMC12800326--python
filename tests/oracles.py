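"""Independent brute-force oracles used to cross-check the package's own
localization routines."""

import numpy as np
from scipy.optimize import fsolve


def grid_scan_count(model, n: int = 400) -> int:
    """Count equilibria by sign-change cells of both nullclines on an n x n
    lattice, polished by a local 2-D root solve and deduplicated.

    Deliberately independent of the package's multistart-Newton path.
    """
    g = np.linspace(0.0, 1.0, n)
    E, I = np.meshgrid(g, g, indexing="ij")
    fE, fI = model.vector_field(E, I, check_domain=False)
    sE, sI = np.sign(fE), np.sign(fI)

    def changes(s):
        c = np.zeros((n - 1, n - 1), dtype=bool)
        c |= s[:-1, :-1] * s[1:, :-1] <= 0
        c |= s[:-1, :-1] * s[:-1, 1:] <= 0
        c |= s[1:, :-1] * s[1:, 1:] <= 0
        c |= s[:-1, 1:] * s[1:, 1:] <= 0
        return c

    cells = np.argwhere(changes(sE) & changes(sI))
    roots: list[tuple[float, float]] = []
    for i, j in cells:
        x0 = [g[i] + 0.5 / n, g[j] + 0.5 / n]
        sol, info, ier, _ = fsolve(
            lambda v: [float(x) for x in
                       model.vector_field(v[0], v[1], check_domain=False)],
            x0, full_output=True)
        if ier != 1:
            continue
        if not (-1e-9 <= sol[0] <= 1 + 1e-9
                and -1e-9 <= sol[1] <= 1 + 1e-9):
            continue
        if all(np.hypot(sol[0] - r[0], sol[1] - r[1]) > 1e-6
               for r in roots):
            roots.append((float(sol[0]), float(sol[1])))
    return len(roots)
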