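"""Straightforward classical PBD stepper, independent of the package solver.

Used as the oracle for the PBD-limit equivalence test: with springs and
dampers off and zero compliance, one step of the package solver must
reproduce this textbook implementation (predict with external forces,
then Gauss-Seidel distance projections in order) to machine-level
agreement.  Deliberately written with plain loops and no shared code.
"""

import numpy as np


def classical_pbd_step(x, x_prev, w, forces, constraints, dt, iterations):
    """One classical PBD step.

    ``constraints`` is a list of ``(i, j, rest)`` distance constraints.
    Returns the new positions.
    """
    x = np.array(x, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    w = np.asarray(w, dtype=float)
    forces = np.asarray(forces, dtype=float)

    p = np.empty_like(x)
    for n in range(len(x)):
        if w[n] == 0.0:
            p[n] = x[n]
        else:
            p[n] = x[n] + (x[n] - x_prev[n]) + w[n] * forces[n] * dt * dt

    for _ in range(iterations):
        for (i, j, rest) in constraints:
            d = p[j] - p[i]
            length = np.sqrt(d @ d)
            if length < 1e-9:
                continue
            denom = w[i] + w[j]
            if denom == 0.0:
                continue
            corr = (length - rest) / (denom * length) * d
            p[i] += w[i] * corr
            p[j] -= w[j] * corr
    return p
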