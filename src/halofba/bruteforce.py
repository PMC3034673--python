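"""Exhaustive reference solver for tiny flux LPs.

Enumerates candidate basic feasible solutions of
``max c.v  s.t.  S.v = 0,  lo <= v <= hi`` by fixing every subset of
variables at a bound and solving the equality system for the rest.  A
bounded feasible LP attains its optimum at a vertex, and every vertex has
some subset of variables at bounds with the remaining columns solvable, so
the best enumerated feasible point is the global optimum.

This is O(3^n) and only sensible for n <= ~10 reactions; it exists purely
as an independent cross-check of the simplex path and shares no code with
it.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from halofba.model import MetabolicModel, build_stoichiometric_matrix

_RESIDUAL_TOL = 1e-7
_BOUND_TOL = 1e-9


def brute_force_fba_optimum(
    model: MetabolicModel, objective_id: str, maximize: bool = True
) -> float | None:
    """Optimum of the flux LP by exhaustive vertex enumeration.

    Returns ``None`` when no feasible candidate point exists (for models
    with 0 in all bound intervals this cannot happen).  All bounds must be
    finite.
    """
    S = build_stoichiometric_matrix(model).to_dense()
    m, n = S.shape
    lo = np.array([r.lower_bound for r in model.reactions])
    hi = np.array([r.upper_bound for r in model.reactions])
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise ValueError("vertex enumeration requires finite bounds")
    j = model.reaction_index[objective_id]
    rank = np.linalg.matrix_rank(S) if m and n else 0

    best: float | None = None
    # 0 = free, 1 = at lower bound, 2 = at upper bound
    for mask in product((0, 1, 2), repeat=n):
        free = [k for k in range(n) if mask[k] == 0]
        if len(free) > rank:
            continue  # cannot be a vertex: free columns would be dependent
        v = np.where(np.array(mask) == 2, hi, lo)
        if free:
            A = S[:, free]
            fixed = [k for k in range(n) if mask[k] != 0]
            b = -S[:, fixed] @ v[fixed] if fixed else np.zeros(m)
            x, *_ = np.linalg.lstsq(A, b, rcond=None)
            v = v.astype(float)
            v[free] = x
        if np.max(np.abs(S @ v), initial=0.0) > _RESIDUAL_TOL:
            continue
        if np.any(v < lo - _BOUND_TOL) or np.any(v > hi + _BOUND_TOL):
            continue
        value = float(v[j])
        if best is None or (value > best if maximize else value < best):
            best = value
    return best
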