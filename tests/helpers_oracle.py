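"""Brute-force LP oracle: enumerate basic solutions of the flux polytope.

For a bounded feasible LP ``max c·v s.t. S·v = 0, l <= v <= u`` the optimum
is attained at a vertex, i.e. a basic solution where (n - rank S) variables
sit at a bound and the basic columns are independent.  Enumerating every
basis/bound assignment is exponential but exact, and independent of the
simplex implementation it cross-checks.  Only usable for tiny fixtures
(all bounds finite, n <= ~12).
"""

from __future__ import annotations

import itertools

import numpy as np

_FEAS_TOL = 1e-7


def brute_force_max(model, objective: str) -> float:
    """Maximum flux of ``objective`` over all vertices of the flux polytope."""
    S, _, rxns = model.stoichiometric_matrix()
    n = len(rxns)
    lo = np.array([r.lower_bound for r in model.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("vertex enumeration needs finite bounds")
    rank = int(np.linalg.matrix_rank(S))
    j_obj = rxns.index(objective)
    best = -np.inf
    for basic in itertools.combinations(range(n), rank):
        B = S[:, basic]
        if np.linalg.matrix_rank(B) < rank:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        bound_choices = [
            (lo[j],) if lo[j] == hi[j] else (lo[j], hi[j]) for j in nonbasic
        ]
        for values in itertools.product(*bound_choices):
            v = np.zeros(n)
            v[nonbasic] = values
            rhs = -S[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(S.shape[0])
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v[list(basic)] = sol
            if np.max(np.abs(S @ v)) > _FEAS_TOL:
                continue
            if np.any(v < lo - _FEAS_TOL) or np.any(v > hi + _FEAS_TOL):
                continue
            if v[j_obj] > best:
                best = v[j_obj]
    return best
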