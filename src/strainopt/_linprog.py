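"""Thin wrappers around scipy's HiGHS LP solver for flux problems.

All flux LPs in the package share the shape

    optimize c' v   s.t.  S v = 0,  lb <= v <= ub,  (extra rows optional)

so they are funnelled through :func:`solve_flux_lp` to keep tolerance and
status handling in one place.  Values with magnitude below ``ZERO_TOL`` are
reported as exact zeros (they feed MILP bounds downstream).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .exceptions import InfeasibleError, UnboundedError

ZERO_TOL = 1e-9


def _clean(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).copy()
    x[np.abs(x) < ZERO_TOL] = 0.0
    return x


def solve_flux_lp(c, S, lb, ub, sense="max", A_ub=None, b_ub=None,
                  A_eq_extra=None, b_eq_extra=None, context=""):
    """Solve the flux LP; returns (optimum value, flux vector).

    Raises :class:`InfeasibleError` / :class:`UnboundedError` with ``context``
    in the message on failure.
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    A_eq = np.asarray(S, dtype=float)
    b_eq = np.zeros(A_eq.shape[0])
    if A_eq_extra is not None:
        A_eq = np.vstack([A_eq, A_eq_extra])
        b_eq = np.concatenate([b_eq, b_eq_extra])
    res = linprog(sign * c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        raise InfeasibleError(f"LP infeasible{': ' + context if context else ''}")
    if res.status == 3:
        raise UnboundedError(f"LP unbounded{': ' + context if context else ''}")
    if res.status != 0:
        raise InfeasibleError(f"LP solver failure (status {res.status}): {context}")
    value = float(sign * res.fun)
    if abs(value) < ZERO_TOL:
        value = 0.0
    return value, _clean(res.x)
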