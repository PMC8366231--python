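"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths of the implementation they check:
the mapping oracle goes through ridge-regularized normal equations (in the
well-conditioned primal or dual form, with a vanishing ridge), and the lmg
oracle enumerates orderings directly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ridge_limit_solution(x: np.ndarray, y: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Least-squares / minimum-norm solution via normal equations with a
    vanishing ridge.  For wide x (underdetermined) the dual form
    x'(xx' + eps I)^-1 y is used; both converge to the pseudoinverse
    solution as eps -> 0."""
    m, n = x.shape
    if m >= n:
        return np.linalg.solve(x.T @ x + eps * np.eye(n), x.T @ y)
    return x.T @ np.linalg.solve(x @ x.T + eps * np.eye(m), y)


def lmg_by_permutations(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """lmg shares by direct averaging of incremental R^2 over all orderings."""

    def r2(cols: tuple[int, ...]) -> float:
        if not cols:
            return 0.0
        exog = np.column_stack([np.ones(len(y)), x[:, cols]])
        beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
        resid = y - exog @ beta
        return 1.0 - float(resid @ resid) / float(np.sum((y - y.mean()) ** 2))

    p = x.shape[1]
    shares = np.zeros(p)
    orderings = list(itertools.permutations(range(p)))
    for order in orderings:
        seen: tuple[int, ...] = ()
        for j in order:
            shares[j] += r2(tuple(sorted(seen + (j,)))) - r2(seen)
            seen = tuple(sorted(seen + (j,)))
    return shares / math.factorial(p)
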