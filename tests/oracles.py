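"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the LP oracle enumerates
basic feasible solutions with plain numpy instead of calling a solver, and
the binomial-CI oracle inverts the exact binomial CDF by bisection instead
of using beta quantiles.
"""

import itertools

import numpy as np
from scipy import stats


def vertex_enumeration_optimum(S, lower, upper, c, tol=1e-9):
    """Max of c.v over {S v = 0, lower <= v <= upper} by vertex enumeration.

    Every vertex of the (bounded) polytope fixes a subset of variables at a
    box bound with the remainder uniquely determined by the equalities; all
    such subsets and bound patterns are enumerated.  Bounds must be finite
    and the polytope non-empty.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(c)
    best = None
    for n_free in range(n + 1):
        for free in itertools.combinations(range(n), n_free):
            fixed = [j for j in range(n) if j not in free]
            A = S[:, list(free)]
            if n_free and np.linalg.matrix_rank(A, tol=1e-10) < n_free:
                continue  # the free block is not uniquely determined
            for pattern in itertools.product((0, 1), repeat=len(fixed)):
                v = np.zeros(n)
                for j, bit in zip(fixed, pattern):
                    v[j] = upper[j] if bit else lower[j]
                if n_free:
                    b = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
                    sol = np.linalg.lstsq(A, b, rcond=None)[0]
                    v[list(free)] = sol
                if not np.allclose(S @ v, 0.0, atol=tol):
                    continue
                if np.any(v < lower - tol) or np.any(v > upper + tol):
                    continue
                value = float(c @ v)
                if best is None or value > best:
                    best = value
    return best


def random_lp_network(rng, max_reactions=6):
    """Random small flux network: (S, lower, upper, c) with 0 always feasible."""
    n = int(rng.integers(2, max_reactions + 1))
    m = int(rng.integers(1, max(2, n - 1)))
    S = np.zeros((m, n))
    for j in range(n):
        rows = rng.choice(m, size=min(m, int(rng.integers(1, 3))), replace=False)
        for i in rows:
            S[i, j] = float(rng.integers(-2, 3))
    lower = np.where(rng.random(n) < 0.3, -np.round(rng.uniform(0.2, 2.0, n), 3), 0.0)
    upper = np.round(rng.uniform(0.2, 2.0, n), 3)
    c = np.round(rng.uniform(-1.0, 1.0, n), 3)
    c[rng.integers(n)] = 1.0  # at least one reaction genuinely maximised
    return S, lower, upper, c


def binomial_ci_exact_cdf(k, n, alpha=0.05, tol=1e-10):
    """Exact 95% binomial CI by bisecting the binomial CDF (no beta quantiles)."""
    def bisect(f, lo, hi):
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    if k == 0:
        low = 0.0
    else:
        low = bisect(lambda p: stats.binom.sf(k - 1, n, p) < alpha / 2, 0.0, 1.0)
    if k == n:
        high = 1.0
    else:
        high = bisect(lambda p: stats.binom.cdf(k, n, p) >= alpha / 2, 0.0, 1.0)
    return low, high
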