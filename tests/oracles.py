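"""Independent reference implementations used only to check results.

Everything here is deliberately naive (breadth-first search, explicit
enumeration, generic constrained optimisation, term-by-term summation)
and shares no code path with the package.
"""

from collections import deque
from itertools import product
from math import comb, exp, lgamma, log

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize


def bfs_components(mask3d: np.ndarray, connectivity: str = "faces") -> list[set]:
    """Connected components of a boolean 3D mask as sets of linear indices."""
    dims = mask3d.shape
    offsets = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        n_nonzero = sum(1 for x in d if x)
        if connectivity == "faces" and n_nonzero > 1:
            continue
        if connectivity == "faces+edges" and n_nonzero > 2:
            continue
        offsets.append(d)
    seen = np.zeros(dims, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask3d)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(int(np.ravel_multi_index(v, dims)))
            for d in offsets:
                w = tuple(v[i] + d[i] for i in range(3))
                if all(0 <= w[i] < dims[i] for i in range(3)) and mask3d[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(comp)
    return comps


def bfs_cluster_correct(mask3d: np.ndarray, min_size: int, connectivity: str = "faces") -> set:
    return set().union(
        *[c for c in bfs_components(mask3d, connectivity) if len(c) >= min_size], set()
    )


def qp_svm_objective(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Optimal soft-margin linear SVM objective via generic SLSQP.

    Solves the primal slack formulation min 1/2||w||^2 + C sum(xi)
    s.t. xi >= 0, xi >= 1 - y(Xw + b), from several starts.
    """
    n, p = X.shape

    def objective(z):
        w = z[:p]
        return 0.5 * w @ w + C * z[p + 1 :].sum()

    def jac(z):
        g = np.zeros_like(z)
        g[:p] = z[:p]
        g[p + 1 :] = C
        return g

    J1 = np.hstack([np.zeros((n, p + 1)), np.eye(n)])
    J2 = np.hstack([y[:, None] * X, y[:, None], np.eye(n)])
    cons = [
        {"type": "ineq", "fun": lambda z: z[p + 1 :], "jac": lambda z: J1},
        {
            "type": "ineq",
            "fun": lambda z: z[p + 1 :] - (1.0 - y * (X @ z[:p] + z[p])),
            "jac": lambda z: J2,
        },
    ]
    best = np.inf
    rng = np.random.default_rng(0)
    for trial in range(4):
        z0 = np.zeros(p + 1 + n)
        z0[p + 1 :] = 1.0
        if trial:
            z0 = z0 + rng.normal(0, 0.3, z0.size)
            z0[p + 1 :] = np.abs(z0[p + 1 :])
        res = minimize(
            objective, z0, jac=jac, constraints=cons, method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-12},
        )
        if res.success:
            w, b = res.x[:p], res.x[p]
            margins = 1.0 - y * (X @ w + b)
            val = 0.5 * w @ w + C * np.clip(margins, 0, None).sum()
            best = min(best, val)
    return best


def signed_rank_enumeration_p(d: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p by full 2^n enumeration."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        mid = (pos + (pos + (j - i))) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        pos += j - i + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    stats = []
    for signs in product((0, 1), repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    n_total = stats.size
    lower = np.sum(stats <= w_obs + 1e-12) / n_total
    upper = np.sum(stats >= w_obs - 1e-12) / n_total
    return min(1.0, 2.0 * min(lower, upper))


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper tail of the chi-square distribution by numerical integration."""

    def density(t):
        k = df / 2.0
        return exp((k - 1) * log(t) - t / 2.0 - k * log(2.0) - lgamma(k))

    val, _ = quad(density, x, np.inf, limit=200)
    return val


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0) by term-by-term summation."""
    return sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1))
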