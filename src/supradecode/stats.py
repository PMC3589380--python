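"""Nonparametric inference for decoding accuracies.

Four tools: a label-permutation null for classifier accuracy (the
permutation shuffles *training* labels and re-fits, leaving test labels
untouched, so the null respects any class imbalance handling upstream);
an exact/approximate Wilcoxon signed-rank test for paired accuracy
comparisons; Fisher's method for aggregating p-values across
comparisons; and the exact binomial tail test used for pantomime
classification rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps


@dataclass
class PermutationResult:
    """Observed score, its permutation null draws, and the add-one p.

    p = (1 + #{null >= observed}) / (n_perm + 1), hence always > 0 and
    invariant to any monotone transform applied to both observed score
    and null draws.
    """

    observed: float
    null_draws: np.ndarray
    p_value: float


def permutation_test(
    observed: float,
    null_fn: Callable[[np.random.Generator], float],
    n_perm: int = 500,
    seed: int = 0,
) -> PermutationResult:
    """Permutation p-value for an observed score.

    ``null_fn(rng)`` must produce one score under the null — for
    decoding accuracy: permute the training labels with ``rng``, re-fit,
    and score on the untouched test set.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.array([null_fn(rng) for _ in range(n_perm)], dtype=float)
    if not np.all(np.isfinite(null)) or not np.isfinite(observed):
        raise ValueError("scores must be finite")
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationResult(observed=float(observed), null_draws=null, p_value=float(p))


def svm_accuracy_null(train_X, train_y, test_X, test_y, C=None, tol=1e-3):
    """Build a ``null_fn`` that permutes training labels and re-fits.

    Returns a callable suitable for :func:`permutation_test`. ``C``
    defaults to the data-driven constant of the (unpermuted) training
    matrix, matching how the observed classifier was fit.
    """
    from . import svm as _svm

    train_y = np.asarray(train_y, dtype=int)
    if C is None:
        C = _svm.default_C(train_X)

    def null_fn(rng: np.random.Generator) -> float:
        y_perm = rng.permutation(train_y)
        model = _svm.train(train_X, y_perm, C=C, tol=tol)
        return _svm.accuracy(_svm.predict(model, test_X), np.asarray(test_y, dtype=int))

    return null_fn


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p of the signed-rank statistic by subset-sum DP.

    ``ranks`` are the midranks of |differences| (ties allowed); doubling
    makes them integers, and the null distribution of W+ over all 2^n
    equiprobable sign patterns is built by convolution. Equivalent to
    full sign-pattern enumeration.
    """
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(a, b, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped (and p = 1 if none remain); with n <=
    ``exact_max_n`` surviving pairs the p is exact over all sign
    patterns (midranks for ties), above that a normal approximation with
    tie correction is used. Requires >= 5 surviving pairs for the exact
    branch to be meaningful; fewer raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    if n < 5:
        raise ValueError(f"only {n} nonzero differences; need >= 5 for a meaningful test")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return _exact_signed_rank_p(ranks, w_plus)
    res = sps.wilcoxon(d, zero_method="wilcox", method="approx", correction=True)
    return float(res.pvalue)


def fisher_combine(p_values) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square(2k) upper tail."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(x, 2 * p.size))


def binomial_test(k_successes: int, n: int, p0: float = 0.5, alternative: str = "greater") -> float:
    """Exact binomial tail p: P(X >= k) under Binomial(n, p0)."""
    if not (0 <= k_successes <= n):
        raise ValueError("need 0 <= k_successes <= n")
    return float(sps.binomtest(int(k_successes), int(n), p0, alternative=alternative).pvalue)
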