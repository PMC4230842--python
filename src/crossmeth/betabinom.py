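"""Beta-binomial likelihoods and maximum-likelihood fitting.

The beta-binomial is the workhorse emission/test distribution of this
package: methylation read counts at a cytosine are binomial given the
molecule-level methylation level, and the level itself varies across sites,
which the beta mixing captures. Both the HMM emissions and the region-level
differential test fit (alpha, beta) pairs to observed (n_meth, n_total)
counts, optionally with per-site weights (the HMM's posterior state
probabilities).
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln, polygamma
from scipy.stats import betabinom as _sp_betabinom

PARAM_MIN = 1e-3
PARAM_MAX = 1e6

digamma = lambda x: polygamma(0, x)  # noqa: E731
trigamma = lambda x: polygamma(1, x)  # noqa: E731


def logpmf(k: np.ndarray, n: np.ndarray, a: float, b: float) -> np.ndarray:
    """log P(K = k | n, a, b); vectorised over k, n."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )


def loglik(k, n, a, b, weights=None) -> float:
    ll = logpmf(k, n, a, b)
    if weights is not None:
        ll = ll * weights
    return float(np.sum(ll))


def rvs(n, a, b, rng: np.random.Generator) -> np.ndarray:
    """Draw beta-binomial counts (level per trial unit drawn from Beta(a, b))."""
    p = rng.beta(a, b, size=np.shape(n))
    return rng.binomial(n, p)


def moment_init(k, n, weights=None, default_conc: float = 10.0) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) from (weighted) per-site rates.

    Falls back to concentration ``default_conc`` when the empirical variance
    is degenerate (zero, or at/above the binomial-mixture bound m(1-m)).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    ok = n > 0
    k, n = k[ok], n[ok]
    if weights is None:
        w = np.ones_like(n)
    else:
        w = np.asarray(weights, dtype=float)[ok]
    wsum = w.sum()
    if wsum <= 0 or len(k) == 0:
        return 1.0, 1.0
    r = k / n
    m = float(np.sum(w * r) / wsum)
    v = float(np.sum(w * (r - m) ** 2) / wsum)
    m = min(max(m, 1e-6), 1 - 1e-6)
    bound = m * (1 - m)
    if v <= 0 or v >= bound:
        conc = default_conc
    else:
        conc = max(bound / v - 1.0, 1e-2)
    a = np.clip(m * conc, PARAM_MIN, PARAM_MAX)
    b = np.clip((1 - m) * conc, PARAM_MIN, PARAM_MAX)
    return float(a), float(b)


def fit_mle(
    k,
    n,
    weights=None,
    init: tuple[float, float] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Weighted ML fit of (alpha, beta) by Newton iteration on the score.

    The score uses the digamma form of the beta-binomial log-likelihood
    derivative. A moment-based start keeps the iteration in the attraction
    basin; step halving guards the likelihood from decreasing; parameters
    are clamped to [PARAM_MIN, PARAM_MAX].
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    ok = n > 0
    k, n = k[ok], n[ok]
    if weights is None:
        w = np.ones_like(n)
    else:
        w = np.asarray(weights, dtype=float)[ok]
    if len(k) == 0 or w.sum() <= 0:
        return 1.0, 1.0
    a, b = init if init is not None else moment_init(k, n, w)
    a = float(np.clip(a, PARAM_MIN, PARAM_MAX))
    b = float(np.clip(b, PARAM_MIN, PARAM_MAX))
    ll = loglik(k, n, a, b, w)
    for _ in range(max_iter):
        s = a + b
        ga = float(np.sum(w * (digamma(k + a) - digamma(a) + digamma(s) - digamma(n + s))))
        gb = float(
            np.sum(w * (digamma(n - k + b) - digamma(b) + digamma(s) - digamma(n + s)))
        )
        # Hessian entries
        common = float(np.sum(w * (trigamma(s) - trigamma(n + s))))
        haa = float(np.sum(w * (trigamma(k + a) - trigamma(a)))) + common
        hbb = float(np.sum(w * (trigamma(n - k + b) - trigamma(b)))) + common
        hab = common
        det = haa * hbb - hab * hab
        if not np.isfinite(det) or abs(det) < 1e-300:
            break
        da = -(hbb * ga - hab * gb) / det
        db = -(haa * gb - hab * ga) / det
        step = 1.0
        improved = False
        for _half in range(20):
            na = float(np.clip(a + step * da, PARAM_MIN, PARAM_MAX))
            nb = float(np.clip(b + step * db, PARAM_MIN, PARAM_MAX))
            nll = loglik(k, n, na, nb, w)
            if np.isfinite(nll) and nll >= ll - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        gain = nll - ll
        a, b, ll = na, nb, nll
        if abs(ga) < tol and abs(gb) < tol:
            break
        if gain < tol * (abs(ll) + 1.0) and max(abs(da), abs(db)) * step < 1e-10:
            break
    return a, b


def scipy_logpmf(k, n, a, b):
    """Independent route through scipy's betabinom, for cross-checks."""
    return _sp_betabinom.logpmf(k, n, a, b)
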