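"""Independent reference implementations used only to check the package.

Everything here is deliberately brute force - dense-grid integration,
rational-arithmetic enumeration, tail bisection, exhaustive outcome
summation - and shares no code with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln


def glmm_oracle(alt, depth, treat, grid_half_width=14.0, grid_points=6001):
    """Maximize the binomial random-intercept likelihood by dense numerical
    integration over the random effect plus a generic simplex optimizer;
    Wald p from a central finite-difference Hessian."""
    alt = np.asarray(alt, float)
    depth = np.asarray(depth, float)
    treat = np.asarray(treat, float)
    v = np.linspace(-grid_half_width, grid_half_width, grid_points)
    phi = np.exp(-v * v / 2.0) / math.sqrt(2.0 * math.pi)

    def loglik(theta):
        b0, b1, sg = theta
        eta = b0 + b1 * treat
        total = 0.0
        for a, d, e in zip(alt, depth, eta):
            p = expit(e + sg * v)
            with np.errstate(divide="ignore", invalid="ignore"):
                logf = np.where(
                    (p > 0) & (p < 1),
                    a * np.log(p) + (d - a) * np.log1p(-p), -np.inf)
                logf = np.where((p == 0) & (a == 0), 0.0, logf)
                logf = np.where((p == 1) & (a == d), 0.0, logf)
            total += (np.log(np.trapezoid(np.exp(logf) * phi, v))
                      + gammaln(d + 1) - gammaln(a + 1) - gammaln(d - a + 1))
        return total

    res = optimize.minimize(lambda th: -loglik(th), [0.0, 0.5, 0.5],
                            method="Nelder-Mead",
                            options=dict(xatol=1e-9, fatol=1e-11,
                                         maxiter=10000, maxfev=10000))
    theta = res.x.copy()
    theta[2] = abs(theta[2])
    h = 1e-4
    hess = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            ei = np.eye(3)[i] * h
            ej = np.eye(3)[j] * h
            hess[i, j] = (loglik(theta + ei + ej) - loglik(theta + ei - ej)
                          - loglik(theta - ei + ej)
                          + loglik(theta - ei - ej)) / (4 * h * h)
    if abs(theta[2]) < 1e-4:  # variance boundary: profile out sigma
        cov = np.linalg.inv(-hess[:2, :2])
    else:
        cov = np.linalg.inv(-hess)
    se1 = math.sqrt(cov[1, 1])
    z = theta[1] / se1
    p = 2.0 * stats.norm.sf(abs(z))
    return {"theta": theta, "loglik": loglik(theta), "se1": se1, "p": p}


def clopper_pearson_lower_bisect(minor: int, depth: int, level: float,
                                 tol: float = 1e-12) -> float:
    """Lower CI bound by bisection on the exact binomial upper tail.

    The Clopper-Pearson lower bound is the q solving
    P(X >= minor | depth, q) = (1-level)/2; for minor = 0 it is 0.
    """
    if minor == 0:
        return 0.0
    alpha2 = (1.0 - level) / 2.0

    def upper_tail(q):
        return sum(math.comb(depth, x) * q ** x * (1 - q) ** (depth - x)
                   for x in range(minor, depth + 1))

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if upper_tail(mid) < alpha2:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def hypergeom_upper_tail_exact(N: int, S: int, n: int, s: int) -> Fraction:
    """P(X >= s) for Hypergeometric(N, S, n) in exact rational arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(s, min(n, S) + 1):
        if n - j > N - S:
            continue
        acc += Fraction(math.comb(S, j) * math.comb(N - S, n - j), total)
    return acc


def binom_two_sided_exact(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided binomial p by summation over outcomes."""
    pmf = [math.comb(n, x) * p0 ** x * (1 - p0) ** (n - x)
           for x in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(q for q in pmf if q <= obs * (1 + 1e-12)))


def diffstat_bruteforce(af, cf):
    """Nine-element enumeration of the diffStat definition."""
    diffs = [a - c for a in af for c in cf]
    if all(d > 0 for d in diffs) or all(d < 0 for d in diffs):
        return min(abs(d) for d in diffs)
    return 0.0


def reynolds_fst_symbolic(p1v: float, p2v: float, n1v: int, n2v: int):
    """Transcription of the Reynolds ANOVA formula evaluated via sympy."""
    import sympy as sp

    p1, p2, n1, n2 = sp.symbols("p1 p2 n1 n2", positive=True)
    n = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - 2)
    nc = n - (n1 ** 2 + n2 ** 2) / n
    fst = (msp - msg) / (msp + (nc - 1) * msg)
    val = fst.subs({p1: sp.Rational(p1v).limit_denominator(10**9),
                    p2: sp.Rational(p2v).limit_denominator(10**9),
                    n1: n1v, n2: n2v})
    return float(sp.nsimplify(val))
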