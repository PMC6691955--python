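"""Independent test oracles: generic convex optimisation, exhaustive
enumeration and direct likelihood maximisation. These never share code with
the implementation paths they check."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def elastic_net_objective_oracle(X, y, l1, l2, w):
    """Minimum of the penalised logistic objective by generic convex
    optimisation: split beta = b+ - b- (both >= 0) makes the problem smooth
    and box-constrained, solved with L-BFGS-B."""
    n, p = X.shape

    def f(z):
        bp, bm, b0 = z[:p], z[p:2 * p], z[2 * p]
        beta = bp - bm
        eta = X @ beta + b0
        smooth = np.mean(np.logaddexp(0.0, eta) - y * eta)
        return smooth + l1 * np.sum(w * (bp + bm)) + 0.5 * l2 * np.sum(beta ** 2)

    res = minimize(
        f, np.zeros(2 * p + 1), method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p) + [(None, None)],
        options=dict(maxiter=50_000, ftol=1e-15, gtol=1e-12),
    )
    return float(res.fun)


def binomial_upper_tail_exact(n_correct, n, p0_frac):
    """Arbitrary-precision upper-tail binomial probability via Fractions."""
    p0 = Fraction(p0_frac).limit_denominator(10**6)
    total = Fraction(0)
    for k in range(n_correct, n + 1):
        total += comb(n, k) * p0 ** k * (1 - p0) ** (n - k)
    return float(total)


def fisher_two_tailed_enumeration(a, b, c, d):
    """Two-tailed Fisher p by exhaustive enumeration of all tables with the
    observed margins, in exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    ntot = r1 + r2

    def table_prob(x):  # x = top-left cell
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(ntot, c1))

    p_obs = table_prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = table_prob(x)
        if px <= p_obs:
            total += px
    return float(total)


def mann_whitney_exact_enumeration(x, y, alternative="two-sided"):
    """Exact Mann-Whitney p by enumerating all C(n1+n2, n1) group
    assignments of the pooled (tie-free) sample."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)

    def u_stat(xs, ys):
        return sum((xi > yi) for xi in xs for yi in ys)

    u_obs = u_stat(x, y)
    n_tot = 0
    count_le = count_ge = count_two = 0
    mu = n1 * n2 / 2
    for idx in combinations(range(n1 + n2), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = u_stat(xs, ys)
        n_tot += 1
        if u <= u_obs:
            count_le += 1
        if u >= u_obs:
            count_ge += 1
        if abs(u - mu) >= abs(u_obs - mu):
            count_two += 1
    if alternative == "less":
        return count_le / n_tot
    if alternative == "greater":
        return count_ge / n_tot
    return count_two / n_tot


def _logrank_chi2(times, events, groups):
    """One-df log-rank statistic, written independently of the package."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & (g == g[0])).sum()
        d = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & (g == g[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def logrank_permutation_pvalue(times, events, groups, n_perm=4000, seed=0):
    """Monte-Carlo permutation null of the log-rank statistic."""
    chi2_obs = _logrank_chi2(times, events, groups)
    rng = np.random.default_rng(seed)
    g = np.asarray(groups).copy()
    count = 0
    for _ in range(n_perm):
        rng.shuffle(g)
        if _logrank_chi2(times, events, g) >= chi2_obs - 1e-12:
            count += 1
    return count / n_perm


def efron_partial_loglik(beta, times, events, x):
    """Efron-approximation Cox partial log-likelihood, single covariate."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    x = np.asarray(x, float)
    theta = np.exp(beta * x)
    ll = 0.0
    for tt in np.unique(t[e == 1]):
        died = (t == tt) & (e == 1)
        at_risk = t >= tt
        d = died.sum()
        sum_died_x = x[died].sum()
        risk_sum = theta[at_risk].sum()
        died_sum = theta[died].sum()
        ll += beta * sum_died_x
        for l in range(d):
            ll -= np.log(risk_sum - (l / d) * died_sum)
    return ll


def cox_beta_numerical_oracle(times, events, x):
    """Maximise the Efron partial likelihood with a generic 1-D optimiser."""
    res = minimize_scalar(
        lambda b: -efron_partial_loglik(b, times, events, x),
        bounds=(-8, 8), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun)
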