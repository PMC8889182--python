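"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the library
routines) they are checking: the Fisher oracle enumerates margin-fixed
tables from log-factorials, the OLS oracle uses the raw-sum closed form,
and the ANCOVA oracle computes the nested residual sums of squares by
direct least squares.
"""

import math

import numpy as np


def log_factorial(n: int) -> float:
    return math.lgamma(n + 1)


def hypergeom_log_pmf(k: int, total: int, total_dead: int, n_a: int) -> float:
    """log P(k deaths in group A | margins) via log-factorials."""
    lf = log_factorial
    return (lf(total_dead) - lf(k) - lf(total_dead - k)
            + lf(total - total_dead) - lf(n_a - k) - lf(total - total_dead - n_a + k)
            - (lf(total) - lf(n_a) - lf(total - n_a)))


def fisher_enumeration(dead_a: int, alive_a: int, dead_b: int, alive_b: int) -> float:
    """One-tailed Fisher p by full enumeration of margin-fixed tables."""
    n_a = dead_a + alive_a
    total = n_a + dead_b + alive_b
    total_dead = dead_a + dead_b
    k_min = max(0, total_dead - (total - n_a))
    k_max = min(total_dead, n_a)
    p = 0.0
    for k in range(k_min, k_max + 1):
        if k >= dead_a:
            p += math.exp(hypergeom_log_pmf(k, total, total_dead, n_a))
    return min(p, 1.0)


def ols_closed_form(x, y):
    """Simple-regression slope/intercept/R^2 from the raw sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy, syy = (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    intercept = (sy - slope * sx) / n
    ss_res = syy - 2 * slope * sxy - 2 * intercept * sy + slope**2 * sxx \
        + 2 * slope * intercept * sx + n * intercept**2
    ss_tot = syy - sy**2 / n
    r_squared = 1.0 - ss_res / ss_tot
    return slope, intercept, r_squared


def ancova_f_from_rss(depth, qm, group):
    """Interaction F by explicit nested least squares: F = dRSS/(RSS1/(N-4))."""
    depth = np.asarray(depth, float)
    qm = np.asarray(qm, float)
    g = np.asarray(group, float)
    n = qm.size
    X_full = np.column_stack([np.ones(n), depth, g, depth * g])
    X_red = X_full[:, :3]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, qm, rcond=None)
        resid = qm - X @ beta
        return float(resid @ resid)

    rss1, rss0 = rss(X_full), rss(X_red)
    return ((rss0 - rss1) / 1.0) / (rss1 / (n - 4))
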