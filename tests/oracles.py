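"""Independent brute-force oracles for every metric.

Deliberately written as plain-Python accumulation loops (no numpy
vectorisation, no shared code with the package) so they constitute an
independent route to the same quantities. The through-origin slope is
additionally obtained by numeric minimisation rather than the closed
form.
"""

from __future__ import annotations

import math
from itertools import combinations

from scipy.optimize import minimize_scalar


def mean(xs):
    return sum(xs) / len(xs)


def oracle_r2(xs, ys) -> float:
    mx, my = mean(xs), mean(ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy * sxy / (sxx * syy)


def oracle_slope_numeric(xs, ys) -> float:
    """Through-origin least-squares slope for xs ~ k*ys by minimisation."""
    def sse(k):
        return sum((x - k * y) ** 2 for x, y in zip(xs, ys))

    res = minimize_scalar(sse, bounds=(-1e3, 1e3), method="bounded",
                          options={"xatol": 1e-12})
    return res.x


def oracle_slopes(xs, ys):
    k = sum(x * y for x, y in zip(xs, ys)) / sum(y * y for y in ys)
    kp = sum(x * y for x, y in zip(xs, ys)) / sum(x * x for x in xs)
    return k, kp


def oracle_r0sq_eq3(xs, ys) -> float:
    k = oracle_slope_numeric(xs, ys)
    mx = mean(xs)
    ss_res = sum((x - k * y) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((x - mx) ** 2 for x in xs)
    return 1.0 - ss_res / ss_tot


def oracle_r0prime_sq_swapped(xs, ys) -> float:
    kp = oracle_slope_numeric(ys, xs)  # ys ~ kp*xs
    my = mean(ys)
    ss_res = sum((y - kp * x) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((y - my) ** 2 for y in ys)
    return 1.0 - ss_res / ss_tot


def oracle_r0sq_eq5(xs, ys) -> float:
    sxy = sum(x * y for x, y in zip(xs, ys))
    return sxy * sxy / (sum(x * x for x in xs) * sum(y * y for y in ys))


def oracle_uncentered_corr_sq(xs, ys) -> float:
    return oracle_r0sq_eq5(xs, ys)


def oracle_rm2(r2, r0sq):
    if r2 < r0sq:
        return None
    return r2 * (1.0 - math.sqrt(r2 - r0sq))


def oracle_ccc(xs, ys) -> float:
    n = len(xs)
    mx, my = mean(xs), mean(ys)
    sx2 = sum((x - mx) ** 2 for x in xs) / n
    sy2 = sum((y - my) ** 2 for y in ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    return 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def oracle_exhaustive_permutation_p(group_a, group_b) -> float:
    """Exact permutation p-value for the absolute mean difference."""
    pooled = list(group_a) + list(group_b)
    na = len(group_a)
    observed = abs(mean(group_a) - mean(group_b))
    total = mean(pooled) * len(pooled)
    count = 0
    n_comb = 0
    for idx in combinations(range(len(pooled)), na):
        n_comb += 1
        sa = sum(pooled[i] for i in idx)
        ma = sa / na
        mb = (total - sa) / (len(pooled) - na)
        if abs(ma - mb) >= observed - 1e-12:
            count += 1
    return count / n_comb
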