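"""Independent brute-force oracles for the statistical operations.

Every function here is written directly from the defining formula or by
exhaustive enumeration, deliberately avoiding the package's own code paths
(and scipy/statsmodels where the package uses them), so tests compare two
independent routes to the same quantity.
"""

import math


def pearson_r2_oracle(x, y):
    """Squared Pearson correlation from raw sums."""
    n = len(x)
    sx = sum(x); sy = sum(y)
    sxx = sum(v * v for v in x); syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    return num * num / den


def watterson_oracle(S, n):
    a1 = 0.0
    for i in range(1, n):
        a1 += 1.0 / i
    return S / a1


def tajimas_d_oracle(counts, n):
    """Tajima's D from an SFS vector via the 1989 constants, looped out."""
    S = float(sum(counts))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi = 0.0
    for i, xi in enumerate(counts):
        pi += i * (n - i) * xi
    pi /= n * (n - 1) / 2.0
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1.0))


def wc_fst_oracle(genos1, genos2):
    """Two-population Weir & Cockerham (1984) theta-hat for one site.

    ``genos1``/``genos2`` are lists of diploid alt dosages (0/1/2), missing
    already removed. Returns None for sites monomorphic across both groups.
    """
    r = 2
    n1, n2 = len(genos1), len(genos2)
    p1 = sum(genos1) / (2.0 * n1)
    p2 = sum(genos2) / (2.0 * n2)
    if (p1 == 0.0 and p2 == 0.0) or (p1 == 1.0 and p2 == 1.0):
        return None
    h1 = sum(1 for g in genos1 if g == 1) / n1
    h2 = sum(1 for g in genos2 if g == 1) / n2
    nbar = (n1 + n2) / 2.0
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    if a + b + c == 0.0:
        return None
    return a / (a + b + c)


def welch_oracle(x, y):
    """Welch t statistic, Satterthwaite df and two-tailed p via the t CDF."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2 * se2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df, 2.0 * _t_sf(abs(t), df)


def _t_sf(t, df):
    """Student-t upper tail via the regularized incomplete beta (math lib only)."""
    x = df / (df + t * t)
    return 0.5 * _betainc_reg(df / 2.0, 0.5, x)


def _betainc_reg(a, b, x):
    """Regularized incomplete beta by continued fraction (Lentz)."""
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_front = (
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + a * math.log(x) + b * math.log(1.0 - x)
    )
    if x < (a + 1.0) / (a + b + 2.0):
        return math.exp(ln_front) * _beta_cf(a, b, x) / a
    return 1.0 - math.exp(
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + b * math.log(1.0 - x) + a * math.log(x)
    ) * _beta_cf(b, a, 1.0 - x) / b


def _beta_cf(a, b, x, max_iter=300, eps=1e-15):
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < 1e-300:
        d = 1e-300
    d = 1.0 / d
    h = d
    for m in range(1, max_iter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            break
    return h


def pooled_anova_f_oracle(groups):
    """Classic one-way F from between/within sums of squares."""
    N = sum(len(g) for g in groups)
    k = len(groups)
    grand = sum(sum(g) for g in groups) / N
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups
    )
    return (ssb / (k - 1)) / (ssw / (N - k))


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration (exact rationals).

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with 1e-7 relative
    slack for ties).
    """
    from fractions import Fraction

    r1, r2 = a + b, c + d
    c1 = a + c
    n = a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)

    def prob(aa):
        return Fraction(math.comb(r1, aa) * math.comb(r2, c1 - aa), denom)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    cutoff = p_obs * (1 + Fraction(1, 10**7))
    total = sum(prob(aa) for aa in range(lo, hi + 1) if prob(aa) <= cutoff)
    return float(total)


def bh_oracle(pvals):
    """BH step-up by the textbook procedure: sort, scale, cumulative min."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def jc69_oracle(p):
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
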