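"""Diversity and divergence statistics for homokaryotype contrasts.

Implements the site frequency spectrum (with hypergeometric down-projection
over missing data), Watterson's theta, nucleotide diversity pi, Tajima's D
with the 1989 constants, sliding-window summaries (default 50-kb windows,
10-kb slide, windows with fewer than 100 segregating sites flagged), the
two-population Weir & Cockerham (1984) per-SNP FST estimator, per-sample
heterozygosity, and the significance tests used to contrast groups (Welch's
unequal-variance t-test, one-way ANOVA), all two-tailed at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import hypergeom

from .genio import MISSING, GenotypeMatrix


@dataclass
class SFS:
    """Allele-frequency spectrum of a sample of n chromosomes.

    ``counts[i]`` is the (possibly fractional, after projection) number of
    sites with derived/minor allele count i; the fixed classes (0 and n, and
    for folded spectra anything above n//2) are zero by construction.
    """

    n_chromosomes: int
    counts: np.ndarray
    folded: bool = False

    @property
    def S(self) -> float:
        return float(self.counts.sum())


@dataclass
class WindowStat:
    chrom: str
    start: int   # half-open [start, end) on the 1-based axis
    end: int
    S: float
    theta_w: float
    pi: float
    tajima_d: float
    passes_filter: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def theta_w_per_bp(self) -> float:
        return self.theta_w / self.length

    @property
    def pi_per_bp(self) -> float:
        return self.pi / self.length


@dataclass(frozen=True)
class FstRecord:
    site_index: int
    pos: int
    fst: float
    n1: int
    n2: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple
    p_two_tailed: float
    test_name: str


# ---------------------------------------------------------------------------
# SFS
# ---------------------------------------------------------------------------

def _site_allele_counts(G: GenotypeMatrix):
    """Per-site (alt chromosome count, observed chromosome count)."""
    d = G.dosages
    obs = d != MISSING
    m = 2 * obs.sum(axis=0)
    k = np.where(obs, d, 0).sum(axis=0)
    return k.astype(int), m.astype(int)


def project_counts(k: int, m: int, n: int) -> np.ndarray:
    """Hypergeometric down-projection of one site from m to n chromosomes.

    Returns the expected contribution to spectrum classes 1..n-1 (fixed
    classes dropped: a projected draw that is monomorphic carries no signal).
    """
    out = np.zeros(n + 1)
    i = np.arange(1, n)
    out[1:n] = hypergeom.pmf(i, m, k, n)
    return out


def sfs_from_genotypes(G: GenotypeMatrix, folded: bool = False,
                       min_fraction: float = 0.8) -> SFS:
    """Site frequency spectrum with projection over missing data.

    Sites observed in fewer than ``min_fraction`` of the 2n chromosomes are
    dropped; the remainder are down-projected to the smallest complete
    chromosome count so every site contributes on a common sample size.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    k, m = _site_allele_counts(G)
    floor = int(np.ceil(min_fraction * 2 * G.n_samples))
    usable = m >= max(floor, 2)
    if not usable.any():
        raise ValueError("all sites missing above the projection floor")
    k, m = k[usable], m[usable]
    n = int(m.min())
    counts = np.zeros(n + 1)
    full = m == n
    seg = full & (k > 0) & (k < n)
    if seg.any():
        counts[: n + 1] += np.bincount(k[seg], minlength=n + 1)
    for kk, mm in zip(k[~full], m[~full]):
        if 0 < kk < mm:
            counts += project_counts(int(kk), int(mm), n)
    if folded:
        half = n // 2
        fold = np.zeros(n + 1)
        for i in range(1, n):
            fold[min(i, n - i)] += counts[i]
        # the middle class of an even n is counted once
        counts = np.zeros(n + 1)
        counts[: half + 1] = fold[: half + 1]
    return SFS(n_chromosomes=n, counts=counts, folded=folded)


# ---------------------------------------------------------------------------
# theta, pi, Tajima's D
# ---------------------------------------------------------------------------

def harmonic_a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: float, n_chromosomes: int) -> float:
    """Watterson's estimator S / a1, a1 = sum_{i=1}^{n-1} 1/i."""
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    return S / harmonic_a1(n_chromosomes)


def pi_from_sfs(sfs: SFS) -> float:
    """Mean pairwise differences: sum i (n - i) counts[i] / C(n, 2)."""
    n = sfs.n_chromosomes
    i = np.arange(len(sfs.counts))
    return float(np.sum(i * (n - i) * sfs.counts) / (n * (n - 1) / 2.0))


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants of Tajima (1989)."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(sfs: SFS) -> float:
    """Tajima's D = (pi - S/a1) / sqrt(e1 S + e2 S (S - 1)).

    Undefined (NaN) when S = 0 or n < 4.
    """
    n = sfs.n_chromosomes
    S = sfs.S
    if S <= 0 or n < 4:
        return float("nan")
    c = tajima_constants(n)
    num = pi_from_sfs(sfs) - S / c["a1"]
    den = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1.0))
    return float(num / den)


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def sliding_window_stats(G: GenotypeMatrix, chrom_length: int,
                         window: int = 50_000, step: int = 10_000,
                         min_S: float = 100, folded: bool = True,
                         region: tuple[int, int] | None = None,
                         region_mode: str = "ignore") -> list[WindowStat]:
    """Per-window S, Watterson's theta, pi and Tajima's D along the chromosome.

    Windows are half-open [1 + k*step, 1 + k*step + window) and only fully
    contained windows are emitted. ``region_mode`` controls the optional
    region mask: 'keep' restricts to windows overlapping the region,
    'exclude' drops them, 'ignore' applies no mask.
    """
    if window < step:
        raise ValueError("window must be >= step")
    if region_mode not in ("ignore", "keep", "exclude"):
        raise ValueError(f"unknown region_mode {region_mode!r}")
    out = []
    start = 1
    while start + window - 1 <= chrom_length:
        end = start + window
        if region is not None and region_mode != "ignore":
            overlaps = start <= region[1] and (end - 1) >= region[0]
            if (region_mode == "keep") != overlaps:
                start += step
                continue
        idx = np.nonzero((G.positions >= start) & (G.positions < end))[0]
        if len(idx) == 0:
            out.append(WindowStat(G.chrom, start, end, 0.0, 0.0, 0.0,
                                  float("nan"), False))
        else:
            sfs = sfs_from_genotypes(G.take_sites(idx), folded=folded)
            S = sfs.S
            out.append(
                WindowStat(
                    chrom=G.chrom,
                    start=start,
                    end=end,
                    S=S,
                    theta_w=watterson_theta(S, sfs.n_chromosomes),
                    pi=pi_from_sfs(sfs),
                    tajima_d=tajimas_d(sfs),
                    passes_filter=S >= min_S,
                )
            )
        start += step
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

def weir_cockerham_fst(G: GenotypeMatrix, group1, group2) -> list[FstRecord]:
    """Per-SNP two-population Weir & Cockerham (1984) theta-hat.

    ``group1``/``group2`` are disjoint lists of sample ids. Variance
    components a (among populations), b (among individuals within
    populations) and c (within individuals) are computed from allele
    frequencies, sample sizes, and observed heterozygote frequencies; sites
    monomorphic across both groups, or with fewer than 2 genotyped samples
    in either group, are skipped. Negative estimates are reported as
    computed.
    """
    if set(group1) & set(group2):
        raise ValueError("groups overlap")
    idx1 = [G.sample_ids.index(s) for s in group1]
    idx2 = [G.sample_ids.index(s) for s in group2]
    out = []
    r = 2
    for j in range(G.n_sites):
        comp = []
        for idx in (idx1, idx2):
            d = G.dosages[idx, j]
            d = d[d != MISSING]
            if len(d) < 2:
                comp = None
                break
            comp.append((len(d), d.mean() / 2.0, float(np.mean(d == 1))))
        if comp is None:
            continue
        (n1, p1, h1), (n2, p2, h2) = comp
        if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
            continue
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        if denom == 0:
            continue
        out.append(
            FstRecord(site_index=j, pos=int(G.positions[j]),
                      fst=float(a / denom), n1=n1, n2=n2)
        )
    return out


# ---------------------------------------------------------------------------
# heterozygosity and tests
# ---------------------------------------------------------------------------

def per_sample_heterozygosity(G: GenotypeMatrix, site_idx=None) -> np.ndarray:
    """Fraction of heterozygous genotypes per sample over polymorphic sites.

    Samples with no genotyped site get NaN.
    """
    sub = G if site_idx is None else G.take_sites(site_idx)
    from .ldscan import minor_allele_frequencies

    poly = np.nan_to_num(minor_allele_frequencies(sub)) > 0
    if not poly.any():
        raise ValueError("no polymorphic sites in the requested set")
    d = sub.dosages[:, poly]
    obs = d != MISSING
    n_obs = obs.sum(axis=1)
    n_het = ((d == 1) & obs).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_obs > 0, n_het / n_obs, np.nan)


def welch_t_test(x, y) -> TestResult:
    """Two-tailed Welch t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, (float(len(x) + len(y) - 2),), 1.0, "welch_t")
        raise ValueError("degenerate variance: both groups constant, means differ")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), (float(res.df),),
                      float(res.pvalue), "welch_t")


def anova_oneway(groups) -> TestResult:
    """One-way fixed-effects ANOVA over two or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    N = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.var(pooled) == 0:
        return TestResult(0.0, (float(k - 1), float(N - k)), 1.0, "anova_oneway")
    res = sps.f_oneway(*groups)
    return TestResult(float(res.statistic), (float(k - 1), float(N - k)),
                      float(res.pvalue), "anova_oneway")
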