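"""Independent reference computations used to check the implementation.

These deliberately take different code paths from the package: the
alignment oracle scans every genomic offset with a sliding window; the
exact-test oracle builds the conditional distribution from lgamma-based
pmf values with explicit normalization.
"""

import math

import numpy as np

from srnakit.io import revcomp


def exhaustive_alignments(seq: str, chroms: dict[str, str], max_mm: int = 3):
    """All best-stratum placements by brute-force Hamming scan."""
    hits = []
    for chrom in sorted(chroms):
        arr = np.frombuffer(chroms[chrom].encode(), dtype=np.uint8)
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            L = len(q)
            if L > len(arr):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mm = (windows != qa).sum(axis=1)
            for pos in np.nonzero(mm <= max_mm)[0]:
                hits.append((int(mm[pos]), chrom, int(pos), strand))
    if not hits:
        return []
    best = min(h[0] for h in hits)
    return sorted((c, p, s, m) for m, c, p, s in hits if m == best)


def _log_nb_pmf(k: int, n_libs: int, mu_per_lib: float, dispersion: float) -> float:
    r = n_libs / dispersion
    m = n_libs * mu_per_lib
    return (math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
            + r * math.log(r / (r + m)) + k * math.log(m / (r + m)))


def exact_test_pvalue(s1: int, s2: int, n1: int, n2: int, dispersion: float) -> float:
    """Doubled-smaller-tail conditional p by full enumeration of splits."""
    t = s1 + s2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    probs = [math.exp(_log_nb_pmf(k, n1, mu, dispersion)
                      + _log_nb_pmf(t - k, n2, mu, dispersion))
             for k in range(t + 1)]
    z = sum(probs)
    probs = [p / z for p in probs]
    lower = sum(probs[: s1 + 1])
    upper = sum(probs[s1:])
    return min(1.0, 2.0 * min(lower, upper))


def binomial_conditional_pvalue(s1: int, s2: int, n1: int, n2: int) -> float:
    """Poisson-limit conditional test (binomial split of the total)."""
    from scipy import stats

    t = s1 + s2
    if t == 0:
        return 1.0
    p = n1 / (n1 + n2)
    lower = stats.binom.cdf(s1, t, p)
    upper = stats.binom.sf(s1 - 1, t, p)
    return min(1.0, 2.0 * min(lower, upper))


def tmm_factor_pair(counts_j, counts_ref, trim_m=0.30, trim_a=0.05):
    """Straight-line recomputation of one library's TMM factor vs a reference."""
    x = np.asarray(counts_j, dtype=float)
    xr = np.asarray(counts_ref, dtype=float)
    n, nr = x.sum(), xr.sum()
    ok = (x > 0) & (xr > 0)
    x, xr = x[ok], xr[ok]
    m = np.log2((x / n) / (xr / nr))
    a = 0.5 * np.log2((x / n) * (xr / nr))
    w = (n - x) / (n * x) + (nr - xr) / (nr * xr)
    nn = len(m)
    lo_m = np.floor(nn * trim_m) + 1
    hi_m = nn + 1 - lo_m
    lo_a = np.floor(nn * trim_a) + 1
    hi_a = nn + 1 - lo_a
    from scipy import stats

    rm, ra = stats.rankdata(m), stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
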