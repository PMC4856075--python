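"""Count-based two-group differential expression.

Implements the classic small-sample RNA-seq workflow from first
principles: trimmed-mean-of-M-values (TMM) normalization, a
quantile-adjusted conditional maximum-likelihood (qCML) common
negative-binomial dispersion, the two-sided conditional exact test on
group sums with the smaller tail doubled, and Benjamini-Hochberg FDR.

Counts are adjusted to a common effective library size by moderated
quantile matching (average of normal- and gamma-based quantile maps)
before conditioning, so the exact test's equal-library-size assumption
holds approximately for unequal libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_POISSON_DISP = 1e-10  # below this the Poisson/binomial limit is used


# ----------------------------------------------------------------------
# TMM normalization


def _quantile_factor(counts: np.ndarray, lib_sizes: np.ndarray, p: float = 0.75):
    return np.array([np.quantile(counts[:, j] / lib_sizes[j], p)
                     for j in range(counts.shape[1])])


def tmm_factors(table: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """TMM scaling factors, rescaled to geometric mean 1.

    Reference library: the one whose upper-quartile count/library-size
    is closest to the mean upper quartile. M/A statistics use features
    with nonzero counts in both libraries; the top and bottom trim_m of
    M and trim_a of A are removed; the factor is 2**(inverse-variance
    weighted mean of remaining M values).
    """
    counts = table.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    lib_sizes = counts.sum(axis=0)
    for j, total in enumerate(lib_sizes):
        if total <= 0:
            raise ValueError(f"library {table.columns[j]} has zero total count")
    uq = _quantile_factor(counts, lib_sizes)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    xr = counts[:, ref]
    nr = lib_sizes[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        x = counts[:, j]
        n = lib_sizes[j]
        ok = (x > 0) & (xr > 0)
        if not ok.any():
            continue
        xo, xro = x[ok], xr[ok]
        m = np.log2((xo / n) / (xro / nr))
        a = 0.5 * np.log2((xo / n) * (xro / nr))
        w = (n - xo) / (n * xo) + (nr - xro) / (nr * xro)  # delta-method variance
        if np.max(np.abs(m)) < 1e-6:
            continue
        nn = len(m)
        lo_m, hi_m = np.floor(nn * trim_m) + 1, nn + 1 - (np.floor(nn * trim_m) + 1)
        lo_a, hi_a = np.floor(nn * trim_a) + 1, nn + 1 - (np.floor(nn * trim_a) + 1)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any():
            f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=table.columns, name="norm_factor")


# ----------------------------------------------------------------------
# quantile adjustment to a common library size


def _fit_group_means(counts: np.ndarray, lib_sizes: np.ndarray,
                     dispersion: float, n_iter: int = 30) -> np.ndarray:
    """Per-feature NB rate (per unit library size) for one group of columns.

    Newton iterations on the log-rate with expected information; the
    dispersion is held fixed.
    """
    total = counts.sum(axis=1)
    rate = total / lib_sizes.sum()
    pos = rate > 0
    beta = np.full(counts.shape[0], -np.inf)
    beta[pos] = np.log(rate[pos])
    for _ in range(n_iter):
        mu = np.exp(beta[:, None]) * lib_sizes[None, :]
        denom = 1.0 + dispersion * mu
        score = ((counts - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5, 5)
        beta = beta + np.where(pos, step, 0.0)
    return np.exp(beta)


def _q2q_nbinom(x: np.ndarray, mean_in: np.ndarray, mean_out: np.ndarray,
                dispersion: float) -> np.ndarray:
    """Moderated quantile matching between two NB distributions.

    Maps observations with mean `mean_in` onto the scale of `mean_out`
    by averaging normal- and gamma-approximated quantile transforms,
    using the upper tail for x >= mean to keep the maps numerically
    stable in both directions.
    """
    x = np.asarray(x, dtype=float)
    mean_in = np.broadcast_to(np.asarray(mean_in, dtype=float), x.shape).copy()
    mean_out = np.broadcast_to(np.asarray(mean_out, dtype=float), x.shape).copy()
    eps = 1e-14
    zero = (mean_in < eps) | (mean_out < eps)
    mean_in[zero] += 0.25
    mean_out[zero] += 0.25
    var_in = mean_in * (1.0 + dispersion * mean_in)
    var_out = mean_out * (1.0 + dispersion * mean_out)
    sd_in, sd_out = np.sqrt(var_in), np.sqrt(var_out)
    shape_in, scale_in = mean_in ** 2 / var_in, var_in / mean_in
    shape_out, scale_out = mean_out ** 2 / var_out, var_out / mean_out

    upper = x >= mean_in
    q = np.empty_like(x)
    # normal map
    p_up = stats.norm.sf(x, loc=mean_in, scale=sd_in)
    p_lo = stats.norm.cdf(x, loc=mean_in, scale=sd_in)
    qn = np.where(upper,
                  stats.norm.isf(np.clip(p_up, 1e-300, 1), loc=mean_out, scale=sd_out),
                  stats.norm.ppf(np.clip(p_lo, 1e-300, 1), loc=mean_out, scale=sd_out))
    # gamma map
    g_up = stats.gamma.sf(x, shape_in, scale=scale_in)
    g_lo = stats.gamma.cdf(x, shape_in, scale=scale_in)
    qg = np.where(upper,
                  stats.gamma.isf(np.clip(g_up, 1e-300, 1), shape_out, scale=scale_out),
                  stats.gamma.ppf(np.clip(g_lo, 1e-300, 1), shape_out, scale=scale_out))
    q = (qn + qg) / 2.0
    return np.maximum(q, 0.0)


def equalize_library_sizes(counts: np.ndarray, groups: np.ndarray,
                           dispersion: float, lib_sizes: np.ndarray):
    """Pseudo-counts at the common (geometric-mean) effective library size."""
    common = float(np.exp(np.mean(np.log(lib_sizes))))
    pseudo = np.empty_like(counts, dtype=float)
    for g in np.unique(groups):
        cols = np.nonzero(groups == g)[0]
        rate = _fit_group_means(counts[:, cols], lib_sizes[cols], dispersion)
        for j in cols:
            mean_in = rate * lib_sizes[j]
            mean_out = rate * common
            pseudo[:, j] = _q2q_nbinom(counts[:, j], mean_in, mean_out, dispersion)
    return pseudo, common


# ----------------------------------------------------------------------
# qCML common dispersion


def _cond_log_lik(pseudo: np.ndarray, groups: np.ndarray, dispersion: float) -> float:
    """Summed conditional log-likelihood over features and groups."""
    r = 1.0 / dispersion
    total = 0.0
    for g in np.unique(groups):
        y = pseudo[:, groups == g]
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        total += float(np.sum(special.gammaln(y + r).sum(axis=1)
                              - n * special.gammaln(r)
                              + special.gammaln(n * r)
                              - special.gammaln(z + n * r)))
    return total


def estimate_common_dispersion(table: pd.DataFrame, groups: list[str],
                               norm: pd.Series | None = None,
                               tol: float = 1e-6) -> float:
    """Common NB dispersion by quantile-adjusted conditional ML.

    Pseudo-counts are computed at an initial dispersion of 0.01, the
    conditional likelihood is maximized on a log10 grid over
    [1e-6, 10], and the equalize/maximize cycle is run once more at the
    estimate.
    """
    counts = table.to_numpy(dtype=float)
    garr = np.asarray(groups)
    sizes = np.array([np.sum(garr == g) for g in np.unique(garr)])
    if not (sizes >= 2).any():
        raise ValueError("no group has replication; supply a dispersion explicitly")
    if norm is None:
        norm = tmm_factors(table)
    lib_sizes = counts.sum(axis=0) * norm.to_numpy()

    disp = 0.01
    for _ in range(2):
        pseudo, _common = equalize_library_sizes(counts, garr, disp, lib_sizes)
        res = optimize.minimize_scalar(
            lambda ld: -_cond_log_lik(pseudo, garr, 10.0 ** ld),
            bounds=(-6.0, 1.0), method="bounded",
            options={"xatol": tol},
        )
        disp = float(10.0 ** res.x)
    return disp


# ----------------------------------------------------------------------
# conditional exact test


def _exact_pvalue(s1: int, s2: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided conditional exact p-value for group sums (s1, s2).

    Conditions on t = s1 + s2 under independent NB group sums with
    equalized per-library means; doubles the smaller of the two tails
    (both including the observed split) and caps at 1. In the
    dispersion -> 0 limit the conditional law is binomial(t, n1/(n1+n2)).
    """
    t = s1 + s2
    if t == 0:
        return 1.0
    if dispersion < _POISSON_DISP:
        lower = stats.binom.cdf(s1, t, n1 / (n1 + n2))
        upper = stats.binom.sf(s1 - 1, t, n1 / (n1 + n2))
        return float(min(1.0, 2.0 * min(lower, upper)))
    mu = t / (n1 + n2)
    r1, r2 = n1 / dispersion, n2 / dispersion
    mu1, mu2 = n1 * mu, n2 * mu
    p1 = r1 / (r1 + mu1)
    p2 = r2 / (r2 + mu2)
    k = np.arange(t + 1)
    logp = (stats.nbinom.logpmf(k, r1, p1)
            + stats.nbinom.logpmf(t - k, r2, p2))
    logp -= stats.nbinom.logpmf(t, r1 + r2, (r1 + r2) / (r1 + r2 + mu1 + mu2))
    probs = np.exp(logp)
    lower = probs[: s1 + 1].sum()
    upper = probs[s1:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    logFC: float
    logCPM: float
    pvalue: float
    fdr: float
    direction: str  # up / down / ns
    status: str = "tested"  # tested / allzero / filtered


def exact_test(table: pd.DataFrame, groups: list[str], norm: pd.Series,
               dispersion: float, pair: tuple[str, str] | None = None,
               prior_count: float = 0.125) -> pd.DataFrame:
    """Per-feature conditional exact test.

    logFC is log2(second group of `pair` over the first), computed from
    pseudo-count group means with `prior_count` added per library.
    Returns a DataFrame indexed by feature with columns logFC, logCPM,
    pvalue, status.
    """
    garr = np.asarray(groups)
    labels = sorted(set(groups)) if pair is None else list(pair)
    if len(labels) != 2:
        raise ValueError("exact test requires exactly two groups")
    counts = table.to_numpy(dtype=float)
    lib_sizes = counts.sum(axis=0) * norm.to_numpy()
    pseudo, common = equalize_library_sizes(counts, garr, max(dispersion, 1e-12),
                                            lib_sizes)
    c1 = garr == labels[0]
    c2 = garr == labels[1]
    n1, n2 = int(c1.sum()), int(c2.sum())
    s1 = np.rint(pseudo[:, c1].sum(axis=1)).astype(np.int64)
    s2 = np.rint(pseudo[:, c2].sum(axis=1)).astype(np.int64)

    mean1 = pseudo[:, c1].sum(axis=1) / n1 + prior_count
    mean2 = pseudo[:, c2].sum(axis=1) / n2 + prior_count
    logfc = np.log2(mean2) - np.log2(mean1)
    avg = (pseudo[:, c1].sum(axis=1) + pseudo[:, c2].sum(axis=1)) / (n1 + n2)
    logcpm = np.log2((avg + prior_count) / common * 1e6)

    pvals = np.ones(len(table))
    status = np.full(len(table), "tested", dtype=object)
    for i in range(len(table)):
        if counts[i].sum() == 0:
            status[i] = "allzero"
            logfc[i] = 0.0
            continue
        pvals[i] = _exact_pvalue(int(s1[i]), int(s2[i]), n1, n2, dispersion)
    return pd.DataFrame(
        {"logFC": logfc, "logCPM": logcpm, "pvalue": pvals, "status": status},
        index=table.index,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def run_de(table: pd.DataFrame, groups: list[str], alpha: float = 0.05,
           dispersion: float | None = None, min_cpm: float = 1.0,
           min_libs: int | None = None,
           pair: tuple[str, str] | None = None) -> pd.DataFrame:
    """Full pipeline: TMM -> common dispersion -> exact test -> BH.

    Features below `min_cpm` counts-per-million in fewer than `min_libs`
    libraries are flagged 'filtered' and excluded from testing (set
    min_cpm=0 to disable). Output is ordered by FDR then feature id.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    if len(groups) != table.shape[1]:
        raise ValueError("group labels must cover all columns")
    labels = sorted(set(groups)) if pair is None else list(pair)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    garr = np.asarray(groups)
    if min_libs is None:
        min_libs = int(min(np.sum(garr == labels[0]), np.sum(garr == labels[1])))

    counts = table.to_numpy(dtype=float)
    raw_sizes = counts.sum(axis=0)
    cpm = counts / raw_sizes[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_libs if min_cpm > 0 else np.ones(
        len(table), dtype=bool)

    tested = table.loc[keep]
    norm = tmm_factors(tested if keep.any() else table)
    if dispersion is None:
        dispersion = estimate_common_dispersion(tested, groups, norm)
    res = exact_test(tested, groups, norm, dispersion, pair=(labels[0], labels[1]))
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())

    rows = []
    for feat, row in res.iterrows():
        direction = "ns"
        if row["status"] == "tested" and row["fdr"] < alpha:
            direction = "up" if row["logFC"] > 0 else "down"
        rows.append(DEResult(feat, row["logFC"], row["logCPM"], row["pvalue"],
                             row["fdr"], direction, row["status"]))
    for feat in table.index[~keep]:
        rows.append(DEResult(feat, np.nan, np.nan, np.nan, np.nan, "ns", "filtered"))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("feature_id")
    tested_mask = out["status"] != "filtered"
    out = pd.concat([
        out[tested_mask].sort_index().sort_values("fdr", kind="mergesort"),
        out[~tested_mask].sort_index(),
    ])
    out.attrs["dispersion"] = dispersion
    out.attrs["alpha"] = alpha
    out.attrs["pair"] = tuple(labels)
    return out


def write_de_tsv(path: str | Path, result: pd.DataFrame) -> None:
    result.to_csv(path, sep="\t", float_format="%.6g")


def write_ma_tsv(path: str | Path, result: pd.DataFrame) -> None:
    """MA-plot data: average abundance vs log fold change vs significance."""
    tested = result[result["status"] == "tested"]
    tested[["logCPM", "logFC", "fdr", "direction"]].to_csv(
        path, sep="\t", float_format="%.6g")
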