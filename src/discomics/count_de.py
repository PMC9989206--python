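"""Classic single-factor differential expression for small count matrices.

The workflow is the classic exact-test path for two-group negative-binomial
count data: TMM (trimmed mean of M-values) between-sample normalization,
common-dispersion estimation by conditional maximum likelihood on counts
quantile-equalized to a common library size, a conditional NB exact test per
feature, Benjamini-Hochberg FDR, and fold-change/FDR calling.

Model: counts y_fs ~ NB(mu_fs, phi) with variance mu + phi * mu^2; within a
group all samples share the same expected proportion of the (effective)
library.  The exact test conditions on the per-feature total of the
equalized group sums; the two-sided p-value is the sum of conditional
probabilities of all splits at most as probable as the observed one
("small-p" rule), which reduces to the conditional binomial when phi = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .isomir_quant import CountMatrix

log = logging.getLogger(__name__)

_MIN_DELTA = 1e-4
_MAX_DELTA = 100.0 / 101.0


@dataclass
class DEParams:
    """Calling thresholds (both inclusive) and TMM/display constants."""

    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    prior_count: float = 0.125
    tmm_logratio_trim: float = 0.30
    tmm_abs_trim: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1 (linear scale)")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
        w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, w = m[fin], a[fin], w[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rm, ra = _rank(m), _rank(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """TMM normalization factors, rescaled so their geometric mean is 1.

    The reference sample is the one whose upper-quartile count rate is
    closest to the mean upper quartile.  For each sample, the factor is the
    precision-weighted mean of trimmed M-values against the reference
    (``logratio_trim`` of M and ``abs_trim`` of A trimmed on each side).
    """
    y = counts.to_numpy(dtype=float)
    if lib_sizes is None:
        lib = y.sum(axis=0)
    else:
        lib = pd.Series(lib_sizes, dtype=float)[counts.columns].to_numpy()
    if (lib <= 0).any():
        raise ValueError("all-zero or non-positive library encountered")
    f75 = np.array([np.quantile(y[:, j], 0.75) / lib[j] for j in range(y.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(y[:, j], y[:, ref_idx], lib[j], lib[ref_idx], logratio_trim, abs_trim)
            for j in range(y.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_library_sizes(
    counts: pd.DataFrame, lib_sizes: pd.Series | None = None
) -> pd.Series:
    """Library sizes multiplied by TMM factors (the normalization offset)."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    else:
        lib_sizes = pd.Series(lib_sizes, dtype=float)[counts.columns]
    return lib_sizes * tmm_factors(counts, lib_sizes)


# ---------------------------------------------------------------------------
# Library equalization (quantile adjustment) and common dispersion
# ---------------------------------------------------------------------------

def _group_means(y: np.ndarray, lib: np.ndarray, phi: float) -> np.ndarray:
    """Per-feature NB rate lambda for one group (intercept-only fit).

    Solves sum_s (y - mu) / (1 + phi * mu) = 0 with mu_s = lambda * lib_s by
    damped Newton iteration on beta = log(lambda), vectorized over features.
    """
    total = y.sum(axis=1)
    lam0 = np.maximum(total / lib.sum(), 1e-12)
    beta = np.log(lam0)
    nonzero = total > 0
    for _ in range(60):
        mu = np.exp(beta)[:, None] * lib[None, :]
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5, 5)
        beta = beta + np.where(nonzero, step, 0.0)
        if np.max(np.abs(step[nonzero])) < 1e-10 if nonzero.any() else True:
            break
    lam = np.exp(beta)
    lam[~nonzero] = 0.0
    return lam


def _q2q_nbinom(
    x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray, phi: float
) -> np.ndarray:
    """Quantile-to-quantile adjustment of counts to a new mean.

    Each count is mapped to the matching quantile of NB(output_mean, phi),
    approximating the NB by the average of a normal and a gamma of the same
    mean/variance (continuity-friendly and monotone in x).
    """
    x = np.asarray(x, dtype=float)
    input_mean = np.array(input_mean, dtype=float)
    output_mean = np.array(output_mean, dtype=float)
    eps = 1e-14
    zero = (input_mean < eps) | (output_mean < eps)
    input_mean[zero] += 0.25
    output_mean[zero] += 0.25
    ri = 1.0 + phi * input_mean
    vi = input_mean * ri
    ro = 1.0 + phi * output_mean
    vo = output_mean * ro
    out = np.empty_like(x)
    upper = x >= input_mean
    lower = ~upper

    def _norm_gamma(idx: np.ndarray, tail_upper: bool) -> None:
        if not idx.any():
            return
        xi = x[idx]
        mi, si = input_mean[idx], np.sqrt(vi[idx])
        mo, so = output_mean[idx], np.sqrt(vo[idx])
        shape_i = mi / ri[idx]
        shape_o = mo / ro[idx]
        if tail_upper:
            logp = stats.norm.logsf(xi, loc=mi, scale=si)
            q1 = mo - so * special.ndtri_exp(logp)
            p2 = special.gammaincc(shape_i, xi / ri[idx])
            q2 = special.gammainccinv(shape_o, np.clip(p2, 0.0, 1.0)) * ro[idx]
        else:
            logp = stats.norm.logcdf(xi, loc=mi, scale=si)
            q1 = mo + so * special.ndtri_exp(logp)
            p2 = special.gammainc(shape_i, xi / ri[idx])
            q2 = special.gammaincinv(shape_o, np.clip(p2, 0.0, 1.0)) * ro[idx]
        out[idx] = 0.5 * (q1 + q2)

    _norm_gamma(upper, True)
    _norm_gamma(lower, False)
    return np.clip(out, 0.0, None)


def equalize_library_sizes(
    counts: pd.DataFrame,
    groups: pd.Series,
    phi: float,
    lib_sizes: pd.Series | None = None,
) -> tuple[pd.DataFrame, float]:
    """Adjust counts to pseudo-counts at the geometric-mean library size.

    Group-wise NB rates are fitted at dispersion ``phi`` and each count is
    quantile-mapped from its sample's expected mean to the common-library
    mean, which makes the per-sample distributions exchangeable — the
    conditioning requirement of the exact test.
    """
    y = counts.to_numpy(dtype=float)
    if lib_sizes is None:
        lib = y.sum(axis=0)
    else:
        lib = pd.Series(lib_sizes, dtype=float)[counts.columns].to_numpy()
    if (lib <= 0).any():
        raise ValueError("non-positive library size")
    common_lib = float(np.exp(np.mean(np.log(lib))))
    groups = pd.Series(groups)[counts.columns]
    pseudo = np.zeros_like(y)
    for level in groups.unique():
        cols = np.flatnonzero((groups == level).to_numpy())
        lam = _group_means(y[:, cols], lib[cols], phi)
        input_mean = lam[:, None] * lib[cols][None, :]
        output_mean = np.broadcast_to((lam * common_lib)[:, None], input_mean.shape)
        pseudo[:, cols] = _q2q_nbinom(y[:, cols], input_mean, output_mean.copy(), phi)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common_lib


def _cond_log_lik(pseudo: np.ndarray, group_cols: Sequence[np.ndarray], phi: float) -> float:
    """Conditional NB log-likelihood (given per-group totals), summed."""
    r = 1.0 / phi
    total = 0.0
    for cols in group_cols:
        yg = pseudo[:, cols]
        n = yg.shape[1]
        z = yg.sum(axis=1)
        total += float(
            np.sum(
                special.gammaln(yg + r).sum(axis=1)
                + special.gammaln(n * r)
                - special.gammaln(z + n * r)
                - n * special.gammaln(r)
            )
        )
    return total


@dataclass
class CommonDispersionFit:
    dispersion: float
    pseudo: pd.DataFrame
    common_lib_size: float


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    lib_sizes: pd.Series | None = None,
    rowsum_filter: float = 5.0,
    tol: float = 1e-4,
) -> CommonDispersionFit:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are equalized to a common library size (initially at dispersion
    0.01), the conditional log-likelihood summed over features is maximized
    on the delta = phi/(1+phi) scale, and the equalization is refreshed at
    the new estimate (two rounds).  Features with total count at or below
    ``rowsum_filter`` carry almost no curvature and are excluded from the
    likelihood (not from the returned pseudo-counts).
    """
    groups = pd.Series(groups)[counts.columns]
    if groups.nunique() < 2:
        raise ValueError("need two groups")
    y = counts.to_numpy(dtype=float)
    if not (y > 0).any():
        raise ValueError("degenerate all-zero matrix")
    sel = y.sum(axis=1) > rowsum_filter
    if not sel.any():
        sel = y.sum(axis=1) > 0
    phi = 0.01
    pseudo_df, common_lib = equalize_library_sizes(counts, groups, phi, lib_sizes)
    group_cols = [
        np.flatnonzero((groups == g).to_numpy()) for g in groups.unique()
    ]
    for _ in range(2):
        pseudo_sel = pseudo_df.to_numpy()[sel]

        def neg_ll(delta: float) -> float:
            return -_cond_log_lik(pseudo_sel, group_cols, delta / (1.0 - delta))

        res = minimize_scalar(
            neg_ll, bounds=(_MIN_DELTA, _MAX_DELTA), method="bounded",
            options={"xatol": tol},
        )
        delta = float(res.x)
        phi = delta / (1.0 - delta)
        pseudo_df, common_lib = equalize_library_sizes(counts, groups, phi, lib_sizes)
    return CommonDispersionFit(phi, pseudo_df, common_lib)


# ---------------------------------------------------------------------------
# Conditional NB exact test
# ---------------------------------------------------------------------------

def exact_test_pvalues(
    s1: np.ndarray,
    s2: np.ndarray,
    n1: int,
    n2: int,
    phi: float,
    chunk_flat: int = 2_000_000,
) -> np.ndarray:
    """Two-sided conditional exact test p-values for group sums (s1, s2).

    Conditions on t = s1 + s2 assuming per-sample NB(mu, phi) counts with a
    common mu (equalized libraries); p = sum of conditional probabilities of
    all splits whose probability is <= that of the observed split.  phi = 0
    reduces to the conditional binomial.
    """
    s1 = np.asarray(np.round(s1), dtype=np.int64)
    s2 = np.asarray(np.round(s2), dtype=np.int64)
    if (s1 < 0).any() or (s2 < 0).any():
        raise ValueError("negative group sums")
    t = s1 + s2
    p = np.ones(t.shape[0], dtype=float)
    order = np.argsort(t)
    # process in chunks of bounded flat size to cap memory
    start = 0
    while start < len(order):
        end = start
        flat = 0
        while end < len(order) and (flat == 0 or flat + t[order[end]] + 1 <= chunk_flat):
            flat += t[order[end]] + 1
            end += 1
        idx = order[start:end]
        p[idx] = _exact_chunk(s1[idx], t[idx], n1, n2, phi)
        start = end
    return p


def _exact_chunk(s1: np.ndarray, t: np.ndarray, n1: int, n2: int, phi: float) -> np.ndarray:
    lens = t + 1
    starts = np.concatenate([[0], np.cumsum(lens)])
    total = int(starts[-1])
    fidx = np.repeat(np.arange(t.shape[0]), lens)
    s = np.arange(total, dtype=np.int64) - np.repeat(starts[:-1], lens)
    tf = t[fidx]
    if phi < 1e-10:
        # conditional Poisson: Binomial(t, n1/(n1+n2)) weights (unnormalized)
        lw = (
            -special.gammaln(s + 1.0)
            - special.gammaln(tf - s + 1.0)
            + s * np.log(n1 / n2)
        )
    else:
        r1 = n1 / phi
        r2 = n2 / phi
        lw = (
            special.gammaln(s + r1)
            - special.gammaln(s + 1.0)
            + special.gammaln(tf - s + r2)
            - special.gammaln(tf - s + 1.0)
        )
    seg_max = np.maximum.reduceat(lw, starts[:-1])
    w = np.exp(lw - seg_max[fidx])
    z = np.add.reduceat(w, starts[:-1])
    probs = w / z[fidx]
    p_obs = probs[starts[:-1] + s1]
    mask = probs <= p_obs[fidx] * (1.0 + 1e-12)
    p = np.add.reduceat(np.where(mask, probs, 0.0), starts[:-1])
    return np.clip(p, np.finfo(float).tiny, 1.0)


def exact_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    dispersion: float | None = None,
    lib_sizes: pd.Series | None = None,
    pseudo: pd.DataFrame | None = None,
) -> pd.Series:
    """Exact-test p-values per feature for a two-group count matrix.

    If ``pseudo`` (equalized counts) is not supplied it is computed at the
    given dispersion; if ``dispersion`` is None the common dispersion is
    estimated first.
    """
    groups = pd.Series(groups)[counts.columns]
    levels = list(groups.unique())
    if len(levels) != 2:
        raise ValueError("exact test requires exactly two groups")
    if dispersion is None:
        fit = estimate_common_dispersion(counts, groups, lib_sizes)
        dispersion, pseudo = fit.dispersion, fit.pseudo
    if pseudo is None:
        pseudo, _ = equalize_library_sizes(counts, groups, dispersion, lib_sizes)
    cols1 = groups[groups == levels[0]].index
    cols2 = groups[groups == levels[1]].index
    s1 = pseudo[cols1].sum(axis=1).to_numpy()
    s2 = pseudo[cols2].sum(axis=1).to_numpy()
    p = exact_test_pvalues(s1, s2, len(cols1), len(cols2), dispersion)
    return pd.Series(p, index=counts.index, name="p_value")


def bh_fdr(p_values: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    arr = np.asarray(p_values, dtype=float)
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index, name="fdr")
    return q


# ---------------------------------------------------------------------------
# Orchestration: the full DE table
# ---------------------------------------------------------------------------

def de_table(
    matrix: CountMatrix | pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | None = None,
    params: DEParams | None = None,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """TMM -> common dispersion -> exact test -> BH FDR -> DE calls.

    log2FC is group2 vs group1 (groups ordered by first appearance) from
    prior-count-moderated group-mean pseudo-counts; a feature is DE iff
    linear |FC| >= fc_threshold and FDR <= fdr_threshold (both inclusive).
    """
    params = params or DEParams()
    if isinstance(matrix, CountMatrix):
        counts = matrix.counts
        if groups is None:
            groups = matrix.groups
        if lib_sizes is None:
            lib_sizes = matrix.library_sizes
        features = matrix.features
    else:
        counts = matrix
        features = None
    if groups is None:
        raise ValueError("sample groups are required")
    groups = pd.Series(groups)[counts.columns]
    levels = list(groups.unique())
    if len(levels) != 2:
        raise ValueError("classic single-factor DE requires exactly two groups")
    eff_lib = effective_library_sizes(counts, lib_sizes)
    fit = estimate_common_dispersion(counts, groups, eff_lib)
    p = exact_test(counts, groups, fit.dispersion, eff_lib, fit.pseudo)
    q = bh_fdr(p)

    cols1 = groups[groups == levels[0]].index
    cols2 = groups[groups == levels[1]].index
    m1 = fit.pseudo[cols1].mean(axis=1)
    m2 = fit.pseudo[cols2].mean(axis=1)
    c = params.prior_count
    log2fc = np.log2((m2 + c) / (m1 + c))
    logcpm = np.log2((m1 + m2 + 2 * c) / (2.0 * fit.common_lib_size) * 1e6)

    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "logCPM": logcpm,
            "p_value": p,
            "fdr": q,
        },
        index=counts.index,
    )
    table.attrs["dispersion"] = fit.dispersion
    table.attrs["group_levels"] = levels
    if features is not None and "is_canonical_seed" in features:
        table["is_isomiR"] = ~features["is_canonical_seed"]
    return call_de(table, params, levels)


def call_de(
    table: pd.DataFrame,
    params: DEParams | None = None,
    group_levels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Apply the fold-change/FDR rule and annotate directions."""
    params = params or DEParams()
    if group_levels is None:
        group_levels = table.attrs.get("group_levels", ["group1", "group2"])
    fc_ok = 2.0 ** np.abs(table["log2FC"]) >= params.fc_threshold
    fdr_ok = table["fdr"] <= params.fdr_threshold
    de = fc_ok & fdr_ok
    direction = np.where(
        ~de, "ns", np.where(table["log2FC"] > 0, f"up_in_{group_levels[1]}", f"up_in_{group_levels[0]}")
    )
    out = table.copy()
    out.attrs.update(table.attrs)
    out["de"] = de
    out["direction"] = direction
    return out
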