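"""Singleton-excess statistics and exact tests.

The central statistic is the mutability-adjusted proportion singleton
computed against intergenic expectations:

    iMAPS = (observed singletons - expected singletons) / number of variants

where the expected singleton count is the sum over variants of the
expected proportion-singleton value looked up from the intergenic
calibration table.  Group comparisons are one-sided exact tests on the
2x2 singleton table, evaluated against a null odds ratio derived from the
two groups' expected counts rather than against independence, using
Fisher's noncentral hypergeometric distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class IMAPSResult:
    n_variants: int
    observed_singletons: int
    expected_singletons: float
    imaps: float


@dataclass(frozen=True)
class GroupTest:
    """One-sided exact comparison of singleton excess between two groups."""

    a_singletons: int
    a_nonsingletons: int
    b_singletons: int
    b_nonsingletons: int
    null_odds_ratio: float
    p_value: float
    method: str = "exact"


def imaps(is_singleton: Sequence[bool], expected_ps: Sequence[float]) -> IMAPSResult:
    """Rate of excess singletons over the calibrated expectation.

    Parameters are per-variant: the singleton indicator and the expected
    proportion-singleton value assigned from the matching calibration
    context.
    """
    obs = np.asarray(is_singleton, dtype=bool)
    exp = np.asarray(expected_ps, dtype=float)
    if obs.size == 0:
        raise ValueError("iMAPS is undefined for an empty variant set")
    if obs.shape != exp.shape:
        raise ValueError("is_singleton and expected_ps must align")
    if np.any((exp < 0) | (exp > 1)):
        raise ValueError("expected proportion singleton values must lie in [0, 1]")
    n = obs.size
    observed = int(obs.sum())
    expected = float(exp.sum())
    return IMAPSResult(n, observed, expected, (observed - expected) / n)


# ---------------------------------------------------------------------------
# Fisher's noncentral hypergeometric machinery
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 200_000  # support enumeration is exact well beyond group sizes used


def _log_weights(n1: int, n2: int, t: int, log_psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized log probabilities over the support of X (successes in
    group 1) for Fisher's noncentral hypergeometric with odds ``exp(log_psi)``,
    margins (n1, n2) and total successes t."""
    lo = max(0, t - n2)
    hi = min(n1, t)
    k = np.arange(lo, hi + 1)
    logw = (
        gammaln(n1 + 1)
        - gammaln(k + 1)
        - gammaln(n1 - k + 1)
        + gammaln(n2 + 1)
        - gammaln(t - k + 1)
        - gammaln(n2 - (t - k) + 1)
        + k * log_psi
    )
    return k, logw


def nchg_sf(x: int, n1: int, n2: int, t: int, psi: float) -> float:
    """P(X >= x) under Fisher's noncentral hypergeometric (exact, log-space)."""
    if psi <= 0:
        raise ValueError("noncentrality (odds ratio) must be positive")
    k, logw = _log_weights(n1, n2, t, math.log(psi))
    total = logsumexp(logw)
    mask = k >= x
    if not mask.any():
        return 0.0
    return float(np.exp(logsumexp(logw[mask]) - total))


def nchg_cdf(x: int, n1: int, n2: int, t: int, psi: float) -> float:
    """P(X <= x) under Fisher's noncentral hypergeometric."""
    if psi <= 0:
        raise ValueError("noncentrality (odds ratio) must be positive")
    k, logw = _log_weights(n1, n2, t, math.log(psi))
    total = logsumexp(logw)
    mask = k <= x
    if not mask.any():
        return 0.0
    return float(np.exp(logsumexp(logw[mask]) - total))


def null_odds_ratio(
    exp_a: float, n_a: int, exp_b: float, n_b: int
) -> float:
    """Null odds ratio from expected singleton counts of the two groups.

    psi0 = [expA / (nA - expA)] / [expB / (nB - expB)].
    """
    if not (0 < exp_a < n_a) or not (0 < exp_b < n_b):
        raise ValueError("expected singleton counts must lie strictly inside (0, n)")
    return (exp_a / (n_a - exp_a)) / (exp_b / (n_b - exp_b))


def compare_groups(
    a_singletons: int,
    a_total: int,
    b_singletons: int,
    b_total: int,
    *,
    exp_a: Optional[float] = None,
    exp_b: Optional[float] = None,
    psi0: Optional[float] = None,
) -> GroupTest:
    """One-sided exact test that group A has excess singletons beyond null.

    The null odds ratio ``psi0`` is either given directly or derived from
    the groups' expected singleton counts (``null_odds_ratio``).  With
    psi0 = 1 this reduces to the ordinary one-sided Fisher exact test.
    The p-value is the upper-tail probability of A's singleton count under
    Fisher's noncentral hypergeometric with margins fixed at the observed
    totals.  Degenerate margins (all variants singleton, or none) carry no
    information about the odds ratio; p = 1 is returned.
    """
    if psi0 is None:
        if exp_a is None or exp_b is None:
            raise ValueError("provide either psi0 or expected counts for both groups")
        psi0 = null_odds_ratio(exp_a, a_total, exp_b, b_total)
    if psi0 <= 0:
        raise ValueError("null odds ratio must be positive")
    if min(a_total, b_total) <= 0:
        raise ValueError("both groups must be non-empty")
    t = a_singletons + b_singletons
    method = "exact"
    if t == 0 or t == a_total + b_total:
        p = 1.0
        method = "degenerate"
    elif max(a_total, b_total) <= _EXACT_LIMIT:
        p = nchg_sf(a_singletons, a_total, b_total, t, psi0)
    else:  # pragma: no cover - cohort sizes beyond exact enumeration
        p = _nchg_sf_normal(a_singletons, a_total, b_total, t, psi0)
        method = "normal-approx"
    return GroupTest(
        a_singletons,
        a_total - a_singletons,
        b_singletons,
        b_total - b_singletons,
        float(psi0),
        float(p),
        method,
    )


def _nchg_mean_var(n1: int, n2: int, t: int, psi: float) -> tuple[float, float]:
    k, logw = _log_weights(n1, n2, t, math.log(psi))
    w = np.exp(logw - logw.max())
    w /= w.sum()
    mean = float((k * w).sum())
    var = float(((k - mean) ** 2 * w).sum())
    return mean, var


def _nchg_sf_normal(x: int, n1: int, n2: int, t: int, psi: float) -> float:
    mean, var = _nchg_mean_var(n1, n2, t, psi)
    if var <= 0:
        return 1.0 if x <= mean else 0.0
    # continuity-corrected upper tail
    return float(stats.norm.sf((x - 0.5 - mean) / math.sqrt(var)))


# ---------------------------------------------------------------------------
# Odds ratios with exact conditional confidence intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def odds_ratio_ci(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> OddsRatioResult:
    """Sample odds ratio (a/b)/(c/d) with an exact conditional CI.

    The confidence interval inverts the tails of Fisher's noncentral
    hypergeometric distribution conditioned on the table margins; the
    p-value is the two-sided Fisher exact test.  Zero cells yield 0 or
    infinite OR/CI endpoints, reported rather than raised.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be nonnegative integers")
    if b == 0 or c == 0:
        or_ = math.inf if a > 0 and d > 0 else math.nan
    elif a == 0 or d == 0:
        or_ = 0.0
    else:
        or_ = (a / b) / (c / d)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    n1, n2, t = a + b, c + d, a + c
    lo_support = max(0, t - n2)
    hi_support = min(n1, t)

    def sf_at(log_psi: float) -> float:
        return nchg_sf(a, n1, n2, t, math.exp(log_psi))

    def cdf_at(log_psi: float) -> float:
        return nchg_cdf(a, n1, n2, t, math.exp(log_psi))

    half = alpha / 2
    # lower bound: largest psi with P(X >= a | psi) <= alpha/2 -> solve sf = half
    if a == lo_support:
        ci_low = 0.0
    else:
        ci_low = math.exp(_solve_monotone(lambda lp: sf_at(lp) - half))
    if a == hi_support:
        ci_high = math.inf
    else:
        ci_high = math.exp(_solve_monotone(lambda lp: cdf_at(lp) - half, increasing=False))
    return OddsRatioResult(or_, ci_low, ci_high, p)


def _solve_monotone(f, increasing: bool = True, span: float = 50.0) -> float:
    """Root of a monotone function of log-odds on a widening bracket."""
    lo, hi = -span, span
    flo, fhi = f(lo), f(hi)
    if increasing:
        if flo > 0:
            return lo
        if fhi < 0:
            return hi
    else:
        if flo < 0:
            return lo
        if fhi > 0:
            return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Cross-mode rescaling and weighted benchmark sampling
# ---------------------------------------------------------------------------


def rescale_imaps(
    x: float,
    bench: tuple[float, float],
    genome_wide: tuple[float, float],
) -> float:
    """Two-point affine map from benchmark scale to genome-wide scale.

    ``bench`` and ``genome_wide`` are (synonymous, missense) iMAPS pairs;
    x on the benchmark scale maps linearly so that the benchmark
    synonymous/missense values land on the genome-wide ones.
    """
    b_syn, b_mis = bench
    g_syn, g_mis = genome_wide
    if b_syn == b_mis:
        raise ValueError("degenerate benchmark: synonymous equals missense")
    return g_syn + (x - b_syn) * (g_mis - g_syn) / (b_mis - b_syn)


def weighted_benchmark_sample(
    gene_ids: Sequence,
    gene_weights: dict,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """Sample variant indices with per-gene probability proportional to weight.

    Used to build coding benchmark cohorts reflecting how many regulatory
    sites each gene carries.  Returns indices into ``gene_ids``; sampling is
    with replacement and reproducible given the seed.
    """
    genes = np.asarray(gene_ids)
    w = np.array([gene_weights.get(g, 0.0) for g in genes], dtype=float)
    if np.any(w < 0):
        raise ValueError("gene weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one gene weight must be positive")
    rng = np.random.default_rng(seed)
    return rng.choice(len(genes), size=n_draws, replace=True, p=w / total)


# ---------------------------------------------------------------------------
# Vectorized two-sided Fisher exact p-values (used by calibration)
# ---------------------------------------------------------------------------


def fisher_two_sided(a, b, c, d) -> np.ndarray:
    """Two-sided Fisher exact p-values for arrays of 2x2 tables [[a,b],[c,d]].

    Sums hypergeometric point probabilities not exceeding the observed
    one (with the customary relative tolerance), evaluated in log space.
    Vectorized across tables by padding each table's support.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    r1 = a + b
    r2 = c + d
    t = a + c
    n = r1 + r2
    lo = np.maximum(0, t - r2)
    hi = np.minimum(r1, t)
    widths = hi - lo + 1
    p = np.empty(len(a), dtype=float)
    # tables padded to a shared support width would let one large table
    # inflate the whole batch; process in width-sorted chunks instead
    order = np.argsort(widths)
    sorted_w = widths[order]
    s0 = 0
    while s0 < len(order):
        w0 = max(int(sorted_w[s0]), 1)
        # block ends where padding would exceed 2x the first width or the
        # block area a few million cells
        s1 = int(np.searchsorted(sorted_w, 2 * w0, side="right"))
        s1 = min(max(s1, s0 + 1), s0 + max(1, 4_000_000 // (2 * w0)), len(order))
        idx = order[s0:s1]
        p[idx] = _fisher_two_sided_block(
            a[idx], r1[idx], r2[idx], t[idx], n[idx], lo[idx], hi[idx]
        )
        s0 = s1
    return p


def _fisher_two_sided_block(a, r1, r2, t, n, lo, hi) -> np.ndarray:
    width = int((hi - lo).max()) + 1
    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    kc = np.where(valid, k, lo[:, None])
    logpmf = (
        gammaln(r1 + 1)[:, None]
        - gammaln(kc + 1)
        - gammaln(r1[:, None] - kc + 1)
        + gammaln(r2 + 1)[:, None]
        - gammaln(t[:, None] - kc + 1)
        - gammaln(r2[:, None] - (t[:, None] - kc) + 1)
        + (gammaln(t + 1) + gammaln(n - t + 1) - gammaln(n + 1))[:, None]
    )
    log_obs = np.take_along_axis(logpmf, (a - lo)[:, None], axis=1)[:, 0]
    include = valid & (logpmf <= log_obs[:, None] + 1e-7)
    terms = np.where(include, logpmf, -np.inf)
    mx = terms.max(axis=1)
    p = np.exp(mx) * np.exp(terms - mx[:, None]).sum(axis=1)
    return np.minimum(p, 1.0)
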