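"""Group-comparison statistics: ECDF, two-sample KS, rank tests, Pearson
correlation, total-least-squares regression, and exponential half-life fits.

The KS statistic is the sup of |F1 - F2| over the pooled sample points with
an asymptotic Kolmogorov p-value at effective size n1*n2/(n1+n2) — the same
convention as base R's ks.test for large samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Ecdf",
    "KsResult",
    "TlsFit",
    "DecayFit",
    "ecdf",
    "ks_two_sample",
    "rank_test",
    "pearson_r",
    "tls_fit",
    "fit_half_life",
]


@dataclass
class Ecdf:
    """Empirical CDF: F(x) = (#values <= x) / n, right-continuous."""

    values: np.ndarray  # sorted

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.values, x, side="right") / len(self.values)
        return float(out) if out.ndim == 0 else out

    @property
    def n(self) -> int:
        return len(self.values)


def ecdf(values: Sequence[float]) -> Ecdf:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("ECDF of an empty sample is undefined")
    if not np.isfinite(arr).all():
        raise ValueError("ECDF requires finite values")
    return Ecdf(values=np.sort(arr))


@dataclass(frozen=True)
class KsResult:
    D: float
    p: float
    n1: int
    n2: int


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup_x |F_a(x) - F_b(x)| over the pooled points; two-sided p from the
    asymptotic Kolmogorov distribution evaluated at sqrt(n_eff) * D with
    n_eff = n1*n2/(n1+n2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("KS test requires finite values")
    fa, fb = ecdf(a), ecdf(b)
    pooled = np.concatenate([a, b])
    d = float(np.max(np.abs(fa(pooled) - fb(pooled))))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(stats.kstwobign.sf(math.sqrt(n_eff) * d))
    return KsResult(D=d, p=min(max(p, np.finfo(float).tiny), 1.0), n1=a.size, n2=b.size)


def rank_test(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "rank_sum",
) -> float:
    """Two-sided rank test p-value.

    ``rank_sum`` (Wilcoxon-Mann-Whitney) treats a and b as independent;
    ``signed_rank`` pairs them elementwise (equal lengths required; zero
    differences handled per Pratt; all-zero differences give p = 1). Exact
    enumeration is used when the combined sample size is at most 12 and
    there are no ties; otherwise the normal approximation with tie
    correction applies.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "rank_sum":
        pooled = np.concatenate([a, b])
        small = a.size + b.size <= 12 and len(np.unique(pooled)) == pooled.size
        method = "exact" if small else "asymptotic"
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    if mode == "signed_rank":
        if a.size != b.size:
            raise ValueError("signed_rank requires paired samples of equal length")
        diff = a - b
        if np.all(diff == 0):
            return 1.0
        small = a.size <= 12 and len(np.unique(np.abs(diff[diff != 0]))) == np.count_nonzero(diff)
        method = "exact" if small and not np.any(diff == 0) else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(
                stats.wilcoxon(
                    a, b, zero_method="pratt", alternative="two-sided", method=method
                ).pvalue
            )
    raise ValueError(f"unknown rank test mode {mode!r}")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Product-moment correlation; None when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("pearson_r requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class TlsFit:
    """Orthogonal (total least squares) line fit y = slope*x + intercept.

    ``slope`` is inf for a vertical principal axis, with ``x_intercept`` set.
    ``residual_variance`` is the mean squared orthogonal distance.
    """

    slope: float
    intercept: float
    residual_variance: float
    x_intercept: Optional[float] = None


def tls_fit(x: Sequence[float], y: Sequence[float]) -> TlsFit:
    """Fit the first principal axis of the centered (x, y) cloud.

    Minimizes the sum of squared orthogonal distances (unit error-variance
    ratio). Equivariant under swapping x and y (slope -> 1/slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("tls_fit needs paired vectors of length >= 2")
    xc, yc = x - x.mean(), y - y.mean()
    if np.all(xc == 0) and np.all(yc == 0):
        raise ValueError("tls_fit undefined for identical points")
    # first right singular vector of the n x 2 centered cloud
    _, s, vt = np.linalg.svd(np.column_stack([xc, yc]), full_matrices=False)
    direction = vt[0]
    resid_var = float(s[1] ** 2 / x.size) if s.size > 1 else 0.0
    if direction[0] == 0.0:
        return TlsFit(
            slope=math.inf,
            intercept=math.nan,
            residual_variance=resid_var,
            x_intercept=float(x.mean()),
        )
    slope = float(direction[1] / direction[0])
    intercept = float(y.mean() - slope * x.mean())
    return TlsFit(slope=slope, intercept=intercept, residual_variance=resid_var)


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit through (t=0, fraction=1)."""

    rate: float  # per minute
    half_life: float  # minutes; inf for non-decaying input
    replicate_half_lives: Optional[tuple[float, ...]] = None
    half_life_sem: Optional[float] = None


def _fit_single(times: np.ndarray, fractions: np.ndarray) -> tuple[float, float]:
    """ln(fraction) regressed on time with intercept fixed at 0."""
    if np.any(fractions <= 0):
        raise ValueError("fractions must be positive for the log-space fit")
    mask = times > 0
    if not mask.any():
        raise ValueError("need at least one time point after t = 0")
    t, lf = times[mask], np.log(fractions[mask])
    k = -float(np.sum(t * lf) / np.sum(t * t))
    if k <= 0:
        warnings.warn("non-decaying input: half-life reported as infinite")
        return k, math.inf
    return k, math.log(2) / k


def fit_half_life(
    times: Sequence[float],
    fractions: Sequence[float] | np.ndarray,
) -> DecayFit:
    """Fit fraction = exp(-k t) (y-intercept fixed at 1) and report t1/2.

    ``fractions`` may be a 1-D array (one course) or a 2-D array with one row
    per replicate; replicate input yields per-replicate half-lives plus their
    mean and standard error of the mean.
    """
    times = np.asarray(times, dtype=float)
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim == 1:
        k, t_half = _fit_single(times, fr)
        return DecayFit(rate=k, half_life=t_half)
    if fr.shape[1] != times.size:
        raise ValueError("each replicate row must match the time vector")
    fits = [_fit_single(times, row) for row in fr]
    halves = np.array([h for _, h in fits])
    rates = np.array([k for k, _ in fits])
    finite = np.isfinite(halves)
    mean_half = float(halves[finite].mean()) if finite.any() else math.inf
    sem = (
        float(halves[finite].std(ddof=1) / math.sqrt(finite.sum()))
        if finite.sum() > 1
        else None
    )
    return DecayFit(
        rate=float(rates.mean()),
        half_life=mean_half,
        replicate_half_lives=tuple(float(h) for h in halves),
        half_life_sem=sem,
    )
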