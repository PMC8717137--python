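"""Descriptive statistics and distribution characterization.

Three families are characterized the way forum count data are conventionally
summarized: gamma (maximum likelihood + one-sample Kolmogorov-Smirnov
decision H), exponential y = a*exp(b*x) and power law y = c*x**(-r), the
latter two fitted by ordinary least squares in the appropriate log domain
with the adjusted coefficient of determination reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._util import round_half_up

__all__ = [
    "DescriptiveStats",
    "GammaFit",
    "CurveFit",
    "describe",
    "fit_gamma_ks",
    "fit_histogram_curve",
    "fit_power_law",
    "power_law_exponent_mle",
    "degree_histogram",
]


@dataclass(frozen=True)
class DescriptiveStats:
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float
    sd: float
    cv: float
    skewness: float
    cv_defined: bool = True

    def as_row(self) -> dict:
        return {
            "Minimum": self.min,
            "Q1": self.q1,
            "Median": self.median,
            "Q3": self.q3,
            "Maximum": self.max,
            "Mean": self.mean,
            "SD": self.sd,
            "CV": round_half_up(self.cv, 2) if self.cv_defined else float("nan"),
        }


@dataclass(frozen=True)
class GammaFit:
    shape: float
    scale: float
    ks_statistic: float
    p_value: float
    H: int  # 1 = reject gamma at level alpha
    alpha: float


@dataclass(frozen=True)
class CurveFit:
    family: str  # "exponential" or "power_law"
    params: tuple[float, float]  # (a, b) or (c, r); r stored positive for decay
    adjusted_r2: float
    n_points: int
    dropped_points: int = 0

    @property
    def r(self) -> float:
        if self.family != "power_law":
            raise AttributeError("r is defined for power_law fits only")
        return self.params[1]


def describe(values) -> DescriptiveStats:
    """Five-number summary plus mean, sample SD, CV = SD/mean and sample skewness.

    Quartiles use linear interpolation; SD uses n-1; skewness is the
    adjusted Fisher-Pearson sample coefficient (0 for constant input).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0 or not np.isfinite(x).all():
        raise ValueError("describe requires at least one finite value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        cv, cv_defined, skew = 0.0, True, 0.0
    elif mean == 0.0:
        cv, cv_defined = float("nan"), False
        skew = float(scipy.stats.skew(x, bias=False))
    else:
        cv, cv_defined = sd / mean, True
        skew = float(scipy.stats.skew(x, bias=False))
    return DescriptiveStats(
        min=float(x.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(x.max()),
        mean=mean,
        sd=sd,
        cv=cv,
        skewness=skew,
        cv_defined=cv_defined,
    )


def fit_gamma_ks(values, alpha: float = 0.05) -> GammaFit:
    """Gamma MLE (location fixed at 0) and one-sample K-S test against the fit.

    H = 1 iff the K-S p-value falls below ``alpha``, i.e. the gamma family is
    rejected.  Because the parameters are estimated from the same sample the
    plain K-S test is conservative (the true type-I rate is below alpha).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 30:
        raise ValueError("fit_gamma_ks requires n >= 30")
    if (x <= 0).any():
        raise ValueError("gamma support requires strictly positive values")
    shape, _, scale = scipy.stats.gamma.fit(x, floc=0)
    ks = scipy.stats.kstest(x, "gamma", args=(shape, 0, scale))
    return GammaFit(
        shape=float(shape),
        scale=float(scale),
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        H=int(ks.pvalue < alpha),
        alpha=alpha,
    )


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray, p: int) -> float:
    n = y.size
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    if n - p - 1 <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_histogram_curve(x, y, family: str) -> CurveFit:
    """OLS curve fit to (x, y) points in the family's log domain.

    power_law: log10 y on log10 x (y = c*x**(-r), r positive for decay);
    exponential: ln y on x (y = a*exp(b*x)).  Points with nonpositive y are
    dropped with a count reported; fewer than 3 surviving points is an error.
    Adjusted R2 uses p = 2 fitted parameters.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = y > 0
    if family == "power_law":
        keep &= x > 0
    dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("fewer than 3 usable points after dropping nonpositive values")
    if family == "power_law":
        lx, ly = np.log10(x), np.log10(y)
        slope, intercept = np.polyfit(lx, ly, 1)
        params = (float(10.0**intercept), float(-slope))
        yhat = intercept + slope * lx
        adj = _adjusted_r2(ly, yhat, p=2)
    elif family == "exponential":
        ly = np.log(y)
        slope, intercept = np.polyfit(x, ly, 1)
        params = (float(np.exp(intercept)), float(slope))
        yhat = intercept + slope * x
        adj = _adjusted_r2(ly, yhat, p=2)
    else:
        raise ValueError(f"unknown family: {family!r}")
    return CurveFit(
        family=family,
        params=params,
        adjusted_r2=float(adj),
        n_points=int(x.size),
        dropped_points=dropped,
    )


def fit_power_law(samples, bin_base: float = 1.7) -> CurveFit:
    """Power-law fit to raw positive integer samples via log-binned OLS.

    The sample histogram is aggregated into logarithmically growing integer
    bins and the bin densities (count / bin width) are fitted by log-log OLS.
    Log-binning removes the strong tail bias that per-integer-value OLS
    suffers on heavy-tailed samples, while remaining a least-squares fit of
    P(k) = c*k**(-r); the returned r is the decay exponent of the density.
    """
    s = np.asarray(samples, dtype=float).ravel()
    s = s[s >= 1]
    if s.size < 10:
        raise ValueError("fit_power_law requires >= 10 samples of value >= 1")
    edges = [1.0]
    while edges[-1] <= s.max():
        edges.append(edges[-1] * bin_base)
    edges = np.unique(np.ceil(edges))
    if edges.size < 4:
        raise ValueError("sample range too narrow for a power-law fit")
    counts, _ = np.histogram(s, bins=np.r_[edges[:-1], edges[-1] + 0.5])
    widths = np.diff(np.r_[edges[:-1], edges[-1] + 1.0])
    centers = np.sqrt(edges[:-1] * np.maximum(edges[1:] - 1.0, edges[:-1]))
    density = counts / widths
    return fit_histogram_curve(centers, density, "power_law")


def power_law_exponent_mle(samples, xmin: int = 1) -> float:
    """Discrete power-law exponent by maximum likelihood.

    Maximizes the zeta-normalized likelihood P(k) = k**(-r) / zeta(r, xmin)
    numerically, seeded by the closed-form continuous approximation.  An
    independent cross-check for the least-squares fit, not a replacement.
    """
    import scipy.optimize
    import scipy.special

    x = np.asarray(samples, dtype=float).ravel()
    x = x[x >= xmin]
    if x.size == 0:
        raise ValueError("no samples at or above xmin")
    mean_log = float(np.mean(np.log(x)))

    def nll(r: float) -> float:
        return math.log(scipy.special.zeta(r, xmin)) + r * mean_log

    r0 = 1.0 + 1.0 / (mean_log - math.log(xmin - 0.5)) if mean_log > 0 else 2.0
    res = scipy.optimize.minimize_scalar(
        nll, bounds=(1.0 + 1e-6, max(10.0, 2 * r0)), method="bounded"
    )
    return float(res.x)


def degree_histogram(summary, normalization: str = "count") -> tuple[np.ndarray, np.ndarray]:
    """(degree values >= 1, user counts or fractions) from a DegreeSummary.

    In ``fraction`` mode the denominator counts every user, so degree-0 users
    are excluded from x but still dilute the fractions (sum <= 1).
    """
    frame = getattr(summary, "frame", None)
    degrees = (
        frame["total_degree"].to_numpy()
        if frame is not None
        else np.asarray(summary, dtype=int)
    )
    if degrees.size == 0:
        raise ValueError("empty degree summary")
    values, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if normalization == "count":
        return values.astype(int), counts.astype(int)
    if normalization == "fraction":
        return values.astype(int), counts / degrees.size
    raise ValueError(f"unknown normalization: {normalization!r}")
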