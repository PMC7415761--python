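"""Classical tests: t-tests with Cohen's d and its CI, correlations.

Effect-size confidence intervals use noncentral-t inversion: the CI for the
noncentrality parameter lambda such that the observed t sits at the 2.5th /
97.5th percentile of the noncentral-t distribution, rescaled to the d scale.
All tests are two-sided at alpha = 0.05 unless configured otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "one_sample_t_vs_chance",
    "paired_t",
    "cohens_d_ci",
    "accuracy_time_correlation",
]


@dataclass
class TestResult:
    """A t-test outcome with effect size."""

    statistic: float
    df: float
    p: float
    d: float
    d_ci: tuple[float, float]
    mean: float
    sd: float
    n: int
    extra: dict = field(default_factory=dict)

    def __str__(self) -> str:
        lo, hi = self.d_ci
        return (f"t[{self.df:g}] = {self.statistic:.2f}, p = {self.p:.3g}, "
                f"d = {self.d:.2f}, 95% CI [{lo:.2f}, {hi:.2f}]")


@dataclass
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float
    ci: tuple[float, float]
    n: int
    defined: bool = True

    def __str__(self) -> str:
        if not self.defined:
            return "r undefined (constant input)"
        lo, hi = self.ci
        return (f"r = {self.r:.3f}, t[{self.df}] = {self.t:.2f}, "
                f"p = {self.p:.3g}, 95% CI [{lo:.3f}, {hi:.3f}]")


def _ncp_ci(t_obs: float, df: float, conf: float = 0.95) -> tuple[float, float]:
    """CI for the noncentrality parameter of a noncentral-t observation."""
    alpha = (1.0 - conf) / 2.0

    def cdf(nc):
        v = sps.nct.cdf(t_obs, df, nc)
        if math.isnan(v):
            # far tails can underflow inside scipy; substitute the limit:
            # cdf -> 0 as nc -> +inf, -> 1 as nc -> -inf (monotone in nc)
            return 0.0 if nc > t_obs else 1.0
        return v

    span = abs(t_obs) + 10.0 + 10.0 / math.sqrt(df)
    lo = optimize.brentq(lambda nc: cdf(nc) - (1.0 - alpha),
                         t_obs - span, t_obs + span, xtol=1e-10)
    hi = optimize.brentq(lambda nc: cdf(nc) - alpha,
                         t_obs - span, t_obs + span, xtol=1e-10)
    return lo, hi


def cohens_d_ci(d: float, n: int, df: float | None = None,
                conf: float = 0.95) -> tuple[float, float]:
    """Noncentral-t CI for a standardized mean difference from *n* units.

    Treats ``t = d * sqrt(n)`` as noncentral-t with ``df`` (default n-1)
    and rescales the noncentrality CI back to the d scale.
    """
    if df is None:
        df = n - 1
    t_equiv = d * math.sqrt(n)
    lo, hi = _ncp_ci(t_equiv, df, conf)
    return lo / math.sqrt(n), hi / math.sqrt(n)


def one_sample_t_vs_chance(values, chance: float = 25.0) -> TestResult:
    """One-sample t of per-pair scores against a chance level (default 25%).

    Cohen's d is ``mean(x - chance) / SD(x)`` with a noncentral-t CI.
    Raises on zero variance (t undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a one-sample t test")
    n = x.size
    sd = x.std(ddof=1)
    mean = x.mean()
    if sd == 0:
        if mean == chance:
            # exact null with no spread: the limit t = 0, d = 0 is reported
            return TestResult(statistic=0.0, df=n - 1, p=1.0, d=0.0,
                              d_ci=(0.0, 0.0), mean=mean, sd=0.0, n=n,
                              extra={"chance": chance, "degenerate": True})
        raise ValueError("zero variance: one-sample t is undefined")
    t = (mean - chance) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    d = (mean - chance) / sd
    return TestResult(statistic=t, df=df, p=p, d=d,
                      d_ci=cohens_d_ci(d, n), mean=mean, sd=sd, n=n,
                      extra={"chance": chance})


def paired_t(a, b, d_method: str = "pooled") -> TestResult:
    """Two-sided paired t-test of *a* vs *b*.

    The t statistic is always on the differences.  Cohen's d is reported in
    both conventions — mean difference over SD of the differences
    (``"diff"``) and over the pooled SD of the two conditions (``"pooled"``,
    default headline) — with a noncentral-t CI on the headline d.
    """
    if d_method not in ("diff", "pooled"):
        raise ValueError(f"d_method must be 'diff' or 'pooled', got {d_method!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t requires two equal-length 1-d samples")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    n = diff.size
    sd_diff = diff.std(ddof=1)
    mean_diff = diff.mean()
    if sd_diff == 0:
        if mean_diff == 0:
            # identical samples: the limit t = 0, d = 0 is reported
            return TestResult(statistic=0.0, df=n - 1, p=1.0, d=0.0,
                              d_ci=(0.0, 0.0), mean=0.0, sd=0.0, n=n,
                              extra={"d_diff": 0.0, "d_pooled": 0.0,
                                     "degenerate": True})
        raise ValueError("zero variance of differences: paired t is undefined")
    t = mean_diff / (sd_diff / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    sd_pooled = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    d_diff = mean_diff / sd_diff
    d_pooled = mean_diff / sd_pooled if sd_pooled > 0 else math.nan
    d = d_pooled if d_method == "pooled" else d_diff
    return TestResult(statistic=t, df=df, p=p, d=d,
                      d_ci=cohens_d_ci(d, n), mean=mean_diff, sd=sd_diff, n=n,
                      extra={"d_diff": d_diff, "d_pooled": d_pooled,
                             "mean_a": a.mean(), "sd_a": a.std(ddof=1),
                             "mean_b": b.mean(), "sd_b": b.std(ddof=1)})


def accuracy_time_correlation(accuracy_flags, anchor_seconds) -> CorrelationResult:
    """Pearson r between per-showing 0/1 accuracy and seconds within trial.

    t statistic at df = n - 2; 95% CI via the Fisher z transform.  With a
    constant accuracy vector (all hits or all misses) the correlation is
    undefined and flagged rather than raised.
    """
    acc = np.asarray(accuracy_flags, dtype=float)
    sec = np.asarray(anchor_seconds, dtype=float)
    if acc.shape != sec.shape or acc.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    n = acc.size
    if n < 3:
        raise ValueError("need at least 3 showings for the correlation")
    if np.ptp(acc) == 0 or np.ptp(sec) == 0:
        return CorrelationResult(r=math.nan, t=math.nan, df=n - 2, p=math.nan,
                                 ci=(math.nan, math.nan), n=n, defined=False)
    r = float(np.corrcoef(acc, sec)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
        return CorrelationResult(r=r, t=t, df=df, p=p, ci=(r, r), n=n)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    if n > 3:
        z = math.atanh(r)
        half = sps.norm.ppf(0.975) / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (-1.0, 1.0)  # Fisher z needs n > 3; the CI is vacuous here
    return CorrelationResult(r=r, t=t, df=df, p=p, ci=ci, n=n)
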