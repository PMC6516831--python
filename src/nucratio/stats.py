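"""Group statistics: mean ± SEM, unpaired t-tests with significance stars,
and Pearson correlation with Fisher-z confidence interval plus least-squares
regression.

Two star-label schemes are provided.  ``conventional`` uses the familiar
strict thresholds 0.05/0.01/0.001/0.0001; ``gp`` uses the GraphPad-style
cutoffs 0.0332/0.0021/0.0002/0.0001 with ``<=`` semantics.  The default is
``conventional``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, ValidationError

__all__ = [
    "GroupSummary",
    "TestResult",
    "CorrResult",
    "group_summary",
    "ttest_unpaired",
    "p_to_stars",
    "fisher_ci",
    "pearson_regression",
]

STAR_SCHEMES = ("conventional", "gp")


@dataclass(frozen=True)
class GroupSummary:
    """Mean and standard error of the mean for one group of values."""

    label: str
    n: int
    mean: float
    sem: float

    def legend_string(self) -> str:
        """Figure-legend style rendering, e.g. ``"ctrl: 1.61 ± 0.13, n = 27"``."""
        return f"{self.label}: {self.mean:g} ± {self.sem:g}, n = {self.n}"


@dataclass(frozen=True)
class TestResult:
    """Outcome of an unpaired two-sided t-test."""

    t: float
    df: float
    p: float
    stars: str
    variant: str
    mode: str


@dataclass(frozen=True)
class CorrResult:
    """Pearson correlation with Fisher-z CI and the least-squares line."""

    r: float
    n: int
    ci_low: float
    ci_high: float
    r_squared: float
    p: float
    slope: float
    intercept: float


def group_summary(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean and SEM (sample sd, n-1 denominator) of ``values``.

    A single value yields ``sem = 0`` with a warning; an empty input is a
    :class:`ValidationError`.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValidationError("group_summary requires at least one value")
    n = int(arr.size)
    mean = float(arr.mean())
    if n == 1:
        warnings.warn("SEM undefined for n = 1; reporting 0", stacklevel=2)
        sem = 0.0
    else:
        sem = float(arr.std(ddof=1) / math.sqrt(n))
    return GroupSummary(label=label, n=n, mean=mean, sem=sem)


def p_to_stars(p: float, scheme: str = "conventional") -> str:
    """Map a p-value to a significance label.

    ``conventional``: ``****`` p<0.0001, ``***`` p<0.001, ``**`` p<0.01,
    ``*`` p<0.05, else ``ns`` (strict ``<`` at every threshold).
    ``gp``: ``<=`` cutoffs 0.0001/0.0002/0.0021/0.0332, else ``ns``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p-value {p!r} outside [0, 1]")
    if scheme == "conventional":
        for threshold, label in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
            if p < threshold:
                return label
        return "ns"
    if scheme == "gp":
        for threshold, label in ((0.0001, "****"), (0.0002, "***"), (0.0021, "**"), (0.0332, "*")):
            if p <= threshold:
                return label
        return "ns"
    raise ParameterError(f"unknown star scheme {scheme!r}; expected one of {STAR_SCHEMES}")


def _welch_df(var1: float, n1: int, var2: float, n2: int) -> float:
    num = (var1 / n1 + var2 / n2) ** 2
    den = (var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1)
    return num / den


def ttest_unpaired(
    a,
    b,
    variant: str = "student",
    mode: str = "raw",
    scheme: str = "conventional",
) -> TestResult:
    """Unpaired two-sided t-test between two samples.

    Parameters
    ----------
    a, b
        In ``raw`` mode: sequences of values (each with n >= 2).  In
        ``summary`` mode: ``(mean, sem, n)`` triples, so printed
        figure-legend statistics can be cross-checked without raw data.
    variant
        ``student`` (pooled variance, df = n1+n2-2) or ``welch``
        (Welch-Satterthwaite df).
    """
    if variant not in ("student", "welch"):
        raise ParameterError(f"unknown t-test variant {variant!r}")
    if mode == "raw":
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValidationError("raw-mode t-test requires n >= 2 per sample")
        res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
        t = float(res.statistic)
        p = float(res.pvalue)
        df = float(res.df)
    elif mode == "summary":
        (m1, sem1, n1), (m2, sem2, n2) = a, b
        if n1 < 2 or n2 < 2:
            raise ValidationError("summary-mode t-test requires n >= 2 per sample")
        if sem1 == 0.0 and sem2 == 0.0:
            # degenerate inputs: identical means -> t=0,p=1; distinct -> p->0
            if m1 == m2:
                t, p = 0.0, 1.0
            else:
                t = math.copysign(math.inf, m1 - m2)
                p = 0.0
            df = float(n1 + n2 - 2)
            return TestResult(t, df, p, p_to_stars(p, scheme), variant, mode)
        sd1 = sem1 * math.sqrt(n1)
        sd2 = sem2 * math.sqrt(n2)
        res = sps.ttest_ind_from_stats(
            m1, sd1, n1, m2, sd2, n2, equal_var=(variant == "student")
        )
        t = float(res.statistic)
        p = float(res.pvalue)
        if variant == "student":
            df = float(n1 + n2 - 2)
        else:
            df = _welch_df(sd1**2, n1, sd2**2, n2)
    else:
        raise ParameterError(f"unknown t-test mode {mode!r}")
    return TestResult(t=t, df=df, p=p, stars=p_to_stars(p, scheme), variant=variant, mode=mode)


def fisher_ci(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation coefficient.

    ``tanh(atanh(r) ± z* / sqrt(n - 3))`` with ``z*`` the two-sided normal
    quantile for the requested confidence level.
    """
    if not -1.0 < r < 1.0:
        raise ValidationError(f"Fisher CI requires |r| < 1, got {r}")
    if n < 4:
        raise ValidationError(f"Fisher CI requires n >= 4, got {n}")
    zcrit = float(sps.norm.ppf(0.5 + confidence / 2.0))
    z = math.atanh(r)
    half_width = zcrit / math.sqrt(n - 3)
    return math.tanh(z - half_width), math.tanh(z + half_width)


def pearson_regression(x, y, confidence: float = 0.95) -> CorrResult:
    """Sample Pearson correlation with Fisher-z CI, two-sided p (t-distribution,
    df = n-2), R² and the ordinary least-squares line of ``y`` on ``x``."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    n = int(xa.size)
    if n < 3:
        raise ValidationError(f"pearson_regression requires n >= 3, got {n}")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise ValidationError("correlation undefined for zero-variance input")
    pres = sps.pearsonr(xa, ya)
    r = float(pres.statistic)
    p = float(pres.pvalue)
    if abs(r) >= 1.0:
        ci_low = ci_high = r
    elif n == 3:
        ci_low, ci_high = -1.0, 1.0  # Fisher interval is vacuous below n = 4
    else:
        ci_low, ci_high = fisher_ci(r, n, confidence)
    lin = sps.linregress(xa, ya)
    return CorrResult(
        r=r,
        n=n,
        ci_low=ci_low,
        ci_high=ci_high,
        r_squared=r * r,
        p=p,
        slope=float(lin.slope),
        intercept=float(lin.intercept),
    )
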