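"""Closed-form (a-priori and post-hoc) power and sample-size calculations.

Three tests are covered:

* two-sample t-test — power from the noncentral t distribution with
  noncentrality d * sqrt(n1 n2 / (n1 + n2)) and N - 2 degrees of freedom;
* Wilcoxon-Mann-Whitney — the A.R.E. (asymptotic relative efficiency)
  method: the t-test machinery with both the noncentrality kernel
  n1 n2 / (n1 + n2) and the degrees of freedom shrunk by the A.R.E.
  (3/pi for a normal parent distribution; the distribution-free minimum
  0.864 is selectable).  For a two-group comparison the Kruskal-Wallis
  test is equivalent to the WMW test, so this also serves as the
  two-group Kruskal-Wallis power;
* balanced one-way fixed-effects ANOVA — noncentral F with
  lambda = f^2 * N and (g - 1, N - g) degrees of freedom.

Cohen's d uses the equal-weight pooled SD sqrt((s1^2 + s2^2)/2).

A-priori sizing for t/WMW searches the per-group size (respecting the
allocation ratio) for the smallest integer solution with power >= target;
ANOVA sizing follows the G*Power convention of searching the smallest
*total* N in steps of one (its ANOVA routine takes total sample size), and
reports per-group n as N // g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .community import ValidationError

ARE_NORMAL = 3.0 / math.pi
ARE_MIN = 0.864  # distribution-free lower bound for the WMW A.R.E.

TESTS = ("t_test", "wmw", "anova")
TAILS = ("one", "two")


@dataclass(frozen=True)
class EffectSizeD:
    """Standardised two-group mean difference (Cohen's d)."""

    mean1: float
    sd1: float
    mean2: float
    sd2: float

    def __post_init__(self):
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValidationError("standard deviations must be positive")

    @property
    def pooled_sd(self) -> float:
        return math.sqrt((self.sd1 ** 2 + self.sd2 ** 2) / 2.0)

    @property
    def d(self) -> float:
        return abs(self.mean1 - self.mean2) / self.pooled_sd


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> EffectSizeD:
    """Cohen's d from group summary statistics (equal-weight pooled SD)."""
    return EffectSizeD(mean1, sd1, mean2, sd2)


@dataclass(frozen=True)
class PowerSpec:
    """Configuration of an analytic power calculation."""

    test: str = "wmw"
    tails: str = "two"
    alpha_level: float = 0.05
    effect: float = 0.5           # d for t/wmw; f for anova
    allocation_ratio: float = 1.0  # n2 / n1
    parent_distribution: str = "normal"
    groups: int = 2               # anova only
    are: float = None             # override; default set by parent dist

    def __post_init__(self):
        if self.test not in TESTS:
            raise ValidationError(f"test must be one of {TESTS}")
        if self.tails not in TAILS:
            raise ValidationError(f"tails must be one of {TAILS}")
        if not 0 < self.alpha_level < 1:
            raise ValidationError("alpha_level must be in (0, 1)")
        if self.effect < 0:
            raise ValidationError("effect size must be >= 0")
        if self.allocation_ratio <= 0:
            raise ValidationError("allocation ratio must be positive")

    @property
    def effective_are(self) -> float:
        if self.test != "wmw":
            return 1.0
        if self.are is not None:
            return self.are
        if self.parent_distribution == "normal":
            return ARE_NORMAL
        if self.parent_distribution == "min":
            return ARE_MIN
        raise ValidationError(
            f"no A.R.E. known for parent {self.parent_distribution!r}"
        )


@dataclass(frozen=True)
class PowerSolution:
    n1: int
    n2: int
    N: int
    achieved_power: float
    noncentrality: float
    critical_value: float
    df: float
    df2: float = None  # anova denominator df
    n_per_group_continuous: float = None


def _t_family_power(d: float, n1: int, n2: int, alpha: float, tails: str,
                    are: float):
    ncp = d * math.sqrt(are * n1 * n2 / (n1 + n2))
    df = (n1 + n2 - 2) * are
    if df <= 0:
        raise ValidationError("sample sizes too small (df <= 0)")
    if tails == "one":
        crit = sps.t.ppf(1 - alpha, df)
        power = 1 - sps.nct.cdf(crit, df, ncp)
    else:
        crit = sps.t.ppf(1 - alpha / 2, df)
        power = (1 - sps.nct.cdf(crit, df, ncp)) + sps.nct.cdf(-crit, df, ncp)
    return float(power), ncp, float(crit), df


def _anova_power(f: float, N: int, g: int, alpha: float):
    df1, df2 = g - 1, N - g
    if df2 <= 0:
        raise ValidationError("total N too small for the ANOVA (df <= 0)")
    lam = f ** 2 * N
    crit = sps.f.ppf(1 - alpha, df1, df2)
    power = 1 - sps.ncf.cdf(crit, df1, df2, lam)
    return float(power), lam, float(crit), df1, df2


def power_posthoc(spec: PowerSpec, n1: int, n2: int = None) -> PowerSolution:
    """Achieved power at given group sizes.

    For ANOVA, pass the per-group size as ``n1`` (balanced design with
    ``spec.groups`` groups); ``n2`` is ignored there.
    """
    if spec.test == "anova":
        n_per = int(n1)
        if n_per < 2:
            raise ValidationError("need at least 2 samples per group")
        N = n_per * spec.groups
        power, lam, crit, df1, df2 = _anova_power(
            spec.effect, N, spec.groups, spec.alpha_level
        )
        return PowerSolution(n1=n_per, n2=n_per, N=N, achieved_power=power,
                             noncentrality=lam, critical_value=crit,
                             df=df1, df2=df2)
    n2 = int(n1 if n2 is None else n2)
    n1 = int(n1)
    if n1 < 2 or n2 < 2:
        raise ValidationError("need at least 2 samples per group")
    power, ncp, crit, df = _t_family_power(
        spec.effect, n1, n2, spec.alpha_level, spec.tails, spec.effective_are
    )
    return PowerSolution(n1=n1, n2=n2, N=n1 + n2, achieved_power=power,
                         noncentrality=ncp, critical_value=crit, df=df)


def sample_size(spec: PowerSpec, target_power: float,
                max_n: int = 1_000_000) -> PowerSolution:
    """Smallest sample size reaching ``target_power``.

    t/WMW: smallest per-group n1 (n2 = ratio * n1, rounded) with
    power >= target.  ANOVA: smallest total N (step 1) with power >=
    target; the per-group size is reported as N // g alongside the
    continuous (real-valued) balanced solution.
    """
    if spec.effect <= 0:
        raise ValidationError(
            "unattainable: a null effect can never reach the target power"
        )
    if not spec.alpha_level < target_power < 1:
        raise ValidationError("target power must lie in (alpha_level, 1)")

    if spec.test == "anova":
        g = spec.groups
        N = g + 1
        while N <= max_n:
            power, lam, crit, df1, df2 = _anova_power(
                spec.effect, N, g, spec.alpha_level
            )
            if power >= target_power:
                break
            N += 1
        else:
            raise ValidationError("target power not reached below max_n")
        n_cont = _anova_n_continuous(spec, target_power)
        n_per = N // g
        return PowerSolution(n1=n_per, n2=N - n_per * (g - 1) if g == 2 else n_per,
                             N=N, achieved_power=power, noncentrality=lam,
                             critical_value=crit, df=df1, df2=df2,
                             n_per_group_continuous=n_cont)

    n1 = 2
    while n1 <= max_n:
        n2 = max(2, round(n1 * spec.allocation_ratio))
        sol = power_posthoc(spec, n1, n2)
        if sol.achieved_power >= target_power:
            return sol
        n1 += 1
    raise ValidationError("target power not reached below max_n")


def _anova_n_continuous(spec: PowerSpec, target_power: float) -> float:
    """Real-valued balanced per-group n solving power = target."""
    from scipy.optimize import brentq

    g = spec.groups

    def gap(n_per):
        power, *_ = _anova_power(spec.effect, n_per * g, g, spec.alpha_level)
        return power - target_power

    lo, hi = 2.0, 10.0
    while gap(hi) < 0 and hi < 1e7:
        hi *= 2
    if gap(lo) > 0:
        return lo
    return float(brentq(gap, lo, hi))


def sample_size_curve(effects, spec: PowerSpec, target_power: float):
    """Required total N for a list of named effect sizes.

    ``effects`` is an iterable of (label, d) pairs; entries with d = 0 are
    reported as unattainable (N = inf).  Returns a pandas DataFrame with
    columns label, d, N, achieved_power.
    """
    import pandas as pd

    rows = []
    for label, d in effects:
        if d <= 0:
            rows.append({"label": label, "d": d, "N": math.inf,
                         "achieved_power": math.nan})
            continue
        sol = sample_size(replace(spec, effect=d), target_power)
        rows.append({"label": label, "d": d, "N": sol.N,
                     "achieved_power": sol.achieved_power})
    if not rows:
        raise ValidationError("no effects supplied")
    return pd.DataFrame(rows)
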