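"""Power analysis for rank tests and correlation tests.

Three computations back the study-design layer:

* post-hoc power of the matched-pairs Wilcoxon signed-rank test, via the
  asymptotic-relative-efficiency (A.R.E.) method: the sample size is
  deflated by the Wilcoxon-vs-t efficiency under the assumed parent
  distribution (3/pi for a normal parent) and the power is read off the
  noncentral t distribution at the reduced, generally non-integer, degrees
  of freedom;
* post-hoc power of the exact test of a bivariate-normal correlation,
  integrating Hotelling's exact density of the sample correlation
  coefficient over the rejection region set by the null t-based critical
  value;
* a-priori sample size for the two-group Wilcoxon-Mann-Whitney test, the
  smallest group sizes whose A.R.E.-adjusted two-sample noncentral-t power
  reaches the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

#: Asymptotic relative efficiency of the Wilcoxon tests vs the t test, by
#: parent distribution of the differences / observations.
ARE = {
    "normal": 3.0 / math.pi,
    "uniform": 1.0,
    "logistic": math.pi**2 / 9.0,
    "laplace": 1.5,
}


@dataclass
class PowerResult:
    """Achieved power together with the noncentral-t quantities behind it."""

    power: float
    noncentrality: float
    df: float
    critical_value: float


@dataclass
class SampleSizeResult:
    n_group_1: int
    n_group_2: int
    n_total: int
    achieved_power: float


def _validate_alpha_tails(alpha: float, tails: int) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")


def noncentral_t_power(ncp: float, df: float, alpha: float = 0.05,
                       tails: int = 2) -> float:
    """P(reject) for a t statistic with the given noncentrality.

    Two-tailed: P(|T'| > t_crit); one-tailed: upper tail only.  The
    degrees of freedom may be non-integer.
    """
    _validate_alpha_tails(alpha, tails)
    if not (np.isfinite(ncp) and np.isfinite(df)) or df <= 0:
        raise ValueError("ncp and df must be finite, df > 0")
    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        upper = stats.nct.sf(tcrit, df, ncp)
        lower = stats.nct.cdf(-tcrit, df, ncp)
        if not np.isfinite(lower):
            # scipy's nct tail can underflow to NaN at large |ncp|; use the
            # reflection P(T'(ncp) <= -t) = P(T'(-ncp) >= t)
            lower = stats.nct.sf(tcrit, df, -ncp)
        if not np.isfinite(upper):
            upper = stats.nct.cdf(-tcrit, df, -ncp)
        power = upper + lower
    else:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = stats.nct.sf(tcrit, df, ncp)
        if not np.isfinite(power):
            power = stats.nct.cdf(-tcrit, df, -ncp)
    return float(min(max(power, 0.0), 1.0))


def power_wilcoxon_matched(d_z: float, n: int, alpha: float = 0.05,
                           tails: int = 2, parent: str = "normal",
                           round_df: bool = False) -> PowerResult:
    """Post-hoc power of the matched-pairs Wilcoxon test, A.R.E. method.

    ``n`` is the total sample size as entered into the analysis (for a
    within-subject comparison of two conditions this is conventionally
    participants x conditions).  The effective size is n' = n * ARE(parent);
    power is the noncentral-t power at ncp = d_z * sqrt(n'), df = n' - 1.
    ``round_df`` rounds n' to an integer first (sensitivity check only).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if parent not in ARE:
        raise ValueError(f"unknown parent distribution {parent!r}; "
                         f"choose from {sorted(ARE)}")
    n_eff = n * ARE[parent]
    if round_df:
        n_eff = round(n_eff)
    ncp = d_z * math.sqrt(n_eff)
    df = n_eff - 1.0
    tcrit = float(stats.t.ppf(1.0 - alpha / tails, df))
    return PowerResult(
        power=noncentral_t_power(ncp, df, alpha, tails),
        noncentrality=ncp, df=df, critical_value=tcrit,
    )


def sample_correlation_pdf(r: np.ndarray | float, rho: float, n: int):
    """Hotelling's exact density of the sample correlation coefficient.

    For n observations from a bivariate normal with correlation ``rho``:

        f(r) = (n-2) G(n-1) (1-rho^2)^((n-1)/2) (1-r^2)^((n-4)/2)
               / (sqrt(2 pi) G(n-1/2) (1-rho r)^(n-3/2))
               * 2F1(1/2, 1/2; n-1/2; (1+rho r)/2)

    evaluated in log space for stability.
    """
    r = np.asarray(r, dtype=float)
    log_f = (
        math.log(n - 2) + special.gammaln(n - 1)
        + (n - 1) / 2.0 * math.log1p(-rho**2)
        + (n - 4) / 2.0 * np.log1p(-r**2)
        - 0.5 * math.log(2.0 * math.pi) - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return np.exp(log_f) * special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)


def power_correlation_exact(rho_alt: float, n: int, alpha: float = 0.05,
                            tails: int = 2, rho_null: float = 0.0) -> PowerResult:
    """Post-hoc power of the exact bivariate-normal correlation test.

    The critical sample correlation is set from the null (rho = 0)
    distribution via the t transform r = t / sqrt(n - 2 + t^2); power is the
    probability mass of Hotelling's exact density under ``rho_alt`` beyond
    it, computed by adaptive quadrature.  Only a zero null is supported.
    """
    _validate_alpha_tails(alpha, tails)
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 < rho_alt < 1.0:
        raise ValueError("|rho_alt| must be < 1")
    if rho_null != 0.0:
        raise NotImplementedError("only rho_null = 0 is supported")
    df = n - 2
    tcrit = float(stats.t.ppf(1.0 - alpha / tails, df))
    rcrit = tcrit / math.sqrt(df + tcrit**2)

    upper, err_u = integrate.quad(sample_correlation_pdf, rcrit, 1.0,
                                  args=(rho_alt, n), limit=200)
    if tails == 2:
        lower, err_l = integrate.quad(sample_correlation_pdf, -1.0, -rcrit,
                                      args=(rho_alt, n), limit=200)
    else:
        lower, err_l = 0.0, 0.0
    if err_u + err_l > 1e-7:
        raise RuntimeError("quadrature of the exact correlation density "
                           "did not converge")
    power = float(min(max(upper + lower, 0.0), 1.0))
    return PowerResult(power=power, noncentrality=float("nan"), df=float(df),
                       critical_value=rcrit)


def power_correlation_fisher_z(rho_alt: float, n: int, alpha: float = 0.05,
                               tails: int = 2) -> PowerResult:
    """Fisher-z approximation to the correlation-test power.

    A labeled large-sample fallback; :func:`power_correlation_exact` is the
    primary route and is never silently replaced by this one.
    """
    _validate_alpha_tails(alpha, tails)
    if n < 4:
        raise ValueError("need n >= 4")
    se = 1.0 / math.sqrt(n - 3)
    zcrit = float(stats.norm.ppf(1.0 - alpha / tails))
    delta = math.atanh(rho_alt) / se
    if tails == 2:
        power = stats.norm.sf(zcrit - delta) + stats.norm.cdf(-zcrit - delta)
    else:
        power = stats.norm.sf(zcrit - delta)
    return PowerResult(power=float(power), noncentrality=delta,
                       df=float("nan"), critical_value=zcrit)


def power_wilcoxon_mann_whitney(d: float, n1: int, n2: int,
                                alpha: float = 0.05, tails: int = 2,
                                parent: str = "normal",
                                round_df: bool = False) -> PowerResult:
    """Power of the two-group Wilcoxon-Mann-Whitney test, A.R.E. method.

    Each group size is deflated by ARE(parent); the power is the two-sample
    noncentral-t power at ncp = d * sqrt(n1' n2' / (n1' + n2')) with
    df = n1' + n2' - 2.
    """
    if parent not in ARE:
        raise ValueError(f"unknown parent distribution {parent!r}")
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 per group")
    n1e, n2e = n1 * ARE[parent], n2 * ARE[parent]
    if round_df:
        n1e, n2e = round(n1e), round(n2e)
    ncp = d * math.sqrt(n1e * n2e / (n1e + n2e))
    df = n1e + n2e - 2.0
    tcrit = float(stats.t.ppf(1.0 - alpha / tails, df))
    return PowerResult(power=noncentral_t_power(ncp, df, alpha, tails),
                       noncentrality=ncp, df=df, critical_value=tcrit)


def sample_size_wmw(d: float, alpha: float = 0.05, power_target: float = 0.80,
                    allocation_ratio: float = 1.0, tails: int = 2,
                    parent: str = "normal") -> SampleSizeResult:
    """Smallest total sample size reaching the target WMW power.

    ``allocation_ratio`` is n2/n1.  With ratio 1 the search walks even total
    sizes (equal groups minimise the total for a given power); otherwise n1
    is incremented with n2 = round(ratio * n1).  Monotonicity of power in n
    makes the first hit minimal.
    """
    _validate_alpha_tails(alpha, tails)
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must be in (0, 1)")
    if allocation_ratio <= 0:
        raise ValueError("allocation_ratio must be positive")

    n1 = 2
    for _ in range(100000):
        n2 = max(2, int(round(allocation_ratio * n1)))
        res = power_wilcoxon_mann_whitney(d, n1, n2, alpha, tails, parent)
        if res.power >= power_target:
            return SampleSizeResult(n_group_1=n1, n_group_2=n2,
                                    n_total=n1 + n2,
                                    achieved_power=res.power)
        n1 += 1
    raise ValueError("target power unreachable at feasible sample sizes")
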