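"""Nonparametric comparisons and effect sizes for paired index values.

Implements the inferential toolkit used on per-participant binding-window
indices and perceptual-dimension ratings: the Wilcoxon signed-rank test with
a normal-approximation z (and exact sign-flip enumeration for small n), the
rank-based effect size r = z / sqrt(n), Cohen's d_z for correlated pairs,
an n-weighted pooled Cohen's d for two independent groups, Spearman rank
correlation, and the t-based test of no correlation with conventional
strength labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class PairedSummary:
    """Summary statistics of two paired samples.

    ``rho`` is the Spearman rank correlation between the two conditions,
    which enters the denominator of Cohen's d_z.
    """

    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    rho: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.sd_1 < 0 or self.sd_2 < 0:
            raise ValueError("standard deviations must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")

    @classmethod
    def from_pairs(cls, x1: Sequence[float], x2: Sequence[float]) -> "PairedSummary":
        a = np.asarray(x1, dtype=float)
        b = np.asarray(x2, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired samples must be equal-length vectors")
        if len(a) < 3:
            raise ValueError("need >= 3 pairs to estimate the correlation")
        return cls(
            mean_1=float(a.mean()), mean_2=float(b.mean()),
            sd_1=float(a.std(ddof=1)), sd_2=float(b.std(ddof=1)),
            rho=spearman_rho(a, b), n_pairs=len(a),
        )


@dataclass
class GroupSummary:
    """Mean, SD and size of one independent group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class WilcoxonResult:
    """Wilcoxon signed-rank test outcome.

    ``W`` is the positive-rank sum; ``z`` its standardisation under the null
    (tie-corrected variance, no continuity correction); ``p_exact`` is the
    two-sided sign-flip enumeration p-value, available for n_nonzero <= 25.
    """

    W: float
    z: float
    p_two_sided: float
    n_nonzero: int
    p_exact: Optional[float] = None


def wilcoxon_signed_rank(values_1: Sequence[float],
                         values_2: Sequence[float]) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped; ties among |differences| receive average
    ranks.  The z statistic uses the normal approximation without continuity
    correction.  For 25 or fewer nonzero differences the exact two-sided
    p-value is also computed by enumerating all sign assignments of the
    observed ranks (a dynamic program over the rank-sum distribution).

    Raises
    ------
    ValueError
        If fewer than 5 nonzero differences remain, or all differences are
        zero.
    """
    d = np.asarray(values_1, dtype=float) - np.asarray(values_2, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test is degenerate")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie-corrected null variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))

    p_exact = _exact_signflip_p(ranks, w_plus) if n <= 25 else None
    return WilcoxonResult(W=w_plus, z=z, p_two_sided=float(min(p, 1.0)),
                          n_nonzero=n, p_exact=p_exact)


def _exact_signflip_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments.

    Ranks are doubled so average ranks (halves) become integers; the
    distribution of the positive-rank sum is built by polynomial convolution.
    """
    d2 = np.rint(2.0 * ranks).astype(int)
    total = int(d2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in d2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-test effect size r = |z| / sqrt(n).

    ``n_total`` follows the convention of counting every observation entering
    the comparison (participants x conditions), not the number of pairs.
    Reported as an absolute value.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    return abs(z) / math.sqrt(n_total)


def cohens_dz(summary: PairedSummary) -> float:
    """Cohen's d_z for correlated (within-subject) designs.

    |m1 - m2| / sqrt(s1^2 + s2^2 - 2 rho s1 s2); the correlation between
    conditions shrinks the denominator, crediting consistent within-subject
    differences.
    """
    denom_sq = (summary.sd_1**2 + summary.sd_2**2
                - 2.0 * summary.rho * summary.sd_1 * summary.sd_2)
    if denom_sq <= 0.0:
        raise ValueError(
            "non-positive d_z denominator (rho too close to 1 with equal SDs)")
    return abs(summary.mean_1 - summary.mean_2) / math.sqrt(denom_sq)


def cohens_d_pooled(g1: GroupSummary, g2: GroupSummary) -> float:
    """Cohen's d with n-weighted (not n-1) pooled SD for two groups.

    |m1 - m2| / sqrt((n1 s1^2 + n2 s2^2) / (n1 + n2)).
    """
    denom_sq = (g1.n * g1.sd**2 + g2.n * g2.sd**2) / (g1.n + g2.n)
    if denom_sq <= 0.0:
        raise ValueError("zero pooled variance")
    return abs(g1.mean - g2.mean) / math.sqrt(denom_sq)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks).

    Returns NaN if either vector has zero rank variance.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    if np.ptp(ra) == 0.0 or np.ptp(rb) == 0.0:
        return float("nan")
    r, _ = stats.pearsonr(ra, rb)
    return float(r)


STRENGTH_LABELS = ("none", "weak", "moderate", "strong", "perfect")


def correlation_strength(rho: float) -> str:
    """Conventional verbal label for |rho|: 0 none, (0, 0.4) weak,
    [0.4, 0.7) moderate, [0.7, 1) strong, 1 perfect."""
    a = abs(rho)
    if a == 0.0:
        return "none"
    if a < 0.4:
        return "weak"
    if a < 0.7:
        return "moderate"
    if a < 1.0:
        return "strong"
    return "perfect"


@dataclass
class CorrelationResult:
    rho: float
    t: float
    df: int
    p_two_sided: float
    strength_label: str


def no_correlation_test(rho: float, n: int) -> CorrelationResult:
    """t test of the null hypothesis of no correlation.

    t = rho sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom, two-sided.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| = 1 gives an infinite statistic")
    df = n - 2
    t = rho * math.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(rho=rho, t=t, df=df, p_two_sided=float(min(p, 1.0)),
                             strength_label=correlation_strength(rho))
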