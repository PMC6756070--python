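"""Statistical primitives shared by every pipeline stage.

All kernels are pure and deterministic.  Established implementations
(scipy, statsmodels) are used wherever they exist; the empirical-Bayes
moderated t-statistic is implemented here directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TestResult",
    "ProportionCI",
    "ModeratedTResult",
    "wilson_ci",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "rank_sum_p",
    "spearman_corr",
    "spearman_rho_p",
    "ks_two_sample",
    "fisher_exact",
    "moderated_t_two_group",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is the test statistic on its native scale (rank-sum U,
    Spearman rho, KS D, odds ratio, ...), ``p_value`` lies in [0, 1] and
    ``method`` is a short label identifying the procedure.
    """

    statistic: float
    p_value: float
    method: str
    rho: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic) and self.method != "fisher-exact":
            raise ValueError(f"non-finite statistic: {self.statistic}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class ProportionCI:
    point: float
    lower: float
    upper: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError(
                f"invalid interval: lower={self.lower} point={self.point} upper={self.upper}"
            )


def wilson_ci(successes: int, trials: int, confidence: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion (no continuity correction)."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ValueError(f"successes must be in [0, {trials}], got {successes}")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    lower, upper = proportion_confint(
        successes, trials, alpha=1.0 - confidence, method="wilson"
    )
    # endpoints are exact at the boundary counts
    lower = 0.0 if successes == 0 else float(max(lower, 0.0))
    upper = 1.0 if successes == trials else float(min(upper, 1.0))
    return ProportionCI(
        point=successes / trials, lower=lower, upper=upper, confidence=confidence
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def rank_sum_p(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float, str]:
    """Wilcoxon rank-sum (Mann-Whitney) p-value with the package's path rule.

    Exact p by full enumeration when both samples have at most 10
    observations and the pooled data are tie-free; otherwise the normal
    approximation with midrank tie correction and continuity correction.
    Returns ``(U, p, method)`` where U is the Mann-Whitney statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    exact = x.size <= 10 and y.size <= 10 and not _has_ties(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue), "exact" if exact else "normal-approx"


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Two-sample Wilcoxon rank-sum test.

    ``alternative`` follows the usual convention: ``greater`` means the
    distribution underlying ``x`` is stochastically larger than ``y``.
    """
    u, p, method = rank_sum_p(np.asarray(x), np.asarray(y), alternative)
    return TestResult(statistic=u, p_value=p, method=f"wilcoxon-{method}")


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Midrank Spearman rho and its t-approximation p-value.

    Vector-friendly inner kernel: rho from the Pearson correlation of
    midranks, p from ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 df.
    """
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValueError("constant input vector: Spearman rho undefined")
    rho = float(rx @ ry) / denom
    rho = max(-1.0, min(1.0, rho))
    if n <= 2 or abs(rho) == 1.0:
        p = 0.0 if abs(rho) == 1.0 else 1.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(special.stdtr(n - 2, -abs(t)))
    return rho, min(p, 1.0)


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = spearman_rho_p(x, y)
    return TestResult(statistic=rho, p_value=p, method="spearman-t", rho=rho)


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method="ks-asymp")


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test by the point-probability method.

    Sums hypergeometric point masses no larger than the observed table's,
    matching the convention of the R implementation.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("cells must be non-negative integers")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p), method="fisher-exact")


@dataclass(frozen=True)
class ModeratedTResult:
    """Per-gene empirical-Bayes two-group comparison."""

    gene_index: np.ndarray = field(repr=False)
    log_fc: np.ndarray = field(repr=False)
    t: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    d0: float = float("nan")
    s0_sq: float = float("nan")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    # standard starting value; converges in a handful of iterations
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0^2) to observed gene variances.

    Works on ``e = log(s2) - digamma(df/2) + log(df/2)`` whose variance in
    excess of ``trigamma(df/2)`` identifies the prior degrees of freedom.
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return math.inf, math.exp(e_mean)
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_sq


def moderated_t_two_group(
    expr: np.ndarray,
    group: np.ndarray,
    d0_override: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated t for a two-group contrast.

    ``expr`` is a genes x samples log2 matrix and ``group`` a boolean vector
    marking the group of interest.  Per-gene pooled variances are shrunk
    toward a prior ``(d0, s0^2)`` estimated by moment matching on the log
    variances; the moderated statistic is referred to a t-distribution with
    ``d0 + dg`` degrees of freedom.  With fewer than 10 genes no shrinkage
    prior can be estimated reliably and the ordinary pooled t is used.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary t; ``inf`` a normal-score test with variance ``s0^2``).
    """
    expr = np.asarray(expr, dtype=float)
    group = np.asarray(group, dtype=bool)
    if expr.ndim != 2 or expr.shape[1] != group.size:
        raise ValueError("expr must be genes x samples matching group length")
    n1 = int(group.sum())
    n2 = int((~group).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    a = expr[:, group]
    b = expr[:, ~group]
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    dg = n1 + n2 - 2
    s2 = ss / dg

    if d0_override is not None:
        d0 = float(d0_override)
        if math.isinf(d0):
            s0_sq = float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300)))))
        else:
            _, s0_sq = _fit_f_dist(s2, dg) if expr.shape[0] >= 10 else (0.0, float(np.mean(s2)))
    elif expr.shape[0] < 10:
        d0, s0_sq = 0.0, 0.0
    else:
        d0, s0_sq = _fit_f_dist(s2, dg)

    if math.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0.0:
        s2_mod = s2
        df_total = float(dg)
    else:
        s2_mod = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = float(d0 + dg)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero residual variance: no difference -> t = 0, any difference -> +/-inf
        t = np.where(se > 0, mean_diff / se, np.sign(mean_diff) * np.inf)
        t = np.where((se == 0) & (mean_diff == 0), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * special.ndtr(-np.abs(t))
    else:
        p = 2.0 * special.stdtr(df_total, -np.abs(t))
    return ModeratedTResult(
        gene_index=np.arange(expr.shape[0]),
        log_fc=mean_diff,
        t=np.asarray(t),
        p=np.minimum(np.asarray(p), 1.0),
        d0=d0,
        s0_sq=s0_sq,
    )
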