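"""Per-gene integration of copy number and expression.

The central call is the *in cis* association: a gene is gain/upregulated
when expression differs between gain and copy-number-neutral samples
(two-sided Wilcoxon rank-sum, BH-adjusted p < 0.05) and expression
correlates positively with the continuous copy-number value (Spearman
rho > 0, BH-adjusted p < 0.05).  Loss/downregulation is the mirror image;
note that rho > 0 is required in both directions, since expression is
expected to fall with copies lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from incis import cna
from incis.stats import bh_adjust, rank_sum_p, spearman_rho_p

__all__ = [
    "InCisRecord",
    "ConcordanceFlag",
    "filter_low_variance",
    "in_cis_test",
    "in_cis_scan",
    "outlier_expression_flag",
    "top_rank_concordance",
]

GAIN_UP = "gain-up"
LOSS_DOWN = "loss-down"


@dataclass
class InCisRecord:
    gene_id: str
    direction: str
    wilcoxon_p: float
    fdr: float
    rho: float
    rho_p: float
    rho_fdr: float
    n_aberrant: int
    n_neutral: int
    evaluable: bool
    in_cis: bool


@dataclass(frozen=True)
class ConcordanceFlag:
    target_id: str
    rule: str  # "outlier" or "top_rank"
    passed: bool
    k_amplified: int
    rank_window: int
    evaluable: bool = True


def filter_low_variance(expr: pd.DataFrame, min_variance: float = 0.1) -> list[str]:
    """Genes whose expression variance (n-1 denominator) reaches the floor."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate variance")
    var = expr.var(axis=1, ddof=1)
    return list(expr.index[var >= min_variance])


def _wilcoxon_p_fast(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p with the same path rule as the stats kernel,
    written inline (asymptotic branch) to keep cohort scans cheap."""
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    if nx <= 10 and ny <= 10 and np.unique(pooled).size == pooled.size:
        return rank_sum_p(x, y)[1]
    ranks = stats.rankdata(pooled)
    u = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)
    return float(2.0 * special.ndtr(-abs(z)))


def in_cis_test(
    expr: np.ndarray,
    cn_state: np.ndarray,
    cn_value: np.ndarray,
    direction: str = GAIN_UP,
    min_per_group: int = 10,
    gene_id: str = "",
) -> InCisRecord:
    """In cis association for one gene; FDR fields are filled by the caller
    across the gene family (NaN here).

    ``cn_state`` uses the :mod:`incis.cna` codes; samples with missing state
    are dropped before grouping.  Genes with fewer than ``min_per_group``
    samples in either the aberrant or the neutral group are not evaluable
    and must be excluded from the BH family.
    """
    if direction not in (GAIN_UP, LOSS_DOWN):
        raise ValueError(f"unknown direction: {direction}")
    expr = np.asarray(expr, dtype=float)
    cn_state = np.asarray(cn_state)
    cn_value = np.asarray(cn_value, dtype=float)
    target = cna.GAIN if direction == GAIN_UP else cna.LOSS
    present = (cn_state == cna.GAIN) | (cn_state == cna.NEUTRAL) | (cn_state == cna.LOSS)
    ab = cn_state == target
    neut = cn_state == cna.NEUTRAL
    n_ab, n_neut = int(ab.sum()), int(neut.sum())
    if n_ab < min_per_group or n_neut < min_per_group:
        return InCisRecord(gene_id, direction, math.nan, math.nan, math.nan, math.nan,
                           math.nan, n_ab, n_neut, False, False)
    p = _wilcoxon_p_fast(expr[ab], expr[neut])
    ev = expr[present]
    cv = cn_value[present]
    if np.unique(ev).size < 2 or np.unique(cv).size < 2:
        rho, rho_p = 0.0, 1.0
    else:
        rho, rho_p = spearman_rho_p(cv, ev)
    return InCisRecord(gene_id, direction, p, math.nan, rho, rho_p, math.nan,
                       n_ab, n_neut, True, False)


def _direction_ok(expr: np.ndarray, ab: np.ndarray, neut: np.ndarray, direction: str) -> bool:
    med_ab = float(np.median(expr[ab]))
    med_neut = float(np.median(expr[neut]))
    return med_ab > med_neut if direction == GAIN_UP else med_ab < med_neut


def in_cis_scan(
    expr: pd.DataFrame,
    cn_state: pd.DataFrame,
    cn_value: pd.DataFrame,
    direction: str = GAIN_UP,
    min_per_group: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """In cis association across a gene set, one BH family per direction.

    All three frames must share sample columns; genes are taken from
    ``expr`` (already variance-filtered) and must be present in the
    copy-number frames.  Returns one row per gene with ``in_cis`` true when
    the Wilcoxon FDR and the Spearman FDR both clear ``alpha``, rho > 0 and
    the group medians move in the tested direction.
    """
    samples = list(expr.columns)
    state = cn_state.loc[expr.index, samples].to_numpy()
    value = cn_value.loc[expr.index, samples].to_numpy()
    emat = expr.to_numpy()
    target = cna.GAIN if direction == GAIN_UP else cna.LOSS
    records: list[InCisRecord] = []
    dir_ok = np.zeros(len(expr.index), dtype=bool)
    for i, gene_id in enumerate(expr.index):
        s = state[i]
        ab = s == target
        neut = s == cna.NEUTRAL
        n_ab, n_neut = int(ab.sum()), int(neut.sum())
        if n_ab < min_per_group or n_neut < min_per_group:
            records.append(InCisRecord(str(gene_id), direction, math.nan, math.nan,
                                       math.nan, math.nan, math.nan, n_ab, n_neut,
                                       False, False))
            continue
        e = emat[i]
        p = _wilcoxon_p_fast(e[ab], e[neut])
        present = (s == cna.GAIN) | (s == cna.NEUTRAL) | (s == cna.LOSS)
        ev, cv = e[present], value[i][present]
        if np.unique(ev).size < 2 or np.unique(cv).size < 2:
            rho, rho_p = 0.0, 1.0
        else:
            rho, rho_p = spearman_rho_p(cv, ev)
        dir_ok[i] = _direction_ok(e, ab, neut, direction)
        records.append(InCisRecord(str(gene_id), direction, p, math.nan, rho, rho_p,
                                   math.nan, n_ab, n_neut, True, False))
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("gene_id")
    mask = df["evaluable"].to_numpy()
    if mask.any():
        df.loc[mask, "fdr"] = bh_adjust(df.loc[mask, "wilcoxon_p"].to_numpy())
        df.loc[mask, "rho_fdr"] = bh_adjust(df.loc[mask, "rho_p"].to_numpy())
        df.loc[mask, "in_cis"] = (
            (df.loc[mask, "fdr"] < alpha)
            & (df.loc[mask, "rho"] > 0)
            & (df.loc[mask, "rho_fdr"] < alpha)
            & dir_ok[mask]
        )
    return df


def outlier_expression_flag(
    peak: cna.AmpliconPeak, expr: pd.DataFrame
) -> ConcordanceFlag:
    """Peak-level concordance: does any peak gene show outlier expression in
    the amplified sample, i.e. strictly above Q3 + 1.5*IQR over the cohort?

    Quartiles use linear interpolation of the ECDF (numpy default, type 7).
    """
    peak_id = f"{peak.sample_id}:{peak.chrom}:{peak.start}-{peak.end}"
    genes = [g for g in peak.genes if g in expr.index]
    if not genes or peak.sample_id not in expr.columns:
        return ConcordanceFlag(peak_id, "outlier", False, 1, 0, evaluable=False)
    sub = expr.loc[genes]
    q1 = sub.quantile(0.25, axis=1)
    q3 = sub.quantile(0.75, axis=1)
    threshold = q3 + 1.5 * (q3 - q1)
    passed = bool((sub[peak.sample_id] > threshold).any())
    return ConcordanceFlag(peak_id, "outlier", passed, 1, 0, evaluable=True)


def top_rank_concordance(
    gene_id: str, amplified_samples, expr: pd.Series
) -> ConcordanceFlag:
    """Gene-level concordance of amplification with top-ranked expression.

    With k amplified samples the rank window is 5 when k < 5 and
    ``ceil(1.5 k)`` otherwise; the flag passes when at least half of the
    amplified samples sit inside the window.  Ties in expression are broken
    by stable sample order after the descending-value sort.
    """
    amplified = [s for s in amplified_samples if s in expr.index]
    k = len(amplified)
    if k == 0:
        raise ValueError("need at least one amplified sample with expression data")
    m = 5 if k < 5 else math.ceil(1.5 * k)
    order = np.argsort(-expr.to_numpy(), kind="stable")
    top = set(expr.index[order[:m]])
    hits = sum(1 for s in amplified if s in top)
    return ConcordanceFlag(gene_id, "top_rank", hits >= 0.5 * k, k, m)
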