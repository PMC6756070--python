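"""CMS-subtype enrichment of copy-number-driven expression.

Quantifies, per consensus molecular subtype (CMS), how much of the
subtype's preferential expression program overlaps the genome-wide in cis
gain/upregulated gene set, and tests the robustness of the contrast with
tumor-resampling and gene-list-resampling schemes.  Also handles the
compartment-sorted reference used to deplete microenvironment
(fibroblast/endothelial/leukocyte) genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from incis.integration import GAIN_UP, in_cis_scan
from incis.stats import TestResult, bh_adjust, fisher_exact, ks_two_sample, moderated_t_two_group

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentSummary",
    "ResampleDistribution",
    "de_upregulated",
    "overlap_fraction",
    "resample_enrichment",
    "resample_gene_lists",
    "compartment_specific_genes",
    "deplete_microenvironment",
    "compartment_enrichment",
    "arm_fraction",
    "median_cn_expr_correlation",
    "ks_compare",
]

MICROENVIRONMENT = ("fibroblast", "endothelial", "leukocyte")
COMPARTMENTS = ("epithelial",) + MICROENVIRONMENT


@dataclass(frozen=True)
class EnrichmentSummary:
    subtype: str
    n_upregulated: int
    n_overlap: int
    overlap_fraction: float  # NaN when n_upregulated == 0
    depleted_variant: bool = False


@dataclass(frozen=True)
class ResampleDistribution:
    pair: tuple[str, str]
    variant: str  # "i", "ii", "iii" or "gene-list"
    n_iter: int
    fractions_a: np.ndarray = field(repr=False)
    fractions_b: np.ndarray = field(repr=False)
    prop_a_greater: float = math.nan
    seed: int = 0


def de_upregulated(
    expr: pd.DataFrame,
    labels: pd.Series,
    subtype: str,
    fdr_alpha: float = 0.05,
    fold_change: float = 1.2,
) -> pd.DataFrame:
    """One-vs-rest moderated-t contrast for one subtype.

    Unlabelled samples (NaN / "NA") are excluded.  A gene is ``upregulated``
    when the BH-adjusted p is below ``fdr_alpha`` and the log2 fold change
    strictly exceeds ``log2(fold_change)``.
    """
    labels = labels.reindex(expr.columns)
    classified = labels.notna() & (labels != "NA")
    if subtype not in set(labels[classified]):
        raise ValueError(f"subtype {subtype!r} absent from labels")
    sub_expr = expr.loc[:, classified]
    group = (labels[classified] == subtype).to_numpy()
    res = moderated_t_two_group(sub_expr.to_numpy(), group)
    fdr = bh_adjust(res.p)
    lfc_min = math.log2(fold_change)
    return pd.DataFrame(
        {
            "contrast": f"{subtype}-vs-rest",
            "log_fc": res.log_fc,
            "p": res.p,
            "fdr": fdr,
            "upregulated": (fdr < fdr_alpha) & (res.log_fc > lfc_min),
        },
        index=expr.index,
    )


def overlap_fraction(
    upregulated, in_cis_gain, subtype: str = "", depleted: bool = False
) -> EnrichmentSummary:
    """Fraction of a subtype's upregulated genes in the in cis gain set."""
    up = set(upregulated)
    overlap = up & set(in_cis_gain)
    frac = len(overlap) / len(up) if up else math.nan
    if not up:
        log.warning("overlap_fraction: empty upregulated set for %s", subtype)
    return EnrichmentSummary(subtype, len(up), len(overlap), frac, depleted)


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    """Deterministic per-iteration stream, independent of iteration order."""
    return np.random.default_rng(np.random.SeedSequence([seed, iteration]))


def resample_enrichment(
    expr: pd.DataFrame,
    cn_state: pd.DataFrame,
    cn_value: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str],
    variant: str = "ii",
    n_iter: int = 1000,
    per_group: int = 20,
    seed: int = 0,
    min_per_group: int = 3,
    original_upregulated: dict[str, list[str]] | None = None,
    gene_subsample: int = 250,
    fdr_alpha: float = 0.05,
    fold_change: float = 1.2,
) -> ResampleDistribution:
    """Tumor-resampling comparison of in cis enrichment between two subtypes.

    Per iteration, ``per_group`` tumors are drawn without replacement from
    each subtype and in cis gain/upregulated genes are recomputed on the
    pooled 2*per_group tumors (group-size floor ``min_per_group``).  The
    subtype-specific upregulated gene lists come from, depending on
    ``variant``:

    * ``"i"`` — a fresh moderated-t contrast between the two drawn groups;
    * ``"ii"`` — the original all-sample differential expression results;
    * ``"iii"`` — ``gene_subsample`` genes drawn at random from the original
      upregulated list of each subtype.

    ``fractions_a``/``fractions_b`` hold, per iteration, the fraction of each
    subtype's upregulated genes found in cis (NaN when the list is empty);
    ``prop_a_greater`` is the proportion of iterations (with both fractions
    defined) where subtype a exceeds subtype b.
    """
    if variant not in ("i", "ii", "iii"):
        raise ValueError(f"unknown variant: {variant}")
    if variant in ("ii", "iii") and original_upregulated is None:
        raise ValueError("variants ii and iii need the original DE gene lists")
    a, b = pair
    labels = labels.reindex(expr.columns)
    samples_a = list(expr.columns[labels == a])
    samples_b = list(expr.columns[labels == b])
    if len(samples_a) < per_group or len(samples_b) < per_group:
        raise ValueError(
            f"subtypes must each have >= {per_group} samples "
            f"(got {len(samples_a)} vs {len(samples_b)})"
        )
    fractions_a = np.full(n_iter, np.nan)
    fractions_b = np.full(n_iter, np.nan)
    for it in range(n_iter):
        rng = _iteration_rng(seed, it)
        draw_a = list(rng.choice(samples_a, size=per_group, replace=False))
        draw_b = list(rng.choice(samples_b, size=per_group, replace=False))
        drawn = draw_a + draw_b
        scan = in_cis_scan(
            expr[drawn], cn_state, cn_value, GAIN_UP,
            min_per_group=min_per_group, alpha=fdr_alpha,
        )
        in_cis = set(scan.index[scan["in_cis"].astype(bool)])
        if variant == "i":
            sub = expr[drawn]
            group = np.array([s in set(draw_a) for s in drawn])
            res = moderated_t_two_group(sub.to_numpy(), group)
            fdr = bh_adjust(res.p)
            lfc_min = math.log2(fold_change)
            sig = fdr < fdr_alpha
            up_a = set(expr.index[sig & (res.log_fc > lfc_min)])
            up_b = set(expr.index[sig & (res.log_fc < -lfc_min)])
        elif variant == "ii":
            up_a = set(original_upregulated[a])
            up_b = set(original_upregulated[b])
        else:  # iii
            up_a = _draw_genes(rng, original_upregulated[a], gene_subsample)
            up_b = _draw_genes(rng, original_upregulated[b], gene_subsample)
        if up_a:
            fractions_a[it] = len(up_a & in_cis) / len(up_a)
        if up_b:
            fractions_b[it] = len(up_b & in_cis) / len(up_b)
    both = np.isfinite(fractions_a) & np.isfinite(fractions_b)
    if both.any():
        # ties split evenly so that an empty-overlap null sits at 0.5
        gt = fractions_a[both] > fractions_b[both]
        eq = fractions_a[both] == fractions_b[both]
        prop = float(np.mean(gt + 0.5 * eq))
    else:
        prop = math.nan
    return ResampleDistribution(pair, variant, n_iter, fractions_a, fractions_b, prop, seed)


def _draw_genes(rng: np.random.Generator, genes: list[str], size: int) -> set[str]:
    if len(genes) < size:
        log.warning("gene list shorter than %d (%d); using the whole list", size, len(genes))
        return set(genes)
    return set(rng.choice(np.asarray(genes, dtype=object), size=size, replace=False))


def resample_gene_lists(
    upregulated: list[str],
    in_cis_gain: list[str],
    size: int = 250,
    n_iter: int = 1000,
    seed: int = 0,
) -> ResampleDistribution:
    """Gene-list resampling: draw ``size`` genes from each list per iteration
    and record the fraction of drawn upregulated genes in the drawn in cis
    list, controlling for unequal list lengths."""
    if len(upregulated) < size or len(in_cis_gain) < size:
        raise ValueError(f"both gene lists must have >= {size} entries")
    up = np.asarray(upregulated, dtype=object)
    ic = np.asarray(in_cis_gain, dtype=object)
    fractions = np.empty(n_iter)
    for it in range(n_iter):
        rng = _iteration_rng(seed, it)
        draw_up = set(rng.choice(up, size=size, replace=False))
        draw_ic = set(rng.choice(ic, size=size, replace=False))
        fractions[it] = len(draw_up & draw_ic) / size
    return ResampleDistribution(
        ("upregulated", "in-cis"), "gene-list", n_iter, fractions,
        np.full(n_iter, np.nan), math.nan, seed,
    )


def compartment_specific_genes(
    compartment_expr: pd.DataFrame,
    compartment_labels: pd.Series,
    fdr_alpha: float = 0.05,
    fold_change: float = 1.2,
) -> dict[str, set[str]]:
    """One-vs-rest upregulated genes per sorted cell compartment."""
    labels = compartment_labels.reindex(compartment_expr.columns)
    present = set(labels.dropna())
    missing = set(COMPARTMENTS) - present
    if missing:
        raise ValueError(f"missing compartments: {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for comp in COMPARTMENTS:
        de = de_upregulated(compartment_expr, labels, comp, fdr_alpha, fold_change)
        out[comp] = set(de.index[de["upregulated"]])
    return out


def deplete_microenvironment(
    upregulated, compartment_sets: dict[str, set[str]]
) -> set[str]:
    """Remove fibroblast/endothelial/leukocyte-specific genes; epithelial
    membership is never a reason for removal."""
    stromal: set[str] = set()
    for comp in MICROENVIRONMENT:
        stromal |= set(compartment_sets.get(comp, set()))
    return set(upregulated) - stromal


def compartment_enrichment(
    in_cis_gain, compartment_sets: dict[str, set[str]], universe
) -> pd.DataFrame:
    """Fisher 2x2 enrichment of in cis genes in each compartment's program."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    in_cis = set(in_cis_gain) & universe
    rows = []
    for comp in COMPARTMENTS:
        comp_set = set(compartment_sets.get(comp, set())) & universe
        if not in_cis:
            rows.append({"compartment": comp, "odds_ratio": math.nan, "p": math.nan,
                         "n_in_cis_in_compartment": 0, "evaluable": False})
            continue
        a = len(in_cis & comp_set)
        b = len(in_cis - comp_set)
        c = len(comp_set - in_cis)
        d = len(universe - in_cis - comp_set)
        res = fisher_exact([[a, b], [c, d]])
        rows.append({"compartment": comp, "odds_ratio": res.statistic, "p": res.p_value,
                     "n_in_cis_in_compartment": a, "evaluable": True})
    return pd.DataFrame(rows).set_index("compartment")


def arm_fraction(genes, arm: str, annotation: pd.DataFrame) -> float:
    """Fraction of a gene set encoded on a chromosome arm (e.g. "20q")."""
    genes = set(genes)
    arms = annotation.set_index("gene_id")["arm"]
    annotated = [g for g in genes if g in arms.index]
    dropped = len(genes) - len(annotated)
    if dropped:
        log.warning("arm_fraction: %d unannotated genes excluded", dropped)
    if not annotated:
        return math.nan
    hits = sum(1 for g in annotated if arms[g] == arm)
    return hits / len(annotated)


def median_cn_expr_correlation(
    expr: pd.DataFrame,
    cn_value: pd.DataFrame,
    subtype_samples,
    min_samples: int = 3,
) -> float:
    """Median, across genes, of the Spearman correlation between copy-number
    value and expression over the given subtype's samples."""
    from incis.stats import spearman_rho_p

    samples = [s for s in subtype_samples if s in expr.columns]
    if len(samples) < min_samples:
        raise ValueError(f"need at least {min_samples} subtype samples")
    e = expr[samples].to_numpy()
    v = cn_value.loc[expr.index, samples].to_numpy()
    rhos = []
    for i in range(e.shape[0]):
        ok = np.isfinite(v[i])
        if ok.sum() < min_samples:
            continue
        ev, cv = e[i][ok], v[i][ok]
        if np.unique(ev).size < 2 or np.unique(cv).size < 2:
            continue
        rho, _ = spearman_rho_p(cv, ev)
        rhos.append(rho)
    return float(np.median(rhos)) if rhos else math.nan


def ks_compare(dist_a, dist_b) -> TestResult:
    """Distributional comparison of two sets of overlap fractions."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    return ks_two_sample(a[np.isfinite(a)], b[np.isfinite(b)])
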