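"""Gene-level copy-number calling, genome summaries, and amplification peaks.

Segmented profiles come in two flavours: *relative* segments (PCF-style mean
log-ratios, one row per ``sample, chrom, start, end, value``) and *allelic*
segments (ASCAT-style integer allele copies ``nA, nB``).  Coordinates are
0-based half-open throughout; only autosomes (1..22) are analysed.

Copy-number states use small integer codes so that cohort-sized matrices
stay cheap:

====================  ====
loss                  -1
neutral                0
gain                   1
missing (conflict)     9
missing (no segment)   8
====================  ====
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from incis.stats import wilson_ci

GAIN_THRESHOLD = 0.15
LOSS_THRESHOLD = -0.15

LOSS, NEUTRAL, GAIN = -1, 0, 1
MISSING_NO_COVERAGE = 8
MISSING_CONFLICT = 9

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "value"]
ALLELIC_COLUMNS = ["sample", "chrom", "start", "end", "nA", "nB"]

__all__ = [
    "GAIN_THRESHOLD",
    "LOSS_THRESHOLD",
    "LOSS",
    "NEUTRAL",
    "GAIN",
    "MISSING_NO_COVERAGE",
    "MISSING_CONFLICT",
    "GeneCNCall",
    "AmpliconPeak",
    "SampleCNSummary",
    "call_state",
    "weighted_median_low",
    "median_center_profile",
    "map_gene_copy_number",
    "gene_cn_matrix",
    "fraction_genome_aberrant",
    "call_loh",
    "estimate_ploidy",
    "sample_median_total_cn",
    "call_amplicon_peaks",
    "cohort_amplicon_peaks",
    "recurrent_amplified_genes",
    "sample_cn_summary",
]


@dataclass(frozen=True)
class GeneCNCall:
    gene_id: str
    sample_id: str
    value: float  # NaN when state is missing
    state: int
    no_coverage: bool = False


@dataclass(frozen=True)
class AmpliconPeak:
    """Maximal run of adjacent segments each >= `min_additional` copies above
    the sample's genome-wide median total copy number."""

    sample_id: str
    chrom: int
    start: int
    end: int
    max_additional_copies: int
    gene_count: int
    genes: tuple[str, ...]
    focal: bool
    high_level: bool


@dataclass(frozen=True)
class SampleCNSummary:
    sample_id: str
    fraction_aberrant: float
    fraction_loh: float
    ploidy: float
    ploidy_group: str  # "low" (<2.2) or "high" (>=2.2)
    median_total_cn: float


def call_state(value: float, gain_threshold: float = GAIN_THRESHOLD,
               loss_threshold: float = LOSS_THRESHOLD) -> int:
    """Three-level call from a relative log value; thresholds inclusive."""
    if not np.isfinite(value):
        raise ValueError(f"non-finite copy-number value: {value}")
    if value >= gain_threshold:
        return GAIN
    if value <= loss_threshold:
        return LOSS
    return NEUTRAL


def _call_states(values: np.ndarray) -> np.ndarray:
    out = np.zeros(values.shape, dtype=np.int8)
    out[values >= GAIN_THRESHOLD] = GAIN
    out[values <= LOSS_THRESHOLD] = LOSS
    return out


def weighted_median_low(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative weight reaches half of the total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    return float(values[order][idx])


def _base_multiset_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of the multiset in which each value is repeated ``weight`` times.

    Equals ``np.median`` applied to the expanded per-base vector (mean of the
    two middle bases when the total weight is even) without materialising it.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=np.int64)
    order = np.argsort(values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order])
    total = int(cum[-1])
    lo_idx, hi_idx = (total - 1) // 2, total // 2
    lo = v[int(np.searchsorted(cum, lo_idx, side="right"))]
    hi = v[int(np.searchsorted(cum, hi_idx, side="right"))]
    return float((lo + hi) / 2.0)


def median_center_profile(segments: pd.DataFrame) -> pd.DataFrame:
    """Subtract the base-pair-weighted median value from one sample's profile."""
    if len(segments) == 0:
        raise ValueError("empty profile")
    lengths = (segments["end"] - segments["start"]).to_numpy()
    center = weighted_median_low(segments["value"].to_numpy(), lengths)
    out = segments.copy()
    out["value"] = out["value"] - center
    return out


def _overlap_rule(values: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Resolve a gene spanning several segments to (value, state).

    (i) all aberrant in one direction: most extreme value; (ii) all neutral:
    base-weighted median; (iii) neutral plus one aberrant direction: most
    extreme (aberrant) value; (iv) gain and loss both present: missing.
    """
    states = _call_states(values)
    has_gain = bool((states == GAIN).any())
    has_loss = bool((states == LOSS).any())
    if has_gain and has_loss:
        return float("nan"), MISSING_CONFLICT
    if has_gain:
        return float(values.max()), GAIN
    if has_loss:
        return float(values.min()), LOSS
    return _base_multiset_median(values, weights), NEUTRAL


def map_gene_copy_number(
    gene: pd.Series | dict, segments: pd.DataFrame, sample_id: str = ""
) -> GeneCNCall:
    """Copy-number value and state for one gene from one sample's segments.

    ``segments`` must be that sample's relative segments, non-overlapping per
    chromosome.  Genes overlapping no segment are returned as missing with
    the ``no_coverage`` flag set.
    """
    chrom, gstart, gend = int(gene["chrom"]), int(gene["start"]), int(gene["end"])
    gene_id = str(gene.get("gene_id", ""))
    seg = segments[segments["chrom"] == chrom].sort_values("start")
    starts = seg["start"].to_numpy()
    ends = seg["end"].to_numpy()
    mask = (starts < gend) & (ends > gstart)
    if not mask.any():
        return GeneCNCall(gene_id, sample_id, float("nan"), MISSING_NO_COVERAGE, True)
    values = seg["value"].to_numpy()[mask]
    weights = np.minimum(ends[mask], gend) - np.maximum(starts[mask], gstart)
    value, state = _overlap_rule(values, weights)
    return GeneCNCall(gene_id, sample_id, value, state, False)


def _profile_gene_calls(
    seg: pd.DataFrame, genes: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-sample gene mapping; returns (values, state codes)."""
    n = len(genes)
    values = np.full(n, np.nan)
    states = np.full(n, MISSING_NO_COVERAGE, dtype=np.int8)
    for chrom, gsub in genes.groupby("chrom", sort=False):
        s = seg[seg["chrom"] == chrom]
        if len(s) == 0:
            continue
        s = s.sort_values("start")
        seg_start = s["start"].to_numpy()
        seg_end = s["end"].to_numpy()
        seg_val = s["value"].to_numpy()
        gs = gsub["start"].to_numpy()
        ge = gsub["end"].to_numpy()
        idx_global = gsub.index.to_numpy()  # genes has a RangeIndex
        # first/last overlapping segment per gene (segments non-overlapping, sorted)
        first = np.searchsorted(seg_end, gs, side="right")
        last = np.searchsorted(seg_start, ge, side="left") - 1
        single = (first == last)
        sel = single & (first < len(s))
        values[idx_global[sel]] = seg_val[first[sel]]
        states[idx_global[sel]] = _call_states(seg_val[first[sel]])
        for k in np.nonzero(~single)[0]:
            f, l = int(first[k]), int(last[k])
            g_idx = idx_global[k]
            if l < f:  # gene falls in a gap
                continue
            vals = seg_val[f : l + 1]
            w = np.minimum(seg_end[f : l + 1], ge[k]) - np.maximum(seg_start[f : l + 1], gs[k])
            keep = w > 0
            if not keep.any():
                continue
            v, st = _overlap_rule(vals[keep], w[keep])
            values[g_idx] = v
            states[g_idx] = st
    return values, states


def gene_cn_matrix(
    segments: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample copy-number value and state matrices for a cohort.

    ``segments`` holds relative segments for all samples (already median
    centered).  Returns ``(values, states)`` DataFrames indexed by gene_id.
    """
    genes = genes.reset_index(drop=True)
    sample_ids = list(dict.fromkeys(segments["sample"]))
    values = np.full((len(genes), len(sample_ids)), np.nan)
    states = np.full((len(genes), len(sample_ids)), MISSING_NO_COVERAGE, dtype=np.int8)
    for j, sid in enumerate(sample_ids):
        seg = segments[segments["sample"] == sid]
        values[:, j], states[:, j] = _profile_gene_calls(seg, genes)
    idx = pd.Index(genes["gene_id"], name="gene_id")
    return (
        pd.DataFrame(values, index=idx, columns=sample_ids),
        pd.DataFrame(states, index=idx, columns=sample_ids),
    )


def fraction_genome_aberrant(segments: pd.DataFrame) -> float:
    """Aberrant bases over total bases with an estimate, for one profile."""
    if len(segments) == 0:
        raise ValueError("empty profile")
    lengths = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    states = _call_states(segments["value"].to_numpy())
    return float(lengths[states != NEUTRAL].sum() / lengths.sum())


def call_loh(allelic: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """LOH segments (exactly one allele at zero copies) and base fraction.

    Homozygous deletions (nA = nB = 0) are not LOH.
    """
    if len(allelic) == 0:
        raise ValueError("empty profile")
    nA = allelic["nA"].to_numpy()
    nB = allelic["nB"].to_numpy()
    loh = ((nA == 0) | (nB == 0)) & ~((nA == 0) & (nB == 0))
    lengths = (allelic["end"] - allelic["start"]).to_numpy(dtype=float)
    frac = float(lengths[loh].sum() / lengths.sum())
    return allelic[loh].copy(), frac


def estimate_ploidy(allelic: pd.DataFrame, cutoff: float = 2.2) -> tuple[float, str]:
    """Base-pair-weighted mean total copy number and the 2.2n dichotomy."""
    if len(allelic) == 0:
        raise ValueError("empty profile")
    lengths = (allelic["end"] - allelic["start"]).to_numpy(dtype=float)
    nab = (allelic["nA"] + allelic["nB"]).to_numpy(dtype=float)
    ploidy = float((nab * lengths).sum() / lengths.sum())
    return ploidy, ("high" if ploidy >= cutoff else "low")


def sample_median_total_cn(allelic: pd.DataFrame) -> float:
    """Base-pair-weighted median of total copy number (nA + nB)."""
    if len(allelic) == 0:
        raise ValueError("empty profile")
    lengths = (allelic["end"] - allelic["start"]).to_numpy(dtype=float)
    nab = (allelic["nA"] + allelic["nB"]).to_numpy(dtype=float)
    return weighted_median_low(nab, lengths)


def call_amplicon_peaks(
    allelic: pd.DataFrame,
    genes: pd.DataFrame,
    min_additional: int = 5,
    high_level_threshold: int = 15,
    focal_max_genes: int = 50,
    sample_id: str | None = None,
) -> list[AmpliconPeak]:
    """Amplification peaks for one sample's allelic segments.

    A segment is amplified when its total copy number exceeds the sample's
    genome-wide median by at least ``min_additional`` copies.  Peaks are
    maximal runs of literally adjacent amplified segments on one chromosome.
    """
    if sample_id is None:
        sample_id = str(allelic["sample"].iloc[0]) if len(allelic) else ""
    if len(allelic) == 0:
        return []
    median_cn = sample_median_total_cn(allelic)
    peaks: list[AmpliconPeak] = []
    for chrom, seg in allelic.groupby("chrom", sort=True):
        seg = seg.sort_values("start")
        add = (seg["nA"] + seg["nB"]).to_numpy(dtype=float) - median_cn
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        amped = add >= min_additional
        i = 0
        while i < len(seg):
            if not amped[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(seg) and amped[j + 1] and starts[j + 1] == ends[j]:
                j += 1
            run_start, run_end = int(starts[i]), int(ends[j])
            max_add = int(round(add[i : j + 1].max()))
            g = genes[
                (genes["chrom"] == chrom)
                & (genes["start"] < run_end)
                & (genes["end"] > run_start)
            ]
            gene_ids = tuple(g["gene_id"])
            peaks.append(
                AmpliconPeak(
                    sample_id=sample_id,
                    chrom=int(chrom),
                    start=run_start,
                    end=run_end,
                    max_additional_copies=max_add,
                    gene_count=len(gene_ids),
                    genes=gene_ids,
                    focal=len(gene_ids) <= focal_max_genes,
                    high_level=max_add >= high_level_threshold,
                )
            )
            i = j + 1
    return peaks


def cohort_amplicon_peaks(
    allelic: pd.DataFrame, genes: pd.DataFrame, min_additional: int = 5, **kwargs
) -> dict[str, list[AmpliconPeak]]:
    return {
        str(sid): call_amplicon_peaks(
            seg, genes, min_additional=min_additional, sample_id=str(sid), **kwargs
        )
        for sid, seg in allelic.groupby("sample", sort=False)
    }


def recurrent_amplified_genes(
    peaks_by_sample: dict[str, list[AmpliconPeak]],
    n_cohort: int,
    min_additional: int = 5,
    min_tumors: int = 2,
    focal_only: bool = False,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-gene amplification recurrence with Wilson confidence intervals.

    A sample counts for a gene when one of its peaks with amplitude
    ``>= min_additional`` (and, optionally, focal) covers the gene.  Genes
    amplified in fewer than ``min_tumors`` samples are dropped.
    """
    carriers: dict[str, set[str]] = {}
    for sid, peaks in peaks_by_sample.items():
        for peak in peaks:
            if peak.max_additional_copies < min_additional:
                continue
            if focal_only and not peak.focal:
                continue
            for g in peak.genes:
                carriers.setdefault(g, set()).add(sid)
    rows = []
    for gene_id, samples in sorted(carriers.items()):
        if len(samples) < min_tumors:
            continue
        ci = wilson_ci(len(samples), n_cohort, confidence)
        rows.append(
            {
                "gene_id": gene_id,
                "n_samples": len(samples),
                "frequency": ci.point,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
                "samples": ",".join(sorted(samples)),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_samples", "frequency", "ci_lower", "ci_upper", "samples"]
    )


def sample_cn_summary(
    relative: pd.DataFrame, allelic: pd.DataFrame, sample_id: str, ploidy_cutoff: float = 2.2
) -> SampleCNSummary:
    """Genome-fraction and ploidy summary for one sample (centered relative
    segments plus allelic segments)."""
    frac_ab = fraction_genome_aberrant(relative)
    _, frac_loh = call_loh(allelic)
    ploidy, group = estimate_ploidy(allelic, ploidy_cutoff)
    return SampleCNSummary(
        sample_id=sample_id,
        fraction_aberrant=frac_ab,
        fraction_loh=frac_loh,
        ploidy=ploidy,
        ploidy_group=group,
        median_total_cn=sample_median_total_cn(allelic),
    )
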