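"""End-to-end orchestration: CNA calling -> integration -> CMS enrichment
-> survival, with every artifact written as TSV/JSON plus a config stamp."""

from __future__ import annotations

import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

import incis
from incis import cms as cms_mod
from incis import cna, integration, io, survival
from incis.config import PipelineConfig

log = logging.getLogger(__name__)

__all__ = ["load_inputs", "run_pipeline"]


def load_inputs(input_dir: str | Path) -> dict:
    d = Path(input_dir)
    inputs = {
        "relative_segments": io.read_segments(d / "relative_segments.tsv"),
        "allelic_segments": io.read_allelic(d / "allelic_segments.tsv"),
        "genes": io.read_bed(d / "genes.bed"),
        "expression": io.read_expression(d / "expression.tsv"),
        "metadata": io.read_metadata(d / "metadata.tsv"),
    }
    comp = d / "compartment_expression.tsv"
    if comp.exists():
        inputs["compartment_expression"] = io.read_expression(comp)
        labels = pd.read_csv(d / "compartment_labels.tsv", sep="\t", index_col=0)
        inputs["compartment_labels"] = labels["compartment"]
    return inputs


def _center_profiles(segments: pd.DataFrame) -> pd.DataFrame:
    parts = [
        cna.median_center_profile(seg) for _, seg in segments.groupby("sample", sort=False)
    ]
    return pd.concat(parts, ignore_index=True)


def _peaks_frame(peaks_by_sample: dict) -> pd.DataFrame:
    rows = [
        {
            "sample": p.sample_id,
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "max_additional_copies": p.max_additional_copies,
            "gene_count": p.gene_count,
            "focal": p.focal,
            "high_level": p.high_level,
            "genes": ",".join(p.genes),
        }
        for peaks in peaks_by_sample.values()
        for p in peaks
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "max_additional_copies",
                 "gene_count", "focal", "high_level", "genes"],
    )


def run_pipeline(
    config: PipelineConfig, inputs: dict, out_dir: str | Path
) -> dict:
    """Run every stage on MSS samples and write the results bundle.

    ``inputs`` is the dict produced by :func:`load_inputs` or by
    :func:`incis.simulate.simulate_cohort` (same keys).  Returns the
    in-memory results; files land under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start, seed=%d", config.seed)
    meta = inputs["metadata"]
    genes = inputs["genes"]
    mss = list(meta.index[meta["msi"] == "MSS"])
    log.info("samples: %d total, %d MSS", len(meta), len(mss))

    results: dict = {"config": config.to_dict(), "version": incis.__version__}

    # ------------------------------------------------------------- CNA core
    rel = inputs["relative_segments"]
    allelic = inputs["allelic_segments"]
    rel = rel[rel["sample"].isin(mss)]
    allelic = allelic[allelic["sample"].isin(mss)]
    centered = _center_profiles(rel)
    gene_values, gene_states = cna.gene_cn_matrix(centered, genes)

    summaries = []
    for sid in gene_values.columns:
        summaries.append(
            cna.sample_cn_summary(
                centered[centered["sample"] == sid],
                allelic[allelic["sample"] == sid],
                sid,
                config.ploidy_cutoff,
            )
        )
    summary_df = pd.DataFrame([asdict(s) for s in summaries]).set_index("sample_id")

    peaks = cna.cohort_amplicon_peaks(
        allelic, genes,
        min_additional=config.amp_min_additional,
        high_level_threshold=config.high_level_threshold,
        focal_max_genes=config.focal_max_genes,
    )
    n_cna_cohort = len(set(allelic["sample"]))
    recurrent5 = cna.recurrent_amplified_genes(
        peaks, n_cna_cohort, config.amp_min_additional, config.min_tumors_recurrent
    )
    recurrent15 = cna.recurrent_amplified_genes(
        peaks, n_cna_cohort, config.high_level_threshold,
        config.min_tumors_recurrent, focal_only=True,
    )
    frac_amp = float(np.mean([len(v) > 0 for v in peaks.values()])) if peaks else math.nan
    results.update(
        {
            "sample_summaries": summary_df,
            "peaks": peaks,
            "recurrent_amplified_5": recurrent5,
            "recurrent_amplified_15": recurrent15,
            "fraction_samples_with_amplification": frac_amp,
        }
    )
    summary_df.to_csv(out / "sample_summaries.tsv", sep="\t", float_format="%.6g")
    _peaks_frame(peaks).to_csv(out / "amplicon_peaks.tsv", sep="\t", index=False)
    recurrent5.to_csv(out / "recurrent_amplified_ge5.tsv", sep="\t", index=False,
                      float_format="%.6g")
    recurrent15.to_csv(out / "recurrent_amplified_ge15_focal.tsv", sep="\t", index=False,
                       float_format="%.6g")

    # ------------------------------------------------------ integration
    expr = inputs["expression"]
    integration_samples = [s for s in gene_values.columns if s in expr.columns]
    log.info("integration cohort: %d samples", len(integration_samples))
    expr_i = expr[integration_samples]
    retained = integration.filter_low_variance(expr_i, config.min_variance)
    retained = [g for g in retained if g in gene_values.index]
    log.info("variance filter: %d of %d genes retained", len(retained), len(expr_i))
    expr_f = expr_i.loc[retained]

    scan_gain = integration.in_cis_scan(
        expr_f, gene_states, gene_values, integration.GAIN_UP,
        config.min_per_group_genome, config.fdr_alpha,
    )
    scan_loss = integration.in_cis_scan(
        expr_f, gene_states, gene_values, integration.LOSS_DOWN,
        config.min_per_group_genome, config.fdr_alpha,
    )
    scan_gain.to_csv(out / "in_cis_gain.tsv", sep="\t", float_format="%.6g")
    scan_loss.to_csv(out / "in_cis_loss.tsv", sep="\t", float_format="%.6g")
    in_cis_gain = set(scan_gain.index[scan_gain["in_cis"].astype(bool)])
    results["in_cis_gain"] = scan_gain
    results["in_cis_loss"] = scan_loss

    conc_rows = []
    for sid, sample_peaks in peaks.items():
        if sid not in expr.columns:
            continue
        for p in sample_peaks:
            if not (p.focal and p.high_level):
                continue
            flag = integration.outlier_expression_flag(p, expr_i)
            conc_rows.append({"target": flag.target_id, "rule": flag.rule,
                              "passed": flag.passed, "evaluable": flag.evaluable})
    amp_samples_by_gene: dict[str, set[str]] = {}
    for sid, sample_peaks in peaks.items():
        for p in sample_peaks:
            for g in p.genes:
                amp_samples_by_gene.setdefault(g, set()).add(sid)
    for g in recurrent5["gene_id"]:
        if g not in expr_f.index:
            continue
        amped = [s for s in amp_samples_by_gene.get(g, set()) if s in integration_samples]
        if not amped:
            continue
        flag = integration.top_rank_concordance(g, amped, expr_f.loc[g])
        conc_rows.append({"target": flag.target_id, "rule": flag.rule,
                          "passed": flag.passed, "evaluable": flag.evaluable})
    concordance = pd.DataFrame(conc_rows, columns=["target", "rule", "passed", "evaluable"])
    concordance.to_csv(out / "concordance.tsv", sep="\t", index=False)
    results["concordance"] = concordance

    # --------------------------------------------------- CMS enrichment
    labels = meta.loc[integration_samples, "cms"]
    labels = labels.where(labels.isin(("CMS1", "CMS2", "CMS3", "CMS4")))
    counts = labels.value_counts()
    subtypes = [s for s in ("CMS1", "CMS2", "CMS3", "CMS4") if counts.get(s, 0) >= 2]

    de_tables: dict[str, pd.DataFrame] = {}
    upregulated: dict[str, list[str]] = {}
    for s in subtypes:
        de = cms_mod.de_upregulated(expr_f, labels, s, config.fdr_alpha, config.fold_change)
        de_tables[s] = de
        upregulated[s] = list(de.index[de["upregulated"]])

    overlap_rows = []
    for s in subtypes:
        summ = cms_mod.overlap_fraction(upregulated[s], in_cis_gain, s)
        overlap_rows.append(asdict(summ))

    comp_sets: dict[str, set[str]] = {}
    if "compartment_expression" in inputs:
        comp_sets = cms_mod.compartment_specific_genes(
            inputs["compartment_expression"], inputs["compartment_labels"],
            config.fdr_alpha, config.fold_change,
        )
        for s in subtypes:
            depleted = cms_mod.deplete_microenvironment(upregulated[s], comp_sets)
            overlap_rows.append(
                asdict(cms_mod.overlap_fraction(depleted, in_cis_gain, s, depleted=True))
            )
        enrich = cms_mod.compartment_enrichment(in_cis_gain, comp_sets, retained)
        enrich.to_csv(out / "compartment_enrichment.tsv", sep="\t", float_format="%.6g")
        results["compartment_enrichment"] = enrich
    overlap_df = pd.DataFrame(overlap_rows)
    overlap_df.to_csv(out / "cms_overlap.tsv", sep="\t", index=False, float_format="%.6g")
    results["cms_overlap"] = overlap_df

    resample_out = {}
    for pair in config.resample_pairs:
        a, b = pair
        if counts.get(a, 0) < config.resample_per_group or \
           counts.get(b, 0) < config.resample_per_group:
            log.warning("skipping resampling %s vs %s: too few samples", a, b)
            continue
        dist = cms_mod.resample_enrichment(
            expr_f, gene_states, gene_values, labels, (a, b),
            variant=config.resample_variant,
            n_iter=config.resample_iterations,
            per_group=config.resample_per_group,
            seed=config.seed,
            min_per_group=config.min_per_group_resample,
            original_upregulated=upregulated,
            gene_subsample=config.gene_subsample,
            fdr_alpha=config.fdr_alpha,
            fold_change=config.fold_change,
        )
        resample_out[f"{a}_vs_{b}"] = {
            "variant": dist.variant,
            "n_iter": dist.n_iter,
            "seed": dist.seed,
            "prop_a_greater": dist.prop_a_greater,
            "mean_fraction_a": float(np.nanmean(dist.fractions_a)),
            "mean_fraction_b": float(np.nanmean(dist.fractions_b)),
        }
        results[f"resample_{a}_vs_{b}"] = dist
    io.write_json(resample_out, out / "resampling.json")

    median_rho = {}
    for s in subtypes:
        subtype_samples = list(labels.index[labels == s])
        if len(subtype_samples) >= 3:
            median_rho[s] = cms_mod.median_cn_expr_correlation(
                expr_f, gene_values, subtype_samples
            )
    results["median_cn_expr_correlation"] = median_rho

    # --------------------------------------------------------- survival
    surv_cols = {"time", "event", "stage"}
    survival_results: dict = {}
    if surv_cols.issubset(meta.columns) and len(recurrent15):
        recs = meta.loc[mss]
        recs = recs[recs["stage"].isin(["I", "II", "III"])].copy()
        recs = survival.censor_at_horizon(recs, config.survival_horizon)
        region_genes = set(recurrent15["gene_id"])
        carriers: set[str] = set()
        for sid, sample_peaks in peaks.items():
            for p in sample_peaks:
                if p.focal and p.high_level and region_genes & set(p.genes):
                    carriers.add(sid)
        recs["group"] = [
            "amplified" if s in carriers else "non-amplified" for s in recs.index
        ]
        if 0 < len(carriers & set(recs.index)) < len(recs):
            km = survival.km_estimate(recs, "group", at=config.survival_horizon)
            lr = survival.logrank(recs, "group")
            recs["amplified"] = (recs["group"] == "amplified").astype(int)
            cov = survival.prepare_covariates(recs)
            fit_df = pd.concat([recs[["time", "event", "amplified"]], cov], axis=1)
            uni = survival.cox_fit(fit_df, ["amplified"], "univariable")
            multi_covs = ["amplified"] + [c for c in cov.columns if fit_df[c].nunique() > 1]
            multi = survival.cox_fit(fit_df, multi_covs, "multivariable")
            survival_results = {
                "n": len(recs),
                "n_amplified": int(recs["amplified"].sum()),
                "logrank_p": lr.p_value,
                "km": {
                    g: {k: v for k, v in d.items() if k != "fitter"}
                    for g, d in km.items()
                },
                "cox_univariable": [asdict(h) for h in uni],
                "cox_multivariable": [asdict(h) for h in multi],
            }
        else:
            log.warning("survival: degenerate amplification groups; skipped")
    results["survival"] = survival_results
    io.write_json(survival_results, out / "survival.json")

    stamp = {
        "config": config.to_dict(),
        "version": incis.__version__,
        "seed": config.seed,
        "n_samples_mss": len(mss),
        "n_genes_retained": len(retained),
        "fraction_samples_with_amplification": frac_amp,
    }
    io.write_json(stamp, out / "run_stamp.json")
    return results
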