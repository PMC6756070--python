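"""Synthetic MSS colorectal-cancer cohort generator with recorded truth.

The generator emulates the statistical structure the analysis pipeline
assumes, on a scaled genome (22 autosomes of 10 Mb, ~2,000 genes):

* per-sample segmented copy-number profiles (allele-specific integer copies
  and matching relative log2 segments) with CMS-dependent aberration
  burden, a diploid/tetraploid ploidy mixture and injected focal
  amplifications;
* bulk log2 expression produced by mixing a malignant-cell signal (baseline
  + subtype programs + linear dosage response) with a stromal signal,
  weighted by tumor purity, plus Gaussian noise;
* a compartment-sorted expression reference (epithelial / fibroblast /
  endothelial / leukocyte) whose marker sets are the ones used in the bulk
  mixture;
* exponential survival times with an excess hazard for carriers of
  high-level focal amplifications.

Each subtype's expression program is split between *dosage-driven* genes,
which sit in subtype-specific gain-prone regions and are upregulated only
through copy number, and *direct* genes with a copy-number-independent
shift; the configured ``dosage_driven_fraction_by_cms`` is therefore the
ground-truth value that the overlap-fraction analysis should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SimTruth", "simulate_cohort",
           "simulate_compartment_reference", "simulate_survival_cohort"]

CMS_LABELS = ("CMS1", "CMS2", "CMS3", "CMS4")


def _default_cms_proportions() -> dict[str, float]:
    return {"CMS1": 0.07, "CMS2": 0.42, "CMS3": 0.15, "CMS4": 0.23}


def _default_purity_means() -> dict[str, float]:
    return {"CMS1": 0.60, "CMS2": 0.70, "CMS3": 0.65, "CMS4": 0.45, "NA": 0.60}


def _default_gain_loss() -> dict[str, tuple[float, float]]:
    return {
        "CMS1": (0.18, 0.15),
        "CMS2": (0.25, 0.20),
        "CMS3": (0.12, 0.10),
        "CMS4": (0.22, 0.18),
        "NA": (0.20, 0.15),
    }


def _default_dosage_fractions() -> dict[str, float]:
    return {"CMS1": 0.06, "CMS2": 0.50, "CMS3": 0.05, "CMS4": 0.05}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Effects are log2 expression units; rates are per sample or per
    chromosome; lengths are bases.
    """

    n_samples: int = 150
    n_genes: int = 2000
    n_chromosomes: int = 22
    chromosome_length: int = 10_000_000
    gene_length: int = 40_000
    arm_boundary_fraction: float = 0.4  # p/q split point

    cms_proportions: dict[str, float] = field(default_factory=_default_cms_proportions)
    msi_fraction: float = 0.15
    purity_mean_by_cms: dict[str, float] = field(default_factory=_default_purity_means)
    purity_sd: float = 0.08

    tetraploid_prob: float = 0.30
    breakpoint_rate: float = 3.0  # expected breakpoints per chromosome
    gain_loss_probs_by_cms: dict[str, tuple[float, float]] = field(
        default_factory=_default_gain_loss
    )
    msi_aberration_prob: float = 0.03
    prone_gain_prob: float = 0.75  # gain prob in a subtype's own prone region
    prone_other_gain_prob: float = 0.05

    amp_rate: float = 0.8  # expected injected focal amplifications per sample
    amp_copies_range: tuple[int, int] = (5, 100)
    amp_width_genes: tuple[int, int] = (3, 30)

    dosage_effect: float = 0.45  # log2 per additional copy in malignant cells
    dosage_saturation: float = 6.0  # cap on the dosage term (log2)
    dosage_driven_fraction_by_cms: dict[str, float] = field(
        default_factory=_default_dosage_fractions
    )
    program_size: int = 250
    program_effect: float = 0.8
    background_dosage_fraction: float = 0.25
    stromal_program_size: int = 200
    stromal_effect: float = 1.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.3
    logr_jitter_sd: float = 0.02

    survival_baseline_rate: float = 0.08  # events per year
    amp_hazard_ratio: float = 3.0
    admin_censor_years: float = 8.0

    compartment_replicates: int = 4
    compartment_effect: float = 2.0
    compartment_noise_sd: float = 0.25

    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cms_proportions.values()) > 1.0 + 1e-9:
            raise ValueError("cms_proportions must sum to <= 1 (remainder unclassified)")
        per_chrom = self.n_genes // self.n_chromosomes
        if self.amp_width_genes[1] > per_chrom:
            raise ValueError("amplification width exceeds genes per chromosome")
        if self.n_genes // self.n_chromosomes * self.gene_length > self.chromosome_length:
            raise ValueError("genes do not fit on the chromosome")
        if self.stromal_program_size > self.n_genes:
            raise ValueError("stromal program larger than the genome")
        for k, v in self.dosage_driven_fraction_by_cms.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"dosage_driven_fraction_by_cms[{k}] outside [0, 1]")


@dataclass
class SimTruth:
    """Generator ground truth for recovery testing."""

    gene_truth: pd.DataFrame  # per-gene driver / program / marker flags
    sample_truth: pd.DataFrame  # purity, base ploidy, high-level carrier flag
    amplifications: pd.DataFrame  # injected events
    true_hazard_ratio: float
    seed: int


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Genome/program, cohort, and compartment streams from one root seed.

    The genome stream is shared between :func:`simulate_cohort` and
    :func:`simulate_compartment_reference` so that marker sets agree.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _build_genome(config: SimConfig) -> pd.DataFrame:
    """Non-overlapping, evenly spaced gene models over the autosomes."""
    rows = []
    base = config.n_genes // config.n_chromosomes
    extra = config.n_genes % config.n_chromosomes
    gid = 0
    for chrom in range(1, config.n_chromosomes + 1):
        k = base + (1 if chrom <= extra else 0)
        pitch = config.chromosome_length / k
        boundary = config.arm_boundary_fraction * config.chromosome_length
        for i in range(k):
            start = int(round(i * pitch + (pitch - config.gene_length) / 2))
            end = start + config.gene_length
            mid = (start + end) / 2
            gid += 1
            rows.append(
                {
                    "gene_id": f"G{gid:04d}",
                    "symbol": f"G{gid:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "arm": f"{chrom}{'p' if mid < boundary else 'q'}",
                }
            )
    return pd.DataFrame(rows)


def _prone_regions(config: SimConfig) -> dict[str, list[tuple[int, int, int]]]:
    """Subtype-specific gain-prone genomic regions (chrom, start, end)."""
    L = config.chromosome_length
    arm = int(config.arm_boundary_fraction * L)
    return {
        "CMS1": [(17, 0, arm)],
        "CMS2": [(19, 0, L), (20, 0, L)],
        "CMS3": [(18, 0, arm)],
        "CMS4": [(16, 0, arm)],
    }


def _assign_programs(config: SimConfig, genes: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene truth flags: subtype programs (driven vs direct), stromal
    markers, background dosage-responsive genes, compartment markers."""
    prone = _prone_regions(config)
    n = len(genes)
    truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "program_subtype": "",
            "dosage_driven": False,
            "dosage_responsive": False,
            "stromal": False,
            "compartment": "",
        }
    ).set_index("gene_id")

    in_prone = np.zeros(n, dtype=bool)
    prone_of: dict[str, np.ndarray] = {}
    for cms, regions in prone.items():
        mask = np.zeros(n, dtype=bool)
        for chrom, start, end in regions:
            mask |= (
                (genes["chrom"].to_numpy() == chrom)
                & (genes["start"].to_numpy() >= start)
                & (genes["end"].to_numpy() <= end)
            )
        prone_of[cms] = mask
        in_prone |= mask

    gene_ids = genes["gene_id"].to_numpy()
    assigned = np.zeros(n, dtype=bool)

    # driven program genes live in the subtype's own prone region
    for cms in CMS_LABELS:
        theta = config.dosage_driven_fraction_by_cms.get(cms, 0.0)
        k = int(round(theta * config.program_size))
        pool = np.nonzero(prone_of[cms] & ~assigned)[0]
        if k > pool.size:
            raise ValueError(f"prone region of {cms} too small for {k} driven genes")
        pick = rng.choice(pool, size=k, replace=False) if k else np.array([], dtype=int)
        truth.iloc[pick, truth.columns.get_loc("program_subtype")] = cms
        truth.iloc[pick, truth.columns.get_loc("dosage_driven")] = True
        assigned[pick] = True

    quiet = ~in_prone

    # stromal markers, split over the three microenvironment compartments
    pool = np.nonzero(quiet & ~assigned)[0]
    stromal_pick = rng.choice(pool, size=config.stromal_program_size, replace=False) \
        if config.stromal_program_size else np.array([], dtype=int)
    truth.iloc[stromal_pick, truth.columns.get_loc("stromal")] = True
    assigned[stromal_pick] = True
    thirds = np.array_split(stromal_pick, 3)
    for comp, idx in zip(("fibroblast", "endothelial", "leukocyte"), thirds):
        truth.iloc[idx, truth.columns.get_loc("compartment")] = comp

    # direct (copy-number-independent) program genes on quiet regions
    for cms in CMS_LABELS:
        theta = config.dosage_driven_fraction_by_cms.get(cms, 0.0)
        k = config.program_size - int(round(theta * config.program_size))
        pool = np.nonzero(quiet & ~assigned)[0]
        if k > pool.size:
            raise ValueError("quiet gene pool exhausted; reduce program sizes")
        pick = rng.choice(pool, size=k, replace=False) if k else np.array([], dtype=int)
        truth.iloc[pick, truth.columns.get_loc("program_subtype")] = cms
        assigned[pick] = True

    # background dosage-responsive genes, outside prone regions so that they
    # stay neutral with respect to subtype programs
    pool = np.nonzero(quiet & ~assigned)[0]
    k = int(round(config.background_dosage_fraction * pool.size))
    pick = rng.choice(pool, size=k, replace=False) if k else np.array([], dtype=int)
    truth.iloc[pick, truth.columns.get_loc("dosage_responsive")] = True

    truth["dosage_responsive"] |= truth["dosage_driven"]
    # the malignant-cell (epithelial) program is every subtype program gene
    is_program = truth["program_subtype"] != ""
    truth.loc[is_program & (truth["compartment"] == ""), "compartment"] = "epithelial"
    _ = gene_ids  # order is by genes frame construction
    return truth


def _draw_labels(config: SimConfig, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Per-sample MSI status and CMS label (or "NA")."""
    msi = ["MSI" if rng.random() < config.msi_fraction else "MSS"
           for _ in range(config.n_samples)]
    labels = list(config.cms_proportions.keys())
    probs = np.array([config.cms_proportions[l] for l in labels])
    rest = 1.0 - probs.sum()
    choices = labels + ["NA"]
    p = np.append(probs, max(rest, 0.0))
    p = p / p.sum()
    cms = [str(rng.choice(choices, p=p)) for _ in range(config.n_samples)]
    return msi, cms


def _segment_chromosome(
    config: SimConfig, rng: np.random.Generator, chrom: int,
    forced: list[int],
) -> list[tuple[int, int]]:
    n_bp = rng.poisson(config.breakpoint_rate)
    cuts = sorted(
        set(int(x) for x in rng.integers(1, config.chromosome_length, size=n_bp))
        | set(forced)
    )
    bounds = [0] + [c for c in cuts if 0 < c < config.chromosome_length] + [
        config.chromosome_length
    ]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _in_region(start: int, end: int, regions: list[tuple[int, int, int]], chrom: int) -> bool:
    mid = (start + end) // 2
    return any(c == chrom and s <= mid < e for c, s, e in regions)


def simulate_cohort(config: SimConfig) -> dict:
    """Generate a full synthetic cohort plus ground truth.

    Returns a dict with keys ``genes``, ``relative_segments``,
    ``allelic_segments``, ``expression``, ``metadata``,
    ``compartment_expression``, ``compartment_labels`` and ``truth``.
    """
    rng_genome, rng, _ = _streams(config.seed)
    genes = _build_genome(config)
    truth_genes = _assign_programs(config, genes, rng_genome)
    prone = _prone_regions(config)

    msi_status, cms_labels = _draw_labels(config, rng)
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]

    baseline = rng_genome.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    stromal_profile = baseline + config.stromal_effect * truth_genes["stromal"].to_numpy()

    rel_rows, all_rows, amp_rows = [], [], []
    sample_rows = []
    expr = np.empty((len(genes), config.n_samples))

    gene_chrom = genes["chrom"].to_numpy()
    gene_mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    responsive = truth_genes["dosage_responsive"].to_numpy()
    program_of = truth_genes["program_subtype"].to_numpy()
    driven = truth_genes["dosage_driven"].to_numpy()

    for j, sid in enumerate(sample_ids):
        cms = cms_labels[j]
        is_msi = msi_status[j] == "MSI"
        base_ploidy = 4 if rng.random() < config.tetraploid_prob else 2
        base_minor = base_ploidy // 2
        purity = float(
            np.clip(
                rng.normal(config.purity_mean_by_cms.get(cms, 0.6), config.purity_sd),
                0.2, 0.95,
            )
        )
        gain_p, loss_p = config.gain_loss_probs_by_cms.get(cms, (0.2, 0.15))
        if is_msi:
            gain_p = loss_p = config.msi_aberration_prob

        own_prone = prone.get(cms, []) if not is_msi else []
        other_prone = [r for c, rs in prone.items() if c != cms for r in rs] \
            if not is_msi else []

        # --- copy-number profile -----------------------------------------
        segs: list[dict] = []
        for chrom in range(1, config.n_chromosomes + 1):
            forced = []
            for c, s, e in [(c2, s2, e2) for cc, rs in prone.items() for (c2, s2, e2) in rs]:
                if c == chrom:
                    forced += [s, e]
            for start, end in _segment_chromosome(config, rng, chrom, forced):
                in_own = _in_region(start, end, [(c, s, e) for c, s, e in own_prone], chrom)
                in_other = _in_region(start, end, other_prone, chrom)
                if in_own:
                    g_p, l_p, gain_delta = config.prone_gain_prob, 0.02, 2
                elif in_other:
                    g_p, l_p, gain_delta = config.prone_other_gain_prob, 0.05, 2
                else:
                    g_p, l_p = gain_p, loss_p
                    gain_delta = 2 if rng.random() < 0.3 else 1
                u = rng.random()
                if u < g_p:
                    delta = gain_delta
                elif u < g_p + l_p:
                    delta = -1
                else:
                    delta = 0
                total = max(base_ploidy + delta, 0)
                minor = max(base_minor + delta, 0) if delta < 0 else min(base_minor, total)
                segs.append(
                    {"chrom": chrom, "start": start, "end": end,
                     "nA": total - minor, "nB": minor}
                )

        # sample-wise genome median before amplification injection
        lengths = np.array([s["end"] - s["start"] for s in segs], dtype=float)
        totals = np.array([s["nA"] + s["nB"] for s in segs], dtype=float)
        order = np.argsort(totals, kind="stable")
        cum = np.cumsum(lengths[order])
        median_cn = int(totals[order][int(np.searchsorted(cum, cum[-1] / 2.0))])

        # --- focal amplification injection -------------------------------
        n_amp = 0 if is_msi else int(rng.poisson(config.amp_rate))
        used_chroms: set[int] = set()
        carrier_high = False
        for _ in range(n_amp):
            free = [c for c in range(1, config.n_chromosomes + 1) if c not in used_chroms]
            if not free:
                break
            chrom = int(rng.choice(free))
            used_chroms.add(chrom)
            gsel = np.nonzero(gene_chrom == chrom)[0]
            width = int(rng.integers(config.amp_width_genes[0], config.amp_width_genes[1] + 1))
            g0 = int(rng.integers(0, gsel.size - width + 1))
            block = gsel[g0 : g0 + width]
            first, last = block[0], block[-1]
            start = 0 if g0 == 0 else int(
                (genes["end"].iloc[gsel[g0 - 1]] + genes["start"].iloc[first]) // 2
            )
            end = config.chromosome_length if g0 + width == gsel.size else int(
                (genes["end"].iloc[last] + genes["start"].iloc[gsel[g0 + width]]) // 2
            )
            add = int(rng.integers(config.amp_copies_range[0], config.amp_copies_range[1] + 1))
            total = median_cn + add
            # split existing segments at the amplicon boundaries
            new_segs = []
            for s in segs:
                if s["chrom"] != chrom or s["end"] <= start or s["start"] >= end:
                    new_segs.append(s)
                    continue
                if s["start"] < start:
                    new_segs.append({**s, "end": start})
                if s["end"] > end:
                    new_segs.append({**s, "start": end})
            new_segs.append(
                {"chrom": chrom, "start": start, "end": end,
                 "nA": total - base_minor, "nB": base_minor}
            )
            segs = new_segs
            carrier_high = carrier_high or add >= 15
            amp_rows.append(
                {"sample": sid, "chrom": chrom, "start": start, "end": end,
                 "additional_copies": add, "n_genes": width,
                 "genes": ",".join(genes["gene_id"].iloc[block])}
            )

        segs.sort(key=lambda s: (s["chrom"], s["start"]))
        for s in segs:
            total = s["nA"] + s["nB"]
            value = math.log2(max(total, 0.25) / base_ploidy) + rng.normal(
                0.0, config.logr_jitter_sd
            )
            all_rows.append({"sample": sid, **s})
            rel_rows.append(
                {"sample": sid, "chrom": s["chrom"], "start": s["start"],
                 "end": s["end"], "value": value}
            )

        # --- expression ---------------------------------------------------
        gene_total = np.empty(len(genes))
        for chrom in range(1, config.n_chromosomes + 1):
            csegs = [s for s in segs if s["chrom"] == chrom]
            starts = np.array([s["start"] for s in csegs])
            tot = np.array([s["nA"] + s["nB"] for s in csegs], dtype=float)
            sel = gene_chrom == chrom
            idx = np.searchsorted(starts, gene_mid[sel], side="right") - 1
            gene_total[sel] = tot[idx]
        dosage = np.where(
            responsive,
            np.minimum(config.dosage_effect * (gene_total - base_ploidy),
                       config.dosage_saturation),
            0.0,
        )
        malignant = baseline + dosage + config.program_effect * (
            (program_of == cms) & ~driven
        )
        bulk = np.log2(
            purity * np.exp2(malignant) + (1.0 - purity) * np.exp2(stromal_profile)
        )
        expr[:, j] = bulk + rng.normal(0.0, config.noise_sd, size=len(genes))

        sample_rows.append(
            {"sample": sid, "purity": purity, "base_ploidy": base_ploidy,
             "carrier_high_level": carrier_high}
        )

    # --- survival and clinical metadata ----------------------------------
    sample_truth = pd.DataFrame(sample_rows).set_index("sample")
    meta_rows = []
    for j, sid in enumerate(sample_ids):
        carrier = bool(sample_truth.loc[sid, "carrier_high_level"])
        rate = config.survival_baseline_rate * (
            config.amp_hazard_ratio if carrier else 1.0
        )
        t = float(rng.exponential(1.0 / rate))
        event = True
        if t > config.admin_censor_years:
            t, event = config.admin_censor_years, False
        t = max(t, 1e-3)
        meta_rows.append(
            {
                "sample": sid,
                "msi": msi_status[j],
                "cms": cms_labels[j],
                "stage": str(rng.choice(["I", "II", "III"], p=[0.2, 0.35, 0.45])),
                "age": float(np.clip(rng.normal(68.0, 10.0), 30.0, 95.0)),
                "gender": str(rng.choice(["male", "female"])),
                "localization": str(rng.choice(["distal", "proximal"])),
                "time": t,
                "event": event,
            }
        )
    metadata = pd.DataFrame(meta_rows).set_index("sample")

    comp_expr, comp_labels = simulate_compartment_reference(config)

    truth = SimTruth(
        gene_truth=truth_genes,
        sample_truth=sample_truth,
        amplifications=pd.DataFrame(
            amp_rows,
            columns=["sample", "chrom", "start", "end", "additional_copies",
                     "n_genes", "genes"],
        ),
        true_hazard_ratio=config.amp_hazard_ratio,
        seed=config.seed,
    )
    expression = pd.DataFrame(
        expr, index=pd.Index(genes["gene_id"], name="gene_id"), columns=sample_ids
    )
    return {
        "genes": genes,
        "relative_segments": pd.DataFrame(rel_rows),
        "allelic_segments": pd.DataFrame(all_rows),
        "expression": expression,
        "metadata": metadata,
        "compartment_expression": comp_expr,
        "compartment_labels": comp_labels,
        "truth": truth,
    }


def simulate_compartment_reference(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """FACS-sorted-style reference matrix for the four cell compartments.

    Marker sets and baselines come from the same genome stream as
    :func:`simulate_cohort`, so the stromal markers spiking the bulk mixture
    are exactly the ones separable here.
    """
    rng_genome, _, rng = _streams(config.seed)
    genes = _build_genome(config)
    truth_genes = _assign_programs(config, genes, rng_genome)
    baseline = rng_genome.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    comp_of_gene = truth_genes["compartment"].to_numpy()
    cols, labels, mats = [], [], []
    for comp in ("epithelial", "fibroblast", "endothelial", "leukocyte"):
        marker = (comp_of_gene == comp).astype(float)
        profile = baseline + config.compartment_effect * marker
        for r in range(config.compartment_replicates):
            cols.append(f"{comp[:4].upper()}_{r + 1}")
            labels.append(comp)
            mats.append(profile + rng.normal(0.0, config.compartment_noise_sd, len(genes)))
    mat = np.column_stack(mats)
    expr = pd.DataFrame(mat, index=pd.Index(genes["gene_id"], name="gene_id"), columns=cols)
    return expr, pd.Series(labels, index=cols, name="compartment")


def simulate_survival_cohort(
    n: int,
    hazard_ratio: float,
    exposure_fraction: float = 0.3,
    baseline_rate: float = 0.1,
    admin_censor_years: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Small exponential survival cohort with a binary exposure, for
    calibration studies of the survival stack."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    exposed = rng.random(n) < exposure_fraction
    rate = baseline_rate * np.where(exposed, hazard_ratio, 1.0)
    t = rng.exponential(1.0 / rate)
    event = t <= admin_censor_years
    t = np.minimum(t, admin_censor_years)
    return pd.DataFrame(
        {"time": np.maximum(t, 1e-3), "event": event, "exposed": exposed.astype(int)}
    )
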