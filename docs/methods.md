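# Methods

## Scope and model

`incis` analyses the interplay between somatic DNA copy-number aberrations
(CNAs) and bulk gene expression in microsatellite-stable (MSS) colorectal
cancer. It consumes two segmentations of the same tumor genome — *relative*
segments (mean log2 ratios from a piecewise-constant fit) and
*allele-specific* segments (integer allele copies nA/nB, ASCAT-style) — a
log2 expression matrix, gene annotation, and clinical metadata. Only
autosomes are analysed. Coordinates are 0-based half-open internally;
segment TSVs are 1-based inclusive on disk, BED is native.

The pipeline has four stages:

1. **CNA core.** Each sample's relative profile is centered on its
   base-pair-weighted median. Gain/loss calls use inclusive thresholds at
   +/-0.15 on the relative log value; the threshold is applied inclusively
   (>= 0.15, <= -0.15) because the boundary convention is otherwise
   arbitrary and the inclusive form is stated once and used everywhere.
   Genes spanning segment breakpoints are resolved by four rules: all
   aberrant in one direction -> most extreme value; all neutral ->
   base-pair-weighted median of the overlapping values (the median of the
   base multiset, interpolating between the two middle bases, so that the
   gene-level call equals a per-base evaluation of the same rules); neutral
   plus one aberrant direction -> the aberrant extreme; gain and loss both
   present -> missing for that sample. Genes with no overlapping segment
   are missing with a distinct no-coverage flag.

   Amplifications are defined on allelic data as total copies at least 5
   above the sample's genome-wide base-pair-weighted median total copy
   number (the "low" weighted median: smallest value whose cumulative
   weight reaches half). Peaks are maximal runs of literally adjacent
   amplified segments — no gap tolerance, because segmentations are
   genome-covering. A peak is *high-level* at >= 15 additional copies and
   *focal* at <= 50 overlapping genes (>= 1 bp overlap counts). Ploidy is
   the base-weighted mean of total copies, dichotomized at 2.2n. LOH is a
   segment with exactly one allele at zero copies; homozygous deletions are
   not LOH. Recurrence tables report per-gene carrier counts with Wilson
   95% intervals (no continuity correction).

2. **Integration.** Genes with expression variance < 0.1 (n-1 denominator)
   are excluded. The *in cis* call per direction (gain/up, loss/down)
   combines a two-sided Wilcoxon rank-sum test of expression between
   aberrant and neutral samples with a Spearman correlation between
   expression and the continuous copy-number value over all samples with a
   state; the continuous value (not the 3-level state) is used because the
   question is a monotone dosage relationship. A gene is in cis when both
   BH-adjusted p-values are below 0.05, rho > 0 (in both directions —
   expression falls with copies lost), and the group medians move the
   tested way. One BH family per direction, over evaluable genes only
   (>= 10 samples per group genome-wide; >= 3 inside resampling runs).
   Amplification-expression concordance uses two rules: *outlier* (any
   peak gene strictly above Q3 + 1.5 IQR in the amplified sample; type-7
   quantiles) and *top-rank* (at least half of the k amplified samples
   within the top max(5, ceil(1.5 k)) expression ranks; ceiling rounding
   keeps the window inclusive, ties broken by stable sample order after
   the descending sort — documented because top-m membership can depend
   on it).

3. **CMS enrichment.** Subtype programs are one-vs-rest empirical-Bayes
   moderated-t contrasts among CMS-classified MSS tumors; upregulated
   means BH-adjusted p < 0.05 and log2 fold change strictly above
   log2(1.2) (the fold-change threshold is applied on the log2 scale).
   The moderated t shrinks per-gene pooled variances toward a scaled-F
   prior whose parameters (d0, s0^2) come from moment matching on log
   variances (trigamma inversion by Newton iteration); with fewer than 10
   genes no prior is estimated and the ordinary t is used. The
   implementation is cross-checked against Bioconductor limma in the test
   suite. The headline statistic is the *overlap fraction*: the share of a
   subtype's upregulated genes that are in the genome-wide in cis
   gain/upregulated set. Robustness is assessed by (i) tumor resampling —
   20 tumors per subtype per iteration, in cis recomputed on the pooled 40
   with a group floor of 3 and per-iteration BH families, upregulated
   lists from a fresh 20-vs-20 contrast (variant i), the original
   all-sample lists (variant ii), or a 250-gene random subsample of the
   original lists (variant iii) — and (ii) gene-list resampling of 250
   genes from each list. `prop_a_greater` splits tied fractions as 0.5 so
   that a cohort with no dosage signal (both fractions almost always
   exactly 0) sits at 0.5 rather than 0. Per-iteration randomness comes
   from `SeedSequence([root_seed, iteration])`, so iterations are
   reproducible and order-independent. CMS1 is excluded from resampling
   defaults (too few MSS samples); pairs whose subtypes fall below 20
   samples are skipped with a logged warning rather than failing the run.
   Microenvironment depletion removes genes upregulated in the fibroblast,
   endothelial or leukocyte compartments of a sorted-cell reference
   (one-vs-rest moderated t, same thresholds); epithelial membership never
   removes a gene.

4. **Survival.** Five-year overall survival among stage I-III MSS
   patients; events after the horizon are administratively censored at 5
   years. Exposure is carriage of a focal high-level amplification
   covering any recurrently amplified (>= 2 tumors) gene region.
   Kaplan-Meier, log-rank, and Cox proportional hazards (Efron ties, Wald
   intervals) via lifelines; multivariable models add age dichotomized at
   the analysis cohort's median, gender, localization (distal/proximal),
   and stage as indicator contrasts with stage I as reference (separate
   II/III levels, not a linear score).

## Synthetic cohort generator

The generator emulates the statistical structure this analysis assumes; it
is first-class, tested code, and its defaults are the study conditions for
every recovery test.

* **Genome.** 22 autosomes of 10 Mb with ~2,000 evenly spaced 40 kb genes —
  a scaled genome that preserves segment/gene topology while keeping runs
  in seconds. Arms split at 40% of chromosome length.
* **Samples.** n = 150 by default; CMS proportions ~ (CMS1 0.07, CMS2 0.42,
  CMS3 0.15, CMS4 0.23, unclassified 0.13); 15% MSI tumors with nearly
  flat profiles; base ploidy 2n or 4n (P(4n) = 0.3); purity normal around
  CMS-specific means (0.70 for CMS2 vs 0.45 for CMS4, reflecting stromal
  infiltration of mesenchymal tumors), sd 0.08, clipped to [0.2, 0.95].
* **Copy number.** Poisson(3) breakpoints per chromosome; segment states
  drawn with CMS-specific gain/loss probabilities (CMS3 lowest).
  Subtype-specific *gain-prone regions* (CMS2: chromosomes 19-20; CMS1,
  CMS3, CMS4: one p-arm each) are gained with probability 0.75 (+2 copies)
  in their own subtype and 0.05 elsewhere. Relative segments are
  log2(total/ploidy) plus N(0, 0.02) jitter. Focal amplifications are
  injected at Poisson(0.8) per sample (at most one per chromosome, so runs
  never merge), amplitude uniform on 5-100 additional copies above the
  sample's realized median, width 3-30 genes with boundaries at mid-gaps
  so the covered gene set is exact; every injection is recorded in the
  truth table.
* **Expression.** Malignant signal = N(7,1) baseline + 0.8 log2 program
  shift for *direct* subtype-program genes + 0.45 log2 per additional copy
  (capped at +6) for *dosage-responsive* genes. Each subtype's 250-gene
  program is split by the configured dosage-driven fraction theta (CMS2
  default 0.5): driven genes sit in the subtype's gain-prone region and
  are upregulated only through copy number; direct genes sit on quiet
  arms. A further 25% of unassigned quiet genes are dosage-responsive
  background, so the genome-wide in cis set is not confined to program
  genes. A 200-gene stromal program (+1.5 log2 in the stromal profile) is
  split over the three microenvironment compartments. Bulk expression
  mixes malignant and stromal profiles on the linear scale weighted by
  purity, then adds N(0, 0.3) noise. The compartment reference uses the
  same marker sets (+2.0 log2, 4 replicates each) and shares the genome
  stream with the cohort, so bulk-mixture markers and sorted-cell markers
  agree by construction.
* **Survival.** Exponential times at 0.08 events/year, hazard multiplied
  by 3 for carriers of an injected high-level focal amplification,
  administratively censored at 8 years.
* **Randomness.** One root seed spawns three PCG64 streams
  (genome/programs, cohort, compartment reference); the genome stream is
  shared with the standalone compartment generator.

What the generator does *not* emulate: probe-level array noise, subclonal
copy-number states, whole-genome-doubling evolution, segmentation error
correlated along the genome, and any direct biological coupling between
stage and outcome. Passing recovery tests therefore show that the
*analysis* recovers planted structure under realistic mixing, noise and
class imbalance — not that real tumors obey the linear dosage model.

## Numerical choices

* Wilcoxon: exact enumeration when both groups have <= 10 observations and
  the pooled data are tie-free; otherwise normal approximation with
  midrank tie correction and continuity correction. Spearman p via the
  t approximation t = rho sqrt((n-2)/(1-rho^2)). Fisher two-sided p by the
  point-probability method (the R convention). Wilson intervals without
  continuity correction, exact 0/1 endpoints at boundary counts.
* Weighted medians: the "low" weighted median (smallest value whose
  cumulative weight reaches half the total) for profile centering and the
  sample median copy number; the interpolating base-multiset median for
  the all-neutral gene rule (required for per-base/segment-level
  equivalence).
* Degenerate inputs: zero residual variance in the moderated t yields
  t = 0 for zero differences and +/-inf otherwise; constant vectors make
  Spearman undefined (error in the kernel, rho = 0 / p = 1 inside cohort
  scans where the gene simply fails the call); empty upregulated sets give
  NaN overlap fractions and are flagged, never silently zero.

## Problem sizes and runtime

Default test-suite cohorts are 150 x 2,000 (shared fixture), 60-90 samples
x 300-400 genes for resampling unit tests, and 200-iteration resampling in
the acceptance checks. `scripts/acceptance.py` uses a 250-sample cohort —
large enough that every CMS subtype clears the 20-per-group resampling
floor for any seed — with 200 iterations per subtype pair, and a separate
200-gene null cohort for false-discovery calibration; a run takes a few
minutes on one core. Survival calibration uses 100 replicate cohorts of
400-500 patients.

## Known limitations

* The in cis test conditions on hard gain/loss state calls; borderline
  segments near +/-0.15 can flip group membership under the log-ratio
  jitter.
* Overlap fractions include a chance-overlap floor: a noisy upregulated
  list (e.g. a subtype with very few samples, like CMS1) intersects the
  genome-wide in cis set at roughly its relative size even without any
  dosage coupling.
* The Cox exposure groups inherit misclassification from peak recurrence:
  carriers of non-recurrent high-level amplifications sit in the reference
  group, attenuating hazard ratios relative to the generator's truth; the
  calibration tests therefore use a clean binary-exposure simulator.
* Gene-list resampling assumes both lists exceed the subsample size;
  inside the tumor-resampling variant iii the whole list is used (with a
  warning) when shorter.
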