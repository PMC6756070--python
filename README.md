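# incis

Integrative DNA copy-number / gene-expression analysis of
microsatellite-stable (MSS) colorectal cancer.

Most colorectal cancers are chromosomally instable, but which copy-number
aberrations (CNAs) actually move gene expression — and whether the
expression-based consensus molecular subtypes (CMS) differ in how strongly
they are copy-number driven — is the question this package addresses. It is
written for cancer-genomics analysts who already have segmented
copy-number profiles (relative log2-ratio segments plus ASCAT-style
allele-specific segments) and a matched bulk expression matrix.

## What it computes

* **Gene-level CN calls** from segmented profiles, with breakpoint-conflict
  resolution and inclusive ±0.15 gain/loss thresholds on the
  median-centered log2 ratio.
* **Amplification peaks**: maximal runs of adjacent segments with total
  copies ≥ 5 above the sample's genome-wide median (high-level at ≥ 15;
  focal at ≤ 50 genes), with per-gene recurrence frequencies and Wilson
  95% intervals.
* **In cis association** per gene and direction: a gene is gain/upregulated
  when expression differs between gain and copy-number-neutral tumors
  (two-sided Wilcoxon rank-sum, BH-adjusted p < 0.05) *and* expression
  correlates positively with the copy-number value (Spearman ρ > 0,
  BH-adjusted p < 0.05).
* **CMS enrichment**: for each subtype, the fraction of its preferentially
  expressed genes (one-vs-rest moderated t, FDR < 0.05, fold change > 1.2)
  that fall in the in cis gain/upregulated set, with tumor-resampling and
  gene-list-resampling controls, microenvironment-gene depletion against a
  sorted-cell compartment reference, and compartment enrichment tests.
* **Survival stratification**: five-year overall survival of carriers of
  recurrent focal high-level amplifications (Kaplan–Meier, log-rank, Cox
  proportional hazards with Efron ties).
* **A synthetic cohort generator** that emulates this data structure —
  CMS-dependent CNA burden, purity/stroma admixture, linear dosage effects,
  injected focal amplifications, exponential survival — and records ground
  truth for recovery testing.

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

```bash
incis simulate --out cohort/ --seed 1
incis run --inputs cohort/ --out results/ --seed 1 --resample-iterations 200
```

or, in Python:

```python
from incis.simulate import SimConfig, simulate_cohort
from incis.config import PipelineConfig
from incis.pipeline import run_pipeline

sim = simulate_cohort(SimConfig(seed=1))
results = run_pipeline(PipelineConfig(seed=1, resample_iterations=200),
                       sim, "results/")
print(results["cms_overlap"])
```

On the default cohort this prints, per CMS subtype, the number of
upregulated genes and the fraction overlapping the in cis gain set:

```
  subtype  n_upregulated  n_overlap  overlap_fraction  depleted_variant
0    CMS1            143         24          0.167832             False
1    CMS2            243        118          0.485597             False
2    CMS3            249         14          0.056225             False
3    CMS4            414         14          0.033816             False
```

Roughly half of CMS2's expression program co-moves with its own copy
number, against ~3–6% for CMS3/CMS4 — the CMS2 program is largely
dosage-driven, while the CMS4 program is dominated by stromal admixture
(its 414-gene list shrinks to 239 after microenvironment depletion).
`results/` also contains the amplification peak table, in cis gene tables
for both directions, the resampling distributions
(CMS2 beats CMS4's overlap fraction in 100% of iterations here), and the
survival fits: carriers of recurrent focal high-level amplifications reach
25% 5-year survival against 54% for non-carriers (univariable Cox HR 2.18
against a generator truth of 3, attenuated because carriers of
non-recurrent amplifications sit in the reference group).

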