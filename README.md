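# compocor

Composition-bias-aware co-expression analysis for bulk RNA-seq.

## The problem

RNA sequencing measures proportions, not amounts: every sample yields a
fixed read budget, so normalizations that scale by the total read count —
TPM and FPKM — are zero-sum within a sample.  Whenever one transcript group
dominates the read pool, every other gene's normalized value is pushed down
in samples where that group is high and up where it is low.  The most
common dominant group is mitochondrial RNA, which ranges from a few percent
to well over half of the reads in human tissues and varies enormously
between donors of the same tissue; haemoglobin in whole blood and digestive
enzymes in pancreas do the same thing.

For correlation analysis this is toxic.  Across donors of one tissue,
total-count normalization manufactures **negative** correlations between
mitochondrial-encoded and nuclear genes and **positive** correlations
between arbitrary pairs of nuclear genes, with both effects growing with the
tissue's mean mitochondrial read fraction.  Genuinely co-expressed gene
pairs can flip sign.  Size-factor normalizations built from the bulk of
moderately expressed genes — median-of-ratios (MRN/RLE, the DESeq2
estimator) and the trimmed mean of M-values (TMM, the edgeR estimator) —
are insensitive to dominant transcripts and leave correlation structure
intact.

`compocor` packages everything needed to demonstrate, quantify and avoid
the artifact:

* **normalize** — TPM, FPKM, CPM-with-exclusions, upper-quartile, MRN and
  TMM, implemented from their definitions (MRN/TMM verified against the
  DESeq2/edgeR reference implementations to 1e-10), plus per-sample
  mitochondrial-fraction computation.
* **regress** — per-gene OLS removal of known confounders (age bracket,
  sex, death classification, ischemic time, sequencing batch), per-cohort
  or combined across cohorts with cohort interactions and donor blocks.
* **correlate** — the resampling machinery for gene-set co-expression:
  within-cohort ranking with cross-cohort rank aggregation and iterated
  medians (Spearman's ρ over subsample-rank-aggregate iterations),
  bootstrap confidence intervals and empirical sign-crossing p values with
  the 1/B substitution rule, random-gene-panel nulls with Shapiro–Wilk
  checks and Z statistics, donor-matched tumour/normal comparison with
  Fisher's exact test, and BH-FDR.
* **diagnostics** — per-cohort composition-bias curves (median set-pair,
  set-vs-random-panel and random-random correlations per normalization
  method against the mitochondrial fraction's mean and CV), Hartigan's dip
  test for bimodality (implemented from the greatest-convex-minorant /
  least-concave-majorant construction with a seeded Monte-Carlo null),
  signature scoring, and cohort-level meta-correlation.
* **simulate** — a negative-binomial multi-cohort count generator with a
  latent per-sample mitochondrial activity factor (controllable mean read
  share and CV), Gaussian-copula-planted block and cross-block Spearman
  correlations, confounder effects and library-size variation.  Because
  expression rates are renormalized to each sample's library size before
  count sampling, the generator reproduces the compositional artifact from
  first principles — and its planted truth makes parameter recovery
  testable.

## Worked example

Three synthetic cohorts of 150 donors with mean mitochondrial read
fractions of 10%, 30% and 60%, and a genuine mito-nuclear coordination
planted at Spearman ρ = 0.3:

```python
from compocor import *
from compocor.regress import DesignSpec

cfg = SimulationConfig(
    n_cohorts=3, samples_per_cohort=150,
    mt_fraction_mean=[0.1, 0.3, 0.6], mt_fraction_cv=0.3,
    rho_mt_nu=0.3, seed=42,
)
cm, catalog, truth = generate_dataset(cfg)

for method in ("tpm", "mrn"):
    for cohort, meta in cm.metadata.groupby("cohort"):
        sub = cm.subset_samples(list(meta.index))
        resid = regress_out(normalize(sub, method), sub.metadata,
                            DesignSpec.gtex_style())
        s = bootstrap_median_correlation(
            resid.values, catalog["mtOXPHOS"], catalog["nuOXPHOS"],
            n_bootstrap=1000, seed=0, cohort=cohort)
        print(method, cohort, round(s.median_rho, 3))
```

Output (median Spearman ρ over all 13 × 126 mito-nuclear gene pairs, with
95% bootstrap CIs):

```
--- TPM ---
cohort01 (mt 10%): rho +0.004 CI [-0.044, +0.042] p 0.459
cohort02 (mt 29%): rho -0.173 CI [-0.222, -0.118] p 0.001 (bound)
cohort03 (mt 58%): rho -0.313 CI [-0.357, -0.264] p 0.001 (bound)
--- MRN ---
cohort01 (mt 10%): rho +0.105 CI [+0.055, +0.147] p 0.001 (bound)
cohort02 (mt 29%): rho +0.083 CI [+0.043, +0.123] p 0.001 (bound)
cohort03 (mt 58%): rho +0.083 CI [+0.044, +0.124] p 0.001 (bound)
```

The coordination is genuinely positive — MRN reports it consistently in
every cohort (attenuated from the latent 0.3 by counting noise; see
`docs/methods.md`).  Under TPM the same data appear *uncorrelated* at a low
mitochondrial fraction and **strongly anticorrelated** at a high one: the
compositional artifact overwhelms and sign-flips the real signal.  A `p
0.001 (bound)` flag means no bootstrap replicate crossed zero, so 1/B is
reported as an upper bound.

The same pipeline is scriptable from the shell:

```bash
compocor simulate --config sim.yaml --seed 42 --out data/
compocor correlate --counts data/counts.tsv --annotation data/annotation.tsv \
    --metadata data/metadata.tsv --sets data/gene_sets.gmt \
    --mode per-cohort --out results/
compocor diagnose --counts data/counts.tsv --annotation data/annotation.tsv \
    --metadata data/metadata.tsv --sets data/gene_sets.gmt \
    --methods tpm,mrn,tmm --out results/
```

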