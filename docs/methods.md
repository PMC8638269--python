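# Methods

## The compositional model of the artifact

A sequenced sample is a multinomial draw of size L (the library size) from
the relative expression rates λ_g of its genes.  Total-count normalizations
divide by L (FPKM) or force the per-sample total to 10^6 (TPM), so the
normalized value of gene g behaves like λ_g / Σ_h λ_h.  Any latent factor
that scales a large group of genes — mitochondrial activity scaling the 13
mtDNA-encoded genes, which carry anywhere from ~5% to >95% of reads in
human tissue samples — enters the denominator of *every* gene.  Across
donors this induces (i) negative correlation between the dominant group and
all other genes and (ii) positive correlation among all other genes, both
increasing with the group's mean share and with the variability of the
latent factor.  Scale normalizations estimated from the bulk of moderately
expressed genes (median-of-ratios, TMM) track the denominator itself and
cancel it.

TPM's nuclear budget makes the effect concrete: with the per-sample total
fixed at 10^6, a sample whose mitochondrial genes carry a fraction f of the
length-normalized rate leaves exactly (1−f)·10^6 TPM for the nuclear
genome — 875,000 at f = 0.125 and 46,000 at f = 0.954.  These closed-form
values are recomputed by `scripts/acceptance.py` from freshly constructed
count matrices.

## Normalizations

* **FPKM**: count · 10^9 / (length_bp · library_size).
* **TPM**: length-normalized rates scaled to a 10^6 column sum; the direct
  route and the FPKM-ratio route agree to 10^-9 relative (asserted).
* **CPM with exclusions**: counts per million where a chosen gene set is
  removed from the denominator used for the remaining genes (the excluded
  genes keep the full-library scaling).  No length term — irrelevant for
  rank-based correlation, which never compares genes within a sample.
* **Upper quartile**: the 75th percentile (linear-interpolation quantile)
  of a sample's *non-zero* counts relative to library size, factors
  rescaled to geometric mean 1.  Note: the widely used edgeR variant takes
  the quantile over all genes including zeros; we follow the non-zero
  definition and record it in provenance.
* **MRN (median-of-ratios / RLE)**: reference = per-gene geometric mean
  over samples, restricted to genes positive in every sample; size factor
  = median over those genes of count/reference, with the median taken on
  the log scale (for an even gene count this is the geometric mean of the
  two middle ratios — the convention of the reference implementation, which
  our factors match to 10^-12 on a frozen fixture).
* **TMM**: reference sample = depth-normalized upper quartile closest to
  the mean (computed over all genes, zeros included, as in the reference
  implementation); per-gene log-ratio M and abundance A on genes positive
  in both sample and reference; double trim (30% of M tails, 5% of A
  tails) by average ranks; factor = 2^(precision-weighted mean of the
  surviving M) with delta-method binomial weights; factors rescaled to
  geometric mean 1.  Matches the reference implementation to 10^-12 on the
  frozen fixture and an independently scripted step-by-step oracle to
  10^-10 on random tables.

## Confounder regression

Each gene's normalized values are regressed by OLS on the cohort design:
age-bracket midpoint and ischemic time (numeric), sex, death
classification and sequencing batch (categorical, dummy-coded).  In
combined scope the covariates interact with cohort and donor is absorbed
as a categorical block.  Donor and batch enter as fixed-effect blocks
rather than random effects: with many levels, shrinkage differences are
immaterial for the rank statistics computed downstream, and the
fixed-effects fit is deterministic.  An exact mixed-model backend is a
declared extension point.  Aliased columns are dropped deterministically
(first occurrence kept) and reported.

Residuals are taken on the natural (pseudocount) scale, not logs.  The
generator applies confounder effects on the log scale; for realistic
effect sizes (≲ 2% per year of age, ≲ 10% per batch) the linear fit
removes them to rank-negligible residual correlation (|ρ| < 0.03 at
n = 500, asserted).  Much larger effects would need the log variant.

## Correlation machinery

**Combined across cohorts.** Residuals are ranked within each cohort on a
fixed-size subsample (k per cohort, equal representation), the
within-cohort ranks concatenated, and Pearson's correlation computed on
the concatenated ranks — the Spearman statistic on aggregated ranks.  No
global re-ranking is applied: within-cohort ranks repeat identically
across cohorts, so re-ranking would only manufacture ties.  The procedure
is repeated R times (default 100) and the elementwise median reported.
Between-set summaries are medians over all between-set gene pairs
(within-set: off-diagonal pairs); a gene appearing in both sets is
excluded from its own pair.

**Within one cohort.** All samples are used.  Inference on the median
set-pair ρ comes from B bootstrap resamples over samples (default 1000):
the 95% CI is the 2.5/97.5 percentile band; the raw empirical p is the
fraction of bootstrap medians on the opposite side of zero from the
observed value (sign-conditional, one-tailed), with 1/B substituted and
flagged as a bound when the fraction is zero; an observed median of
exactly zero gives p = 1.  Because the raw p is sign-conditional it is
uniform on (0, 0.5) under the null; the two-sided equivalent (twice the
fraction, capped at 1) is also reported and is the calibrated quantity.
BH-FDR is applied across cohorts and drives the significance call.

*Calibration caveat.* Bootstrapping a median over a large set of gene
pairs is conservative under the global null: each pair's bootstrap noise
has the same scale as its sampling noise, so the bootstrap median
regresses toward the ensemble centre by ≈ 1/√2 (measured centre-shrinkage
factor 0.70 for the 13 × 126 pair set; rejection 0.005 at nominal 0.05).
For the atomic single-pair statistic the percentile bootstrap is
consistent and the measured rejection rate sits inside the binomial
envelope.  The test suite pins down both behaviours.  The procedure is
never anticonservative, and for the effect sizes this analysis targets
(|ρ| an order of magnitude above the null spread) the conservatism is
immaterial.

**Random-gene null.** The comparison set is replaced by random panels of
expressed nuclear genes (median TPM > 5 across all samples, configurable)
for n_iter iterations (default 100, panel size 126); the observed median
is standardized against the null medians' mean and SD into a Z statistic,
with a Shapiro–Wilk check on the null medians and a normal-CDF p
(two-sided by default; the one-sided tail is also emitted).  The Z
statistic is N(0,1)-calibrated exactly when the comparison set is
exchangeable with the panels — the null scenario used in testing plants no
nuclear block, making the nuclear-OXPHOS set statistically identical to
the panel pool (measured over 50 null cohorts: mean −0.11, SD 0.98).

**Matched pairs.** Cohorts with at least 10 adjacent-normal samples;
normals matched 1:1 to same-donor primary tumours (one chosen at random
under the seed if several; unmatched normals dropped and counted); per
class, MRN-normalized residual medians with a subsampling SE (SD of the
median over 100 unique 90% subsets) and a bootstrap significance call; the
cross-class 2 × 2 table of significant-positive calls is tested with a
two-sided Fisher exact test implemented by hypergeometric summation
(p = sum of table probabilities ≤ the observed table's), verified against
full enumeration on all tables with margins ≤ 12 and against an
independent library implementation.

## Hartigan's dip

`dip_statistic` returns the sup-norm distance from the empirical CDF to
the nearest unimodal CDF via the iterative greatest-convex-minorant /
least-concave-majorant construction, narrowing onto the modal interval.
Anchors: D = 1/(2n) for any sample a unimodal CDF can thread exactly
(e.g. an equally spaced grid), D = 0.25 for two equal point masses (the
universal maximum), D = 0.125 for masses (¼, ½, ¼) — all derived by hand
and asserted; D ∈ [1/(2n), 0.25] is property-tested on 1000 random
samples.  p values come from a seeded Monte-Carlo uniform(0,1) null
(default 2000 draws, cached per sample size), floored at the 1/n_mc
resolution, rather than interpolation tables: exact reproducibility under
a seed, no table dependency.

## The synthetic generator

Each cohort draws, per sample, a standard-normal mitochondrial activity
latent w and a nuclear-block latent v with corr(w, v) set so the planted
cross-block Spearman is achieved; Spearman targets are converted to latent
Pearson correlations by the Gaussian-copula identity r = 2·sin(πρ/6), so
planted Spearman values are exact at the latent-rate level (verified to
±0.02 at n = 2000).  The mitochondrial multiplier exp(σ_m·w) — σ_m from
the target CV — is the mt block's *shared* factor: a varying mt fraction
necessarily co-expresses the mt genes (as their shared polycistronic
transcription does in real data), so mt_fraction_cv > 0 requires
rho_mt > 0 and the per-gene independent noise is set from the block
correlation target.  The mt baseline is calibrated analytically so the
expected read share equals mt_fraction_mean.  Confounder shifts (age, sex,
batch) are added on the log scale with per-gene coefficients; rates are
renormalized to a log-normal library size — the step that creates the
compositional artifact — and counts drawn Gamma–Poisson with per-gene
technical dispersion.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| mt_fraction_mean | 0.30 | mid-range of real tissue means (≈5%–>50%) |
| mt_fraction_cv | 0.30 | moderate within-tissue spread of the latent activity |
| rho_mt | 0.80 | tight mt co-expression, as observed for the polycistronic mt transcripts |
| rho_nu | 0.35 | the observed within-nuclear-OXPHOS coherence |
| bio_log_sd | 0.20 | ≈20% residual between-donor CV after confounder correction |
| nb_dispersion | 0.01 | technical overdispersion beyond Poisson; biological variation is modelled separately by bio_log_sd, so using a full (biological+technical) dispersion here would double-count |
| library size | log-normal, mean 2·10^6, log-SD 0.3 | desk-scale libraries for a 339-gene panel |
| confounders | age 0.003/yr, sex 0.10, batch 0.10 (log-scale coefficient SDs) | modest, realistic covariate effects |

**What the miniature does and does not emulate.** At 13 + 126 + 200 genes,
the correlated 126-gene block is ~37% of the size-factor estimation pool —
in a real transcriptome no co-expression program is more than a fraction
of a percent of the genes.  Large block amplitudes therefore leak into the
median-of-ratios/TMM estimates (the estimated factor picks up a component
of the block latent), producing a residual negative mito-nuclear median of
order −0.05 under MRN/TMM that has no counterpart at transcriptome scale;
the default amplitudes above keep this leakage small, and the
random-panel medians (which the leakage does not touch) are the stable
flatness readout.  The finite-sample correlation of the two block latents
adds irreducible noise of SD ≈ 0.04 to the mito-nuclear median at
n = 150, so that quantity is bounded by the sampling envelope ±2/√n
rather than a fixed ±0.05.  Other real-data features not emulated:
isoforms, gene-length biases beyond the length term, ancestry structure,
cell-type composition shifts, NUMT contamination.  Passing tests show the
*pipeline* behaves correctly under the compositional model; they are not a
claim about any specific tissue's biology.

**Recovery conditions.** The planted-correlation recovery check runs under
high-signal settings: bio_log_sd 0.8, nb_dispersion 0.01, mt CV 0.4, and
4000 background genes so the block fraction of the estimation pool is
transcriptome-like (3%).  Expected attenuation from counting noise is then
< 5%, and the combined pipeline recovers a planted cross-set Spearman of
0.5 to 0.44–0.48 across seeds.

**Problem sizes.** Test scenarios use 3–5 cohorts of 80–150 samples and
339–4139 genes; calibration suites use 40–200 single-cohort replicates
with B = 200 bootstrap resamples and 100-iteration null panels.  These
sizes give the asserted tolerances comfortable margins while keeping the
full suite under a minute of compute.

## Numerical conventions

* Ties in ranking: average ranks everywhere.
* All randomness flows from one seed through named SHA-256-keyed
  substreams per stage, so adding iterations to one stage never perturbs
  another, and identical seed + config reproduces every output byte.
* Aliased design columns: first occurrence kept, later duplicates dropped
  and logged.
* Degenerate inputs raise with the offending sample/gene named: zero
  libraries, all-zero samples, no all-positive gene for MRN, < 3 genes
  surviving the TMM trim, empty gene sets, constant signature genes.
* Bootstrap resamples that make a gene constant are redrawn (counted);
  observed medians of exactly zero short-circuit to p = 1.
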