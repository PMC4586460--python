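# Methods notes

## The outlier model

At each retained probe the cohort's β values x₁…x_N are screened for a
single outlier with the two-sided Smirnov–Grubbs statistic
G = maxᵢ |xᵢ − x̄| / s (sample SD, ddof = 1).  The p-value uses the
classical t inversion, p = min(1, 2N·P(T_{N−2} ≥ t_G)) with
t_G = √(N(N−2)G² / ((N−1)² − NG²)).  Two properties matter in practice:

* The formula is a union bound over the N observations.  We verified it
  against a 10⁶-draw Monte-Carlo null at N = 33: at G = 3.0 the bound is
  tight (0.0404 vs 0.0403 empirical), at G = 2.5 it is conservative by
  ~0.012, and below G ≈ 2.2 it saturates at 1.  Calls are made at
  Bonferroni-corrected p < 0.1, i.e. raw p below ~10⁻⁶ — far inside the
  regime where the bound is essentially exact — so the conservatism at
  small G never affects a call.
* One call per probe, attributed to the single most-deviant sample
  (ties broken to the lowest sample index); there is no iterative
  re-testing after outlier removal.  Δβ is computed against the mean of
  the other N − 1 samples, and sign(Δβ) fixes the hyper/hypo label.
* The Bonferroni denominator defaults to the number of probes actually
  tested.  It is exposed (`ScanParams.n_tests`) because the choice is a
  convention, not a theorem.  The cutoff is strict (< 0.1).
* Probes with zero variance (s ≤ 1e−8) or missing values are skipped
  and counted in the scan provenance rather than tested.

## Batch correction

`combat.py` implements the parametric empirical-Bayes location/scale
model: standardize per probe by the batch-design fit (grand mean
weighted by batch size, pooled residual variance with 1/n denominator),
estimate per-batch normal/inverse-gamma hyperparameters by method of
moments across probes, and solve the posterior (γ*, δ²*) by the standard
fixed-point iteration (tolerance 1e−4, ≤ 500 iterations — the reference
implementation's conventions).  No covariates are modelled, matching an
uncorrected-design correction; whether the phenotype should be protected
during correction is a genuinely open choice and the default here is
not to.  Correction is applied directly on β with [0, 1] clipping
afterwards (clips counted); an unclipped mode exists for diagnostics.
The implementation reproduces Bioconductor `sva::ComBat`
(par.prior=TRUE) on a frozen fixture to ~5e−13.

Degenerate inputs: one batch ⇒ identity; a single-sample batch is an
error (its variance is undefined); zero-variance probes are flagged and
passed through; a degenerate across-probe spread disables variance
shrinkage rather than producing undefined inverse-gamma moments.

Shrinkage means the correction does not exactly preserve per-probe
means in general (it does when the batch effect is homogeneous across
probes), and it mildly attenuates extreme single-sample deviations by
inflating the outlier's batch variance estimate.  The attenuation is a
property of the real analysis pipeline too, and is visible in the
recovered Δβ summaries (below).

## Group tests

Per-probe two-sided Wilcoxon rank-sum via `scipy.stats.mannwhitneyu`,
exact null when the smaller group has ≤ 10 samples and the probe is
tie-free, normal approximation with tie correction otherwise (group
sizes here are 4–19, where the approximation alone is unreliable).
Benjamini–Hochberg across probes at 0.05 through
`statsmodels.stats.multitest`.  The cohort's eight standard comparisons
are named presets.

## Annotation choices

* Lead-off rule: when a probe maps to several genes/features, only the
  first entry of the semicolon-joined manifest lists is used.
* pTSS = {TSS1500, TSS200, 5'UTR, 1stExon}; genic additionally includes
  Body and 3'UTR.
* Adjacency for clustering = consecutive rows of the retained
  (post-filter) manifest on the same chromosome, with no base-pair cap
  by default (a `max_gap_bp` option exists: probe spacing inside CpG
  islands is dense, but whether "adjacent" should tolerate distance is
  not well defined, so it is configurable rather than guessed).
  Clusters are direction-homogeneous and, by default, single-subject
  (`same_sample=True`), since epimutation clusters are per-individual
  events; cross-sample clustering is available for aggregate views.
* Gene subgroups use strict thresholds (Δβ > 0.2 excludes exactly 0.2).
* Enrichment is a generic one-sided hypergeometric test against
  user-supplied GMT gene sets, BH-corrected across terms, with fold
  enrichment (k/n)/(K/N).  The default universe should be the genes
  with ≥ 1 retained probe (array-composition bias control), which is
  what the pipeline passes; no ontology database is bundled.

## The synthetic cohort

The generator emulates the study design the scanner targets: 33
subjects in six phenotype × gestational-weight-gain categories
(5/5/4/9/5/5), injected epimutation burdens uniform in 46–74 per
subject in the reference category (normal_adequate) and 44–421 in the
five adverse ones, 68% of injected outlier probes hypermethylated,
hyper Δβ ~ N(0.18, 0.11) truncated positive and applied as runs of ≥ 2
adjacent CpG-island promoter probes (geometric run lengths, mean ≈ 3.2,
capped at 8), hypo Δβ ~ N(−0.27, 0.12) truncated negative at isolated
open-sea probes.  Per-subject burdens beyond the min/max ranges are not
specified anywhere, so uniform draws are used (configurable).

Probe landscape: 60,000 autosomal probes apportioned to chromosomes by
hg19 length, 30% in CGI-promoter blocks of 4–12 adjacent probes (gene
per block, pTSS features, island relation with shore/shelf edges), the
rest open-sea singles (55% gene bodies); 1,000 sex-chromosome probes,
65 rs-named genotyping controls, 18.5% SNP-flagged probes (the
array-wide flag rate), 50 detection-failure probes.  The probe count is
a scaled-down array: it preserves every structural feature the
analysis touches while keeping a full pipeline run in single-digit
seconds; the worst-case injected burden (421 per subject everywhere)
still fits the eligible promoter runs with headroom.

β model: per-probe baseline μ drawn from a low component
(U(0.02, 0.07)) at CGI promoters and a high component (U(0.87, 0.97))
at open sea, 5% intermediate; per-probe noise on the logit scale
(promoters σ ∈ U(0.05, 0.15) — constitutively unmethylated promoters
are tightly regulated on this platform, β-scale SD ≲ 0.01; open sea
σ ∈ U(0.10, 0.30)); batch 2 gets a +0.25 logit shift and ×1.10 scale
(the model class ComBat removes).  5% of SNP-flagged probes are
trimodal across samples (HWE genotypes at MAF U(0.05, 0.3) mapping to
β ≈ 0.03/0.5/0.97), mimicking sequence-dependent allele-specific
methylation — these justify the SNP-probe call filter.  Mosaicism of
epimutated and normal cells is represented implicitly by intermediate
Δβ magnitudes, not by explicit cell mixtures: the analysis only ever
sees aggregate β.  Injections are applied additively on the β scale
with clipping; injection sites exclude flagged/failed probes, so truth
recovery measures the scanner rather than the filters.

What the generator does **not** emulate: probe-type chemistry
differences (Infinium I vs II), spatial chip artifacts, cell-type
composition variation, correlated biological covariates, or genuine
group-level differential methylation.  Passing recovery tests therefore
demonstrates the scanner's operating characteristics under its own
model assumptions, not performance on any real cohort.

## Observed operating characteristics

Computed by the test suite and `scripts/acceptance.py`, never assumed:
sensitivity ≈ 0.91 overall and 1.00 for |Δβ| ≥ 0.25 at probes with
baseline SD ≤ 0.02, with 100% subject attribution and 0–2 false calls
per genome scan; null scans (10,000 probes, N = 33) show ≥ 1 false call
in well under 10% of replicates, conservative as Bonferroni promises.
Recovered Δβ means are attenuated relative to the injected means
(≈ 0.16 vs 0.18 hyper; ≈ −0.24 vs −0.27 hypo) by detection truncation
near threshold and by the batch-correction shrinkage discussed above.

## Numerical conventions

Grubbs G values above the algebraic maximum (N−1)/√N (floating-point
overshoot) collapse to the maximum; argmax ties break to the lowest
sample index; SD floors at 1e−8; manifest positions are 1-based
(MAPINFO convention) and BED export converts to 0-based half-open;
strand is ignored (CpG methylation is strand-symmetric on this array).
All randomness flows from a single integer seed through
`numpy.random.default_rng` seed sequences, so identical configurations
reproduce byte-identical artifacts.
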