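# Methods

## The per-CpG observation unit

All analyses run over a table with one row per genomic CpG dinucleotide that
has methylation data: chromosome, 0-based position of the forward-strand C,
methylation fraction `M`, replication timing `R` of the enclosing fixed-size
window (1 Mb by default; higher values = earlier replication), the
trinucleotide context centred on the C, and the mutation outcome. The table
is restricted to autosomes by default (configurable allow-list), since sex
chromosomes differ in both methylation dynamics and effective copy number.

Track-processing conventions:

* **Methylation.** Input bedGraph/BED rows are single-base records. A row on
  the C of a forward-strand CpG is authoritative; a row on the paired G is
  folded back onto the C and used only when no C-strand row exists (logged).
  Rows not on either base of a genomic CpG are dropped and counted. No
  coverage filter is applied by default; a minimum-coverage threshold is
  exposed. CpGs absent from the methylation file are dropped, not imputed.
* **Timing.** Each input track (bedGraph or text WIG) is averaged within
  windows (bp-weighted), then windows are averaged *across tracks* with equal
  weight per track, so a densely sampled cell type cannot dominate the
  consensus. Windows with no data carry NaN and are excluded from modelling;
  trailing sub-size windows at chromosome ends are kept.
* **Mutations.** Single-base substitutions only; indels/MNVs are skipped with
  a warning. Positions are 1-based on disk (tab-delimited or VCF-style) and
  0-based in memory. A PASS-only filter is available and is the default in
  the CLI pipeline.
* **Mutation classes.** A mutation is assigned to a CpG if it falls on either
  base of the dinucleotide. The default class set is deamination-equivalent
  (C>T on the C, G>A on the G); an "all substitutions at the CpG" option
  exists. The binary outcome is pooled per analysis cohort: a CpG is
  "mutated" if at least one sample of that cohort hits it, so the same site
  can be mutated for one subtype and unmutated for another.

## The logistic mutation model

`logit(P_mut) = b0 + b1·M + b2·M² + b3·R + b4·(M×R)`, fitted by Newton
maximum likelihood (statsmodels Logit; convergence tolerance 1e-8 on the
objective, 100 iterations maximum, deterministic given the input).
`M` enters as a raw fraction without centering and `R` on its native scale,
so coefficients are directly interpretable; this costs some numerical
conditioning, which the Newton solver handles at these problem sizes.
Complete separation raises an explicit error naming the worst-offending
term rather than returning divergent estimates.

* **Vertex** = −(b1 + b4·r) / (2·b2) at reference timing r (cohort mean by
  default). Values outside [0, 1] are meaningful and returned as-is: a
  vertex above 1 describes a monotone association over the attainable
  methylation range.
* **Model selection** walks the nested chain ∅ → M → M+M² → M+M²+R →
  M+M²+R+M×R. The LRT criterion selects the largest model for which *every*
  step improves at P < 0.05 (statistic 2Δℓ, χ² with Δk df); AIC = 2k − 2ℓ
  independently selects its minimum; disagreement between the criteria is
  reported, with the LRT choice as the headline. Equal adjacent specs are
  tolerated (LRT statistic 0, p = 1); non-subset chains are rejected.
* **AUC** is in-sample (the model is descriptive, not predictive;
  out-of-sample validation is out of scope) and computed as the
  tie-aware rank probability. "AUC delta" for a term is 100 × the AUC
  difference between the chain models just after and just before the term
  enters.
* **Per-sample fits** reuse the table with each sample's own outcome vector;
  vertices from two groups of samples are compared by unpaired t-test.

## Binned association statistics

Rates use mutations per Mb of CpG dinucleotide sequence: with n CpGs (2 bp
each) and k events in a methylation bin of width 0.1, rate = k/(2n)×10⁶.
Bin midpoints are the regression abscissae; the topmost bin is closed at
1.0; bins with zero CpGs are kept in the table but excluded from fits,
which require ≥3 non-empty bins. Slopes between groups are compared on the
stacked binned points with one OLS model containing a group × midpoint
interaction against a declared reference group; the interaction t-tests are
the slope-difference p-values. Replication-timing strata are genome-wide
tertiles of per-site timing (highest tertile = "early"); tie values at a
boundary go deterministically to the lower stratum. Whether binned rates
pool events or mutated-site counts is configurable upstream (events are the
default throughout).

Candidate-fraction analysis (per-sample percentage of low-methylation
(<0.25) vs high-methylation (>0.75) TCG-context CpGs carrying a
deamination-class mutation) reports both paired and unpaired two-sided
t-tests across samples, with the paired test as headline. One-sample t-tests
against a constant (e.g. gene-body CpG methylation against a hotspot
codon's methylation) define p by sign convention under zero variance
(p = 1 iff the common value equals the constant), flagged by a warning.

## Sample classification

96-channel spectra use the canonical pyrimidine-strand layout (6
substitution classes × 16 flanking contexts); purine-reference mutations
fold by reverse complement; contexts containing N are excluded with counts
otherwise conserved. POLE-mutant = somatic POLE mutation within amino acids
268–471 AND Pearson correlation strictly > 0.85 between the
proportion-normalised spectrum and the signature-10 reference (Pearson is
location/scale invariant, so normalisation is presentation only). An
MSI-high annotation takes effect only when the POLE criteria fail; all
remaining samples are MSS; a zero-variance spectrum leaves the correlation
undefined and the sample unclassified with a recorded reason. The packaged
signature-10 vector is a constructed synthetic stand-in
(`data/signature10_synthetic.tsv`) dominated by T[C>A]T and T[C>T]G, the
defining channels of the POLE ultramutator signature; any user-supplied
96-channel vector can replace it.

## Stop-gain candidates and origin asymmetry

The TCG stop-gain scan enumerates, over an in-frame CDS with one flanking
base on each side, every position where a single C>T (i) sits in a
5'-TCG-3' context on the mutated strand and (ii) converts a non-stop codon
into TAA/TAG/TGA. Both strands are scanned; "immediate truncation" means
the mutated codon itself becomes a stop, with no readthrough or splice
reasoning. A structural corollary the tests pin down: template-strand hits
(coding G>A) can never qualify, because the only G>A stop gains come from
TGG, whose Gs cannot carry the required coding-strand CGA context — so all
reported candidates are coding-strand C>Ts, consistent with hotspots like
the CGA→TGA arginine codons.

Origin strand asymmetry assigns each mutation of a context class (e.g.
T[C>T]G, written on the pyrimidine strand) within a flank (default 25 kb) of
a declared origin to (5' vs 3' of the origin) × (strand carrying the mutated
pyrimidine), and applies a two-sided Fisher exact test to the 2×2 table.
Hotspot contingency (group × mutant/wild-type) uses the same test.

## The synthetic-data generator

The generator emulates exactly the statistical structure the analysis
assumes, and is itself first-class, tested code:

* **Genome**: background sequence drawn without any C followed by G, with
  CpGs planted one per 1/density window (default density 0.02/bp over a
  10 Mb, 4-chromosome genome ≈ 2×10⁵ CpGs — the standard problem size used
  throughout the tests and the acceptance script, chosen to give the model
  comfortable power while keeping a full pipeline run in seconds). The
  planted CpGs are therefore provably the only CpGs, which makes scans
  exactly verifiable.
* **Methylation**: two-component Beta mixture, 75% Beta(6, 1.5) (high mode)
  and 25% Beta(1.5, 6), reproducing the bimodal shape of somatic WGBS data.
* **Timing**: one low-frequency sinusoid per chromosome over megabase
  windows, scaled to [25, 75] — the wavelet-smoothed Repli-seq scale on
  which timing coefficients of order 0.01 are meaningful. Methylation is
  independent of timing by default; a correlation knob exists to stress-test
  the model's ability to separate the two effects, a confounding that real
  genomes do exhibit.
* **Mutations**: per sample, each CpG mutates independently with probability
  expit of the planted linear predictor (default coefficients
  (−8, 3, −1, 0.01, 0.005)); a mutated CpG carries C>T on the C or G>A on
  the G with equal probability. Per-sample odds multipliers shift the
  intercept by log(multiplier). Any probability reaching 1 is rejected as
  implausible. Cohorts with a planted vertex v use b2 = −2 (curvature),
  b1 = −2·b2·v and b4 = 0, so the planted vertex is exact by construction.
* **Origins and CDSs**: strand labels around a declared origin are
  reassigned at a chosen 5'/3' bias ratio without changing positions or
  counts; toy CDSs embed ACT-CGA codon pairs as known stop-gain sites.

What the generator does *not* emulate — regional mutation-rate covariates
beyond timing, signature mixtures, selection, CpG islands, sample-matched
methylation changes in tumours — bounds what passing tests show: they
validate the statistical machinery and its calibration, not the biological
conclusions on any real cohort.

## Numerical and design choices

* Coordinates are 0-based half-open internally; BED-family inputs are read
  as 0-based, VCF-style positions as 1-based.
* Pooling both strands' mutations per CpG dinucleotide is the default
  (the deamination process is strand-symmetric at a palindromic site).
* The pooled multi-sample binary outcome shifts the fitted intercept
  relative to a per-sample generative model (≈ +log n_samples for rare
  events) while preserving the shape terms; single-sample simulation is
  used where intercept recovery itself is asserted.
* Fisher p-values come from scipy's exact routine and are cross-checked in
  the tests against full hypergeometric enumeration for all table sizes
  n ≤ 200; the logistic fit is cross-checked against an independent
  gradient-based likelihood maximisation to 1e-6, and the AUC against an
  O(n²) pairwise oracle.
* The slope-comparison test is calibrated: under identical generating
  slopes with Gaussian bin noise its type-I error is 0.05 ± 0.02 over 1000
  replicates (asserted in the test suite and recomputed by the acceptance
  script).

## Known limitations

Timing input must be text bedGraph/WIG (no bigWig). Gene models are BED12
only. The signature-10 reference is a labelled synthetic stand-in, adequate
for exercising the classification rule but not for classifying real
cohorts. AUC is in-sample by design. Raw p-values are reported without
multiple-testing correction, matching the analysis style the toolkit
implements.
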