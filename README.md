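# mutscape

Methylated cytosines deaminate readily: a 5-methylcytosine (5mC) in a CpG
dinucleotide that loses its amine group reads as thymine, and if the G•T
mismatch is not repaired before replication, a C>T mutation is fixed in the
genome. How fast such mutations accumulate depends not only on how often a
CpG is methylated but on *when* its neighbourhood replicates, because the
repair pathways that catch deamination damage (mismatch repair, nucleotide
excision repair) work better in early-replicating chromatin. `mutscape` is
a toolkit for quantifying that interplay in somatic mutation data: it is
aimed at cancer-genomics analysts who have whole-genome somatic mutation
calls, a tissue-matched WGBS methylation track and Repli-seq replication
timing, and want to measure how methylation and timing jointly shape the
CpG mutation landscape of a cohort.

## The model

Every genomic CpG with methylation data becomes one observation: methylation
fraction *M* ∈ [0, 1], replication timing *R* of its megabase window (higher
= earlier), and a binary outcome — mutated in at least one sample of the
cohort, or never mutated. The core is a binary logistic regression with a
quadratic methylation term and a methylation × timing interaction:

```
log( P_mut / (1 − P_mut) ) = b0 + b1·M + b2·M² + b3·R + b4·(M × R)
```

The quadratic makes the log-odds a parabola in *M*; its extremum (the
**vertex**, evaluated at a reference timing, by default the cohort mean) is
the methylation fraction beyond which more methylation no longer increases
mutation probability. A vertex above 1 means the association is monotone
over the whole methylation range; a vertex inside [0, 1] is the signature of
repair processes that preferentially protect highly methylated,
early-replicating gene bodies. Nested models (intercept → +M → +M² → +R →
+M×R) are compared by likelihood-ratio tests (every step must improve at
P < 0.05) and by AIC, with in-sample AUC quantifying what each term adds.

Around the model sit the supporting analyses: binned mutation rates per Mb
of CpG sequence in 0.1-methylation bins with slope comparisons between
cohorts or replication-timing tertiles; per-sample slopes and vertices;
MSS / MSI / POLE-mutant sample classification from 96-channel trinucleotide
spectra (POLE-mutant = exonuclease-domain mutation at amino acids 268–471
plus Pearson r > 0.85 with signature 10); exhaustive enumeration of coding
TCG sites where a single C>T creates an immediate stop codon; and Fisher
exact tests of mutation strand asymmetry across replication origins. A
synthetic-data module generates genomes, bimodal methylation, smooth timing
tracks and mutation cohorts drawn from the logistic model itself, so the
entire pipeline runs and is tested without any external data.

## Worked example

```python
from mutscape import simulate as sim
from mutscape.model import CpGMutationModel, select_model, auc_delta
from mutscape.association import binned_rate

cfg = sim.SimulationConfig(seed=1)            # 10 Mb genome, ~2e5 CpGs, 10 samples
tracks, table, mutations = sim.simulate_cohort(cfg)
assoc = binned_rate(table)
sel = select_model(table)
print(sel.fits[-1].summary())
print(f"AUC gain from adding timing: {auc_delta(sel, 'R'):.1f} percentage points")
```

prints

```
CpG mutation logistic model
  n = 199996, terms = intercept + M + M2 + R + MxR
  log-likelihood = -27701.1347   AIC = 55412.2695
  converged = True

  coef     estimate    std err        z
    b0     -5.63461     0.1744   -32.31
    b1      3.11664     0.3383     9.21
    b2     -1.17327     0.2305    -5.09
    b3   0.00667265   0.002933     2.27
    b4   0.00873753   0.003642     2.40

  AUC = 0.6560
  vertex (at mean R) = 1.5144
AUC gain from adding timing: 2.3 percentage points
```

The cohort was generated with coefficients (−8, 3, −1, 0.01, 0.005); pooling
ten samples into the binary outcome shifts the intercept upward (roughly by
log 10) while leaving the shape terms near truth, so each slope estimate
lands within two standard errors of its generating value. The vertex above 1
says mutation probability rises with methylation across the whole [0, 1]
range in this cohort, and timing adds 2.3 AUC percentage points. The binned
view of the same table (`binned_rate`) gives a slope of ~25,300 mutations/Mb
per unit methylation with r² = 0.97.

The same pipeline is scriptable from the shell:

```
mutscape reproduce-synthetic --seed 1 --out runs/demo
mutscape simulate --seed 3 --out runs/sim      # writes FASTA/bedGraph/TSV inputs
mutscape annotate --genome runs/sim/genome.fa --methylation runs/sim/methylation.bedgraph \
    --timing runs/sim/timing.bedgraph --mutations runs/sim/mutations.tsv --out runs/ann
mutscape fit --table runs/ann/cpg_table.tsv --out runs/fit
```

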