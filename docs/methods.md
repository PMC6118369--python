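# Methods

This note documents the models, statistics and numerical choices behind
`ffconcord`: what each stage assumes, which knobs matter, what the
synthetic world does and does not emulate, and therefore what a green
test establishes.

## 1. The synthetic matched experiment

### Design

Eight tumors, two per subtype (Luminal-A ER+/HER2−, Luminal-B ER+/HER2+,
HER2-amplified ER−/HER2+, Triple-Negative ER−/HER2−), profiled as five
matched datasets:

| dataset  | design           | preservation | default severity d |
|----------|------------------|--------------|--------------------|
| ff.A     | A (PM-MM)        | fresh-frozen | –                  |
| ffpe.A   | A (PM-MM)        | FFPE         | 0.8                |
| ff.B     | B (PM-only + AG) | fresh-frozen | –                  |
| ffpe.B1  | B                | FFPE         | 0.5                |
| ffpe.B2  | B                | FFPE         | 0.5                |

Design A mirrors a classic PM-MM expression array processed with a
polyA-dependent amplification kit (hence the near-destroyed FFPE
counterpart, severity 0.8); design B mirrors a PM-only array with 23
anti-genomic background probesets and FFPE-capable kits (moderate
severity 0.5).  Genomic probesets are 1:1 with genes, 11 probes each; an
optional flag adds duplicate probesets for a leading fraction of genes
to exercise max-variance probeset selection.

### Intensity model

Linear intensity of PM probe p (gene g, sample s, dataset k):

    I = 2^( mu_gs + log2 r_gsk + a_p + b_pk + eps ) + B

* `mu_gs` — true log2 expression: a per-gene base mean Uniform(6.5, 12)
  for expressed genes (fraction 0.6 of 2000), plus a per-gene per-tumor
  biological deviation N(0, 1²) shared by all datasets (the same tumors
  are profiled everywhere), plus planted ER/HER2 effects ±2 log2 units
  in marker-positive samples (50 genes per pathway, alternating sign).
  The base range starts just above the background mean (6.0) because
  real arrays measure many transcripts near the detection limit; this is
  what lets degradation push a realistic fraction of genes below
  background.  Inter-tumor biological variance (σ = 1 log2) is the
  signal that gene- and module-level concordance measures.
* `r_gsk` — retention.  Per gene and FFPE dataset, r_gk ~
  Beta(κ(1−d)+1, κd+1) with concentration κ = 10 and severity d; r ≡ 1
  for FF and for d = 0 (severity zero is lossless by definition).  The
  per-gene fragility *rank* is drawn once and mapped through each
  dataset's Beta quantile function, so the same genes are lost in every
  FFPE dataset while each dataset keeps the exact stated marginal —
  degradation is a property of the tissue block, and this sharing is
  what makes FFPE↔FFPE concordance exceed FF↔FFPE, the study design's
  central contrast.  On top, each block's fixation history perturbs
  individual gene × sample measurements: a tissue-shared standard-normal
  field scaled by d·1.0 log2 shifts log2 retention (clipped at 0).
* `a_p` — per-probe affinity N(0, 0.3²), shared across datasets of a
  design; `b_pk` — per-dataset kit perturbation N(0, 0.2²).
* `eps` — measurement noise N(0, 0.25²), plus a fragmentation term
  (d·0.5)·z with a tissue-shared per-probe-per-sample field z: random
  fragmentation hits probe target regions unevenly, which is the
  mechanism by which FFPE probesets lose probe-level coherence and PVAC
  keeps fewer of them.
* `B` — additive background, log2 B ~ N(6.0, 0.5²), drawn independently
  per probe and sample, identical in law for genomic, anti-genomic and
  MM probes.  Anti-genomic probesets, non-expressed genes, incoherent
  probesets and MM probes emit background only.  A per-dataset
  background-mean override reproduces the "unrealistically low
  background" artifact some amplification kits show.

Seeding: the master seed spawns named substreams (hash of
"truth"/"design"/"dataset"/… tags), so adding a dataset never perturbs
the draws of another, and reruns are bit-identical.

### What the generator does not emulate

No probe-sequence/GC cross-hybridization model, no 3′-positional bias
curve (retention is flat across a probeset), no batch/scanner effects,
no IHC misclassification.  A green end-to-end test therefore establishes
that the pipeline recovers the planted degradation structure — not that
it would be robust to sequence-driven artifacts real arrays can show.

## 2. Preprocessing

Fixed stage order per dataset, each dataset normalized independently:
background-correct (linear) → quantile-normalize (linear) → log2 →
median-polish → collapse to genes.

* **Normexp background correction.**  X = S + B with B ~ N(μ, σ²),
  S ~ Exp(mean α).  The posterior of S given X = x is N(μ_sf, σ²)
  truncated to [0, ∞), μ_sf = x − μ − σ²/α, so E[S|X] has the closed
  form μ_sf + σ·φ(μ_sf/σ)/Φ(μ_sf/σ), evaluated in log space for the far
  tail.  Parameters per sample, by a deliberately simple mode-anchored
  scheme: μ = histogram mode (coarse 64-bin pass, then a finer pass
  around the coarse mode — the signal exponential tilts a single coarse
  histogram), σ = RMS of values at or below the mode, α = mean excess
  above the mode.  The stage accepts injected parameters, which is how
  the quadrature oracle pins the transform independently of estimation.
* **Quantile normalization.**  Ordinal ranks (stable ties) onto the
  across-sample mean of sorted columns; after normalization every sample
  holds the identical sorted vector.  Single-sample input passes through
  with a warning.
* **Median polish.**  Additive probes + samples model per probeset,
  alternating row/column median sweeps; stop when the sum of absolute
  residuals changes by < 0.01, max 10 iterations (both configurable).
  Probeset expression for sample j = overall + column effect j.
  Anti-genomic probesets are summarized too (background diagnostics use
  them).
* **Gene collapse.**  Per gene, keep the probeset with maximal log2
  variance *in this dataset*; a gene may be represented by different
  probesets in different datasets (deliberate — this is also why
  probeset-level sample correlations can beat gene-level ones).
  Anti-genomic and unannotated probesets are dropped.

Open choice: whether anti-genomic probes belong in the quantile
reference distribution.  Default: include all probes of the design;
`include_antigenomic_in_norm=False` normalizes them separately.

## 3. Detection calls

Binary Present/Absent at α = 0.05, computed on raw linear intensities
(no Marginal category).

* PM-MM: discrimination scores R_i = (PM_i−MM_i)/(PM_i+MM_i); one-sided
  Wilcoxon signed-rank of R − τ > 0, τ = 0.015.  All-zero score vectors
  (PM ≡ MM with τ = 0) are Absent with p = 1 and a warning.
* PM-only: per sample, all probes of all anti-genomic probesets are
  pooled into one background vector (`ag_pool="all"`; a
  per-probeset-representative variant exists).  Each genomic probeset's
  probes are tested one-sidedly (greater) against the pool; anti-genomic
  probesets are tested against the pool of the *other* anti-genomic
  probesets, so they carry calls and can be Present by chance —
  their Present-rate is the empirical type-I calibration check.
  p-values: exact null when the pooled size is ≤ 60 and tie-free, else
  the tie-corrected normal approximation with continuity correction.
  One-sidedness and the exact/asymptotic switch are documented
  interpretations (the upstream algorithm description leaves them open).

## 4. PVAC probe-coherence filtering

Score per probeset: probes as variables over samples, centered (no
rescaling — the agreement interpretation needs raw covariance); score =
λ₁/Σλ of the probe×probe covariance = proportion of probe-level
variance on the first principal component, computed by SVD of the
centered block.  Zero-variance blocks score 0 with a warning.

Scores are computed on background-corrected, quantile-normalized log2
probe data (raw-input use is possible by passing that matrix instead).
Negatives: `AAB` = genomic probesets Absent in all samples (fails
loudly when detection is compromised and no all-absent probesets
exist); `AG` = the design's anti-genomic probesets (PM-only designs
only).  Cutoff = 0.95 quantile of negative scores (`max` rule
available); selection is strict (score > cutoff); anti-genomic
probesets are never selected; ≥ 5 scored negatives required.

## 5. Module scores and subsets

Score = mean(+1-gene log2 expr) − mean(−1-gene log2 expr).  An empty
weight class contributes 0, so all-positive control modules score as a
plain mean.  Genes absent from a dataset are silently dropped; a module
needs ≥ 2 present genes to be scored.  All log2 expression is expected
positive for the sign interpretation.  The classic weighted average
Σw·x/n is provided for diagnostics only; the two coincide (up to the
per-class normalization) exactly when the weight classes are equally
large.

Subsets: per dataset and PVAC strategy, a module subset keeps the
selected genes with their original weights; if any version anywhere
falls below 2 genes, every version of the module is discarded.
Surviving modules are validated on the FF PM-MM reference dataset: any
subset version whose scores correlate (Spearman) < 0.9 with the full
module's reference scores discards the module.  Versions from the
near-background FFPE PM-MM dataset are excluded from this validation
(their expression is too close to background to be meaningful) but they
do participate in the size rule.  Complement subsets (the non-selected
genes) and expression-quartile subsets q1–q4 (empirical quartiles of
module genes' dataset-specific mean expression; boundary ties fall into
the lower quartile, so mean expression is ordered q4 > q3 > q2 > q1;
quartiles are over module genes only, not the whole array) support the
diagnostics on what drives module-score concordance.

## 6. Concordance measurement

Comparison schemes: ref-1 (reference ff.A vs all others), ref-2 (ff.B
vs the FFPE PM-only datasets), ref-3 (ffpe.B1 vs ffpe.B2).  All
correlations are Spearman.

* Module level: the robust correlation = arithmetic mean of Spearman ρ
  over all n leave-one-out subsets of the n = 8 paired samples.
  Subsets where either vector is constant are skipped and counted (the
  count is reported for audit).  Matched-dataset scores — full module
  and every subset version — are always correlated against the
  *reference full-module* scores.  Reproducible ⇔ ρ > 0.8 (strict).
  The leave-one-out averaging applies to module scores only.
* Gene level: per common gene, Spearman across the 8 paired samples;
  the fraction with ρ > 0.75 is reported as the descriptive summary.
  Constant genes are excluded with a count.
* Sample level: per sample, Spearman across common features, at gene or
  (same-design pairs only) probeset level.

A high module-score correlation measures agreement, not presence, of a
biological signal: a module whose genes sit at background in both
datasets can correlate highly.  Control modules (all +1 weights, drawn
from genes absent in the tissue) make this limitation visible in the
reports.

## 7. De-novo signatures and ROC validation

Per dataset, marker (ER or HER2) and gene universe (all genes,
PVAC-AAB-selected, PVAC-AG-selected): Welch's unequal-variance t-test
(two-sided; Welch–Satterthwaite df) and the log2 fold change (difference
of group log2 means = log2 ratio of geometric means) between
marker-positive and marker-negative tumors.  A gene enters the module
iff |log2FC| > log2(2) and p < 0.05; weight = sign(log2FC).  No
multiple-testing correction — the fold-change + raw-p screen is the
point of this selection style; its reliability is judged by external
validation, not by the p-values.

Validation: module scores on an independent synthetic cohort (default
100 samples, statuses cycling through the four subtypes, gene-level
noise σ = 0.5); AUC computed as the tie-aware pairwise-comparison
probability (equal to the area under the empirical ROC curve).
Signature comparisons use DeLong's test for correlated ROC curves via
the structural-components estimator: per-positive components V10,
per-negative V01, covariance of the paired components, two-sided normal
p for the AUC difference.  Degenerate variance (e.g. two perfect,
rank-identical ROCs) returns p = 1 with a warning.

## 8. Numerical and edge-case policy

* Spearman on ≤ 8 samples is coarse (ρ granularity ~0.02); the
  leave-one-out average smooths but does not remove this.
* Exact signed-rank/rank-sum nulls are used whenever tie-free and small
  enough; otherwise tie-corrected normal approximations with continuity
  correction.
* Constant vectors: correlations are undefined, never zero-filled —
  they are skipped/failed with warnings and counts.
* TSV floats are read with round-trip precision so write→read→write is
  byte-stable.
* The pipeline is a pure function of (RunConfig, SimulationConfig):
  identical seeds give bit-identical bundles.

## 9. Known limitations

* The PVAC cutoff from 23 anti-genomic negatives is a 0.95 quantile of
  23 values — noisy by construction; AAB (hundreds of negatives) gives
  a more stable cutoff when detection is trustworthy.
* The de-novo validation cohort shares the generator's truth (fresh
  noise, fresh samples); it is independent in the statistical sense but
  not an external dataset — AUCs near 1 reflect the strength of the
  planted effects, not field performance.
* With eight samples per dataset, fraction-reproducible estimates move
  in steps of 1/(number of kept modules); small-world runs wobble
  accordingly, which is why directional tests use larger worlds or
  stronger severities.
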