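# ffconcord

Concordance analysis for matched fresh-frozen (FF) / FFPE microarray
expression profiles.

Formalin fixation fragments RNA, so expression profiles measured from
FFPE tissue on short-oligo arrays are only partially faithful to the
profiles of matched fresh-frozen material.  `ffconcord` implements the
full analytical chain used to quantify that loss on a matched study
design — the same eight breast tumors (two per subtype: Luminal-A
ER+/HER2−, Luminal-B ER+/HER2+, HER2-amplified ER−/HER2+,
Triple-Negative ER−/HER2−) profiled as five datasets across a PM-MM
array and a PM-only array carrying anti-genomic background probesets —
together with a synthetic-data generator that emulates the design with
known ground truth, so every stage can be validated against planted
truth.

The package is aimed at computational biologists evaluating whether
gene signatures derived from (or applied to) FFPE expression data can be
trusted, and at method developers who need a controlled testbed for
probe-level QC procedures.

## What it computes

* **Preprocessing** — normal+exponential ("normexp") background
  correction, quantile normalization, median-polish summarization,
  max-variance collapse of probesets to genes.  For observed intensity
  X = S + B with B ~ N(μ, σ²) and signal S ~ Exp(α), the corrected value
  is the exact posterior mean E[S | X = x] = μ_sf + σ·φ(μ_sf/σ)/Φ(μ_sf/σ),
  μ_sf = x − μ − σ²/α.
* **Detection calls** — Present/Absent at level α = 0.05.  PM-MM designs:
  one-sided Wilcoxon signed-rank on discrimination scores
  R_i = (PM_i−MM_i)/(PM_i+MM_i) against τ = 0.015.  PM-only designs:
  one-sided Wilcoxon rank-sum of each probeset's probes against the
  pooled anti-genomic background probes.
* **PVAC probe-coherence filtering** — per probeset, the proportion of
  probe-level variance captured by the first principal component;
  cutoff at the 0.95 quantile of "negative" probesets (all-absent, AAB,
  or anti-genomic, AG).
* **Module scores** — for a weighted (±1) gene set, score = mean(log2
  expr of +1 genes) − mean(log2 expr of −1 genes), so a positive score
  directly reads as "positively associated genes are higher".
* **Reproducibility** — module-score agreement between a reference and a
  matched dataset as the average Spearman ρ over all leave-one-out
  (7-of-8) sample subsets; a module is reproducible when ρ > 0.8.
  Comparisons follow three schemes: ref-1 (gold-standard FF PM-MM as
  reference), ref-2 (FF PM-only), ref-3 (FFPE vs FFPE).
* **De-novo ER/HER2 signatures** — genes with |linear fold change| > 2
  and Welch's t-test p < 0.05 between marker-positive/negative tumors,
  weighted by fold-change sign; validated by AUC on an independent
  cohort and compared against a reference signature with DeLong's test
  for correlated ROC curves.

The preprocessing, filtering and signature stages are also exposed as
scikit-learn estimators (`QuantileNormalizer`, `RmaBackgroundCorrector`,
`MedianPolishSummarizer`, `PvacSelector`, `DenovoModuleClassifier`) that
compose with sklearn pipelines.

## Worked example

Run the whole pipeline on the default synthetic world (2000 genes,
8 tumors, severities: FFPE PM-MM 0.8, FFPE PM-only 0.5):

```sh
ffconcord run-all --seed 1 --out ffconcord_out
```

or equivalently `python scripts/acceptance.py --seed 1 --out results/acceptance.json`,
which prints (stderr):

```
percent-present per dataset:
  ff.A: 60.7%
  ffpe.A: 54.2%
  ff.B: 61.6%
  ffpe.B1: 60.8%
  ffpe.B2: 61.3%
modules kept after filtering: 43/47
ref1 reproducible fraction (full modules): {'ffpe.A': 0.49, 'ff.B': 1.0, 'ffpe.B1': 0.58, 'ffpe.B2': 0.63}
ref2 reproducible fraction (full modules): {'ffpe.B1': 0.65, 'ffpe.B2': 0.7}
ref3 reproducible fraction (full modules): {'ffpe.B2': 0.95}
median de-novo validation AUC by marker: {'ER': 1.0, 'HER2': 1.0}
```

Reading: percent-present falls in the degraded datasets (most for the
polyA-kit FFPE dataset `ffpe.A`).  Between the two frozen datasets every
kept gene module is reproducible (ref-1 fraction 1.0 for `ff.B`), but
only ~half to two-thirds of the modules survive the move from frozen to
FFPE (0.49–0.63).  The two FFPE datasets agree with each other far
better (ref-3 fraction 0.95) — the signal lost in fixation is lost
consistently, not at random per dataset.  Both ER and HER2 de-novo
signatures derived from any dataset separate the validation cohort
essentially perfectly (AUC ≈ 1), showing strong differential signals
survive even heavy degradation.

The bundle under `ffconcord_out/` contains per-dataset probe matrices,
probeset/gene expression TSVs, detection calls, PVAC selections, the
per-comparison correlation tables and the de-novo ROC summary.
Individual stages are available as subcommands (`simulate`,
`preprocess`, `detect`, `pvac`, `score`, `compare`, `denovo`) operating
on the TSV / weighted-GMT formats, so external data exported to TSV can
enter at any stage.

## Acceptance script

`scripts/acceptance.py --seed <int> --out <path>` re-runs the full
default pipeline from scratch with the given master seed — simulation,
preprocessing, detection, PVAC filtering, module filtering and scoring,
the three reference comparisons and de-novo signature validation — and
writes the results JSON to `--out` while printing the run summary to
stderr.

## Layout

```
src/ffconcord/
  design.py       array designs (probe -> probeset -> gene, PM-MM / PM-only)
  io.py           TSV / weighted-GMT formats, run configuration
  simulate.py     matched-experiment generator with ground truth
  preprocess.py   normexp background, quantile norm, median polish, gene collapse
  detection.py    MAS5-style and anti-genomic rank-sum detection calls
  pvac.py         PVAC scoring, negative strategies, filtering
  modules.py      gene modules, scores, subsets, diagnostics
  concordance.py  ref-1/2/3 comparisons, robust module correlation
  denovo.py       Welch screen, AUC, DeLong test, signature classifier
  pipeline.py     end-to-end orchestration
  cli.py          click command-line interface
docs/methods.md   model and procedure documentation
```
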