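# Methods

## Problem setting

A tumor-only RNA-seq variant callset is a mixture of four populations: true
somatic mutations, germline variants, FFPE fixation artifacts (deaminated
cytosines read as C>T on one strand, G>A on the other), and RNA-specific
calling noise (reverse-transcription errors, splice-boundary misalignment,
allele-specific expression). TMB only counts the first population. The
package provides two routes from the raw callset to a somatic estimate — a
deterministic rule recipe and a supervised classifier — and an evaluation
layer that scores either route against WES-derived TMB.

## Filtering recipes

Matched-normal WES callsets are filtered to `FILTER == PASS`: the caller has
already used the normal to flag germline calls. Tumor-only WES adds the two
population criteria (ExAC ALL frequency < 3.3 × 10⁻⁵ and no dbSNP
identifier). Tumor-only RNA-seq uses a FILTER-label whitelist instead of
PASS — a tumor-only caller without a panel of normals marks most genuine
somatic variants `germline_risk`, so the default whitelist is {∅,
{germline_risk}, {panel_of_normals, germline_risk}}. The stricter reading
that excludes PASS records is available by configuration
(`allowed_rnaseq_filter_sets`); which of the two a given assay should use
depends on how its caller was run, and both are first-class.

Two deliberate conventions:

* a variant absent from ExAC **passes** the frequency filter — population
  resources do not contain most somatic mutations, and the contrary choice
  would discard nearly everything of interest;
* the frequency comparison is a strict `<` at exactly 3.3 × 10⁻⁵ (a variant
  observed at exactly the threshold is removed);
* dbSNP membership is true if either the VCF ID column carries an `rs`
  identifier or the annotation field does — real pipelines populate both
  channels (caller resource and annotator), and either alone is evidence.

Multiallelic sites never enter the pipeline: a record with a comma in ALT is
dropped at ingestion, and so are groups of biallelic lines sharing
(chrom, pos, ref), which are the same tri-allelic site after splitting. The
exclusion count is kept on the callset so totals reconcile.

## Feature representation

The default registry has 31 features: 23 numeric caller fields (allelic
depths, allele fraction, depth, TLOD, NLOD, ECNT, POPAF, GERMQ, SEQQ, median
base/mapping quality and position, median fragment lengths, the
strand-artifact MAP allele-fraction and posterior pairs, and the F1R2/F2R1
orientation counts), the non-TCGA ExAC allele frequency, and 7 engineered
features (insertion flag, deletion flag, C>T (G>A) transition flag, C>A
(G>T) transversion flag, total depth from the AD pair, and the literal REF
and ALT string lengths). The exact caller-field list is configurable because
Mutect2's INFO/FORMAT vocabulary varies across GATK versions; the default
covers the fields current Mutect2 emits. Published feature counts for this
kind of model vary between 31 and 32 depending on how the strand-artifact
list is expanded; this registry settles on 31 and treats the discrepancy as
a bookkeeping difference, not a modeling one.

Strand-artifact lists are mapped deterministically: a 3-element list
(forward-artifact, reverse-artifact, no-artifact) keeps its last two
entries as (SA_MAP_AF_1, SA_MAP_AF_2) = (reverse-artifact, no-artifact); a
2-element list maps positionally.

Missing fields become NaN and stay NaN — gradient-boosted trees route
missing values natively, and imputation would inject information the data
does not contain. Transition/transversion flags are defined only for 1-bp
substitutions; indels get 0 for both.

## Labels and the classifier

Training labels are produced per sample: an RNA-seq variant is **signal**
iff the same genomic coordinate appears in that sample's filtered WES
callset (coordinate matching is the labeling rule; full-key matching — also
requiring REF/ALT agreement — is exposed and is what the `isec` analysis
mode uses). When training callsets are pooled across samples, each variant
is still matched only against the WES callset of its origin sample;
cross-sample matching would manufacture false signal labels.

The classifier is XGBoost (`binary:logistic`, `hist`), tuned by randomized
search over nine hyperparameters — learning_rate, n_estimators,
min_child_weight, gamma, subsample, colsample_bytree, max_depth, reg_alpha,
reg_lambda — with the widest grids on the first two, which dominate in
practice. Model selection uses five-fold **stratified** CV scored by ROC
AUC; stratification matters because signal prevalence is typically a few
percent or less. The search budget defaults to 50 draws; the test suite and
the acceptance script use 3-draw searches, which on the simulated cohorts
already reach CV AUC ≈ 1 — the problem sizes there are chosen so the whole
suite runs comfortably on one CPU. Class re-weighting
(`scale_pos_weight`) is available but off by default. The classification
cutoff on the signal probability defaults to 0.5 and is exposed.

Everything is seeded: the CV folds, the search, and the booster share one
integer seed, and two runs with equal inputs and seed produce bitwise-equal
predictions. Positive class is signal throughout, including the confusion
matrix layout (TP = correctly predicted signal).

## TMB and concordance

TMB = (calls inside the analyzed regions) / (region megabases). The region
set is always explicit — there is no built-in denominator constant, because
a hidden denominator is the main source of irreproducible TMB numbers. An
empty region set is an error, not an infinity. Dichotomization is inclusive:
high iff TMB ≥ threshold, at thresholds 6, 10 and 20 Mut/Mb.

Concordance treats WES-TMB as the gold standard: high/low labels always come
from the WES values and the raw RNA-seq TMB is the ranking score. ROC AUC
uses mid-ranks (Mann–Whitney), so tied scores count ½; a threshold that
empties one class yields "not applicable" (NaN / JSON null), never a
fabricated number. Correlations are Pearson and Spearman with two-sided
p-values and no multiple-testing correction; a constant vector yields NaN
with a warning.

## The simulator

`simulate_cohort` emulates the study conditions the pipeline is meant for:

| parameter | default | meaning |
| --- | --- | --- |
| `n_samples` | 40 | cohort size |
| regions | 3.0 Mb over 66 exonic-style intervals, chr1–22 | TMB denominator |
| `tmb_median`, `tmb_sigma` | 5.0, 1.0 | log-normal true TMB (Mut/Mb); P(TMB ≥ 10) ≈ 0.24, matching the ~27 % high-TMB fraction of pan-cancer FFPE cohorts |
| `germline_per_mb` | 150 | germline burden; frequencies log-uniform on [10⁻⁴, 0.5], dbSNP-tagged with p = 0.95, absent from ExAC with p = 0.02 |
| `ffpe_artifact_per_mb` | 30 | artifact burden, C>T/G>A with p = 0.8 |
| `rna_noise_per_mb` | 20 | RNA-specific noise burden |
| `mean_gene_mapped_reads` | 23 × 10⁶ | depth regime (the 11/23/68 M regimes are the interesting sweep points) |
| detection curve | 0.95 · d/(d + 15 × 10⁶) | probability a true variant is detected in RNA-seq at depth d |
| TLOD log-normals | somatic (3.4, 0.8), germline (3.7, 0.8), artifact (2.1, 0.8), noise (1.6, 0.8) | class-conditional caller confidence; overlapping so the classifier's advantage is learnable but not free |

The burden rates are scaled to desk size (a real unfiltered FFPE RNA-seq
callset carries ~10× more records per sample); the *ratios* between classes,
not the absolute counts, drive the qualitative behavior. A true variant's
WES depth is drawn at a deep-exome scale, and germline records in the
matched-WES file carry non-PASS labels (what a matched-normal caller does),
while in tumor-only WES mode they are PASS with rsID/ExAC annotations so the
rule filter must catch them.

Depth enters only through detection thinning and the AD/DP draws, never
through truth: `depth_sweep` builds one truth skeleton and emits it at
several depths, and thinning is coupled — each true variant draws one
uniform *u* and is detected at depth *d* iff *u* < p(d) — so a deeper
emission detects a per-sample superset of a shallower one, deterministically.
The per-sample true TMB recorded in the truth table is the *realized*
somatic count divided by megabases, exactly.

What the simulator does **not** model: position-dependent coverage along
transcripts, expression-level heterogeneity between genes (detection is
i.i.d. across variants given depth), haplotype phasing, sequencing-center
batch effects, and caller-internal behavior (FILTER labels are drawn from
class-conditional distributions, not produced by re-running a caller).
Passing tests therefore demonstrate that the pipeline machinery is correct
and that its qualitative behavior (rules remove germline; the classifier
beats rules when artifact burden is material; concordance improves with
depth) holds under these controlled conditions — not that any particular
correlation value will be attained on real tumors.

## Numerical and interface choices

* Coordinates are 1-based (VCF) internally; BED input is converted once at
  the boundary. Chromosome names are normalized to the `chr` prefix.
* VCF I/O goes through pysam/htslib; emitted VCFs are valid 4.2 text that
  round-trips bit-exactly through the package's own reader for every field
  the pipeline consumes.
* Sorting is by (chromosome rank, position, ref, alt, sample); merging
  pooled callsets keeps per-variant origin so they can be re-aggregated per
  sample after prediction.
* Model files are single JSON documents embedding the booster, the feature
  registry and training metadata; scoring refuses a matrix whose registry
  digest differs from the model's.
* All library computation is single-threaded; the CLI's `--threads` flag is
  accepted for interface stability but results never depend on it.

## Known limitations

* The rule whitelist ambiguity (PASS in or out) is configuration, not
  resolution; assays must decide based on their caller setup.
* The simulator's artifact and noise records are exchangeable within class;
  a classifier trained on them cannot be expected to transfer to real data,
  and is not meant to — real deployments train on real paired cohorts.
* `coordinate_only` labeling ignores allele identity, so a germline SNP
  overlapping a somatic indel position would be labeled signal; at realistic
  densities this is rare, and the stricter `full_key` mode is available.
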