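# Methods

This note documents the models, conventions and numerical choices behind
`aptapanel`, and what the synthetic-data validation does and does not show.

## The measurement model

An enriched aptamer pool is sequenced once per plasma sample. Reads have the
layout `5'-primer + variable region + 3'-primer` (constant 20-nt flanks,
40-nt variable region by default). Counting collapses retained reads to unique
variable-region sequences; the per-sample multiplicity of a sequence is the
abundance signal. Sequences are handled in the DNA alphabet throughout (U is
mapped to T on input): sequencing reads cDNA, and a single alphabet avoids
silent U/T mismatches between reads, tables and motif clustering.

Read retention is deliberately conservative: both flanks must match as exact
prefix/suffix (an optional per-flank Hamming budget exists), and reads whose
trimmed region deviates from the expected length are discarded rather than
padded. Discards are tallied by reason (`no_5p`, `no_3p`, `bad_length`) so
the loss is transparent.

## Abundance filtering

Aptamers are ranked by total count (rank 1 = most abundant; ties break
lexicographically by identifier so ranks are deterministic). The number of
zero samples per aptamer, plotted against rank, characterises missingness:
zeros break log-normalisation and mark low signal-to-noise aptamers. The
analysis set is cut at a configured K (default 500). A knee finder — the rank
maximising the forward difference of the moving-average-smoothed zero curve
(window 25) — is provided as a diagnostic only; making K explicit
configuration rather than automating the visual cutoff keeps runs
reproducible. Sample-level QC summarises per-group library sizes with Tukey
1.5·IQR fences (the standard boxplot convention); flags are advisory and
nothing is excluded automatically.

## Differential selection

Counts are normalised to log2(CPM + 1). CPM removes library-size differences;
the pseudocount (default 1 on the CPM scale) resolves zeros; the log2 scale
makes the regression coefficient a log2 fold change, so the magnitude
threshold 0.25 reads as |log2 FC| ≥ 0.25. Per aptamer, OLS of abundance on an
intercept plus the two-group indicator is computed in closed form: the
coefficient is the difference of group means, its standard error uses the
pooled variance, and the two-sided p comes from the t distribution with
n_A + n_B − 2 degrees of freedom — algebraically identical to the
pooled-variance two-sample t-test, which the tests exploit as an independent
oracle. No covariates are included. Degenerate aptamers with zero residual
variance get p = 0 when the coefficient is nonzero and p = 1 otherwise (a
documented convention; they only arise in constructed data). Three-level
factors (fibrosis F0/F1–2/F3–4) are handled as pairwise contrasts on sample
subsets. Benjamini–Hochberg adjustment is applied within one contrast across
the K filtered aptamers (m = K); the selection rule is |coefficient| ≥ 0.25
AND adjusted p ≤ 0.05. Median dichotomisation contrasts (LDL, sCD163,
and similar covariates) compute the cut on the training cohort's non-missing
values, with at-or-above going to the positive level, and the fixed cut is
reused unchanged in other cohorts.

## Panel scoring and evaluation

The scoring model is deliberately deployable: center vector (training column
means of log2-CPM over panel members), unit-norm first right singular vector
of the centered training submatrix, and an orientation sign chosen so the
disease-ward training class has the higher mean score (if class means tie
exactly, the first nonzero loading component is forced positive). Columns are
not scaled to unit variance by default — log2-CPM values are already on a
common scale — though standardisation is a documented option. Applying the
model to another cohort uses the training center and loading unchanged; an
option to re-center per cohort exists because batch handling between cohorts
is genuinely open, but projection is the default since it is the only mode
that yields a transferable score.

AUC is the Mann–Whitney statistic with ties counted ½. The DeLong variance
combines the sample variances of positive and negative placement values
(computed from midranks); the 95% CI is the Wald interval auc ± 1.96·√V
clipped to [0, 1], collapsing to a point when V = 0 (perfect separation).
The implementation agrees with R pROC's `ci.auc(method="delong")` to 1e-10 on
a frozen fixture. Qualitative bands resolve boundaries upward: < 0.70
below-acceptable, [0.70, 0.80) acceptable, [0.80, 0.90) excellent, ≥ 0.90
outstanding. Wilcoxon rank-sum tests use exact enumeration when the pooled
size is ≤ 20 with no ties, else the normal approximation with tie and
continuity corrections. Evaluation tables carry one row per cohort ×
comparison × score; a comparison with an empty class becomes an N/A row with
a reason, never a dropped row. Comparator clinical scores are computed per
sample — FIB-4 = (age·AST)/(platelets·√ALT), AST/ALT — with missing inputs
propagating to missing scores, and are evaluated through the same AUC
machinery as generic columns.

## Families and MS targets

Two aptamers are linked when their longest common substring is at least the
motif threshold (default 12 nt, configurable, floor 8); families are the
connected components of this relation (single linkage: "sharing a motif" is a
pairwise relation whose closure defines the family). The implementation uses
the identity *LCS(a,b) ≥ L ⇔ a and b share an exact L-mer*: an L-mer index
discovers candidate pairs without all-pairs alignment, and a quadratic-time
LCS is computed only on discovered links to report a witness motif. Exact
substring matching (rather than degenerate or approximate motifs) is the
operational definition chosen because it is deterministic and directly
testable; clustering always runs on variable regions — constant primers would
link everything. Representatives are the most-abundant members (ties: the
lexicographically smallest sequence).

MS pull-down tables are aggregated in a fixed order: percent-of-total per
run, then mean over the triplicate, then log2 of max(mean percent, 0.01) —
the 0.01% floor keeps never-observed proteins finite on the log scale. The
primary target is the protein with the highest mean percent; a runner-up
within a log2 margin of 1.0 (within 2-fold; configurable) is reported as a
comparable secondary target. "Comparable" had to be quantified somewhere; a
2-fold window is a conservative reading of dual-binder calls.

## The synthetic-cohort generator

The generator emulates, at desk scale, the features of real pool-sequencing
data that the pipeline's behaviour depends on:

- **Heavy-tailed abundance** — per-aptamer baseline log2 abundances are i.i.d.
  normal (sd 2 by default), i.e. log-normal pool shares, reproducing a steep
  rank-abundance curve in which a top-K cut captures most of the pool.
- **Family structure** — a configured fraction of aptamers (default one half)
  is partitioned into families carrying an exact 16-nt motif at a fixed
  per-family offset.
- **Family-coherent effects** — disease effects are planted at family level
  (all members share the effect), reflecting the assumption that one family
  binds one epitope; a configured fraction of effects points down. Effects
  attach to named contrasts (steatohepatitis: MASH vs rest; fibrosis: stage
  ≥ 3) through per-sample indicators.
- **Count noise** — counts are negative binomial via the gamma–Poisson
  mixture: mean N_j·p_ij with p_ij ∝ 2^(baseline + planted effect), common
  dispersion φ (default 0.3, variance m + φm²), reducing to Poisson at φ = 0.
  Library sizes are drawn uniformly from a configured range.
- **Cohorts** — group sizes (default 40 vs 40) or exact per-(group, stage)
  counts; stage distributions and clinical covariates (age, BMI, LDL, sCD163,
  AST, ALT, platelets, metabolic syndrome) are drawn from group-dependent
  distributions with medians in the range typical of MASLD cohorts.
- **Reads** — FASTQ emission reproduces the count matrix exactly at error
  rate 0 (default, so round trips are exact); a per-base substitution mode
  exists for robustness tests.
- **MS tables** — triplicate runs per aptamer; the true target receives a
  dominant share (uniform 0.4–0.7) of total intensity, the remainder is
  Dirichlet-spread over background proteins, and replicates get multiplicative
  log-normal noise (σ = 0.5 natural-log by default).

One deliberate departure from pure randomness: the generator maintains a
global k-mer registry (k = the clustering guard length, default 12) and
resamples any candidate sequence that would share a k-mer with a different
family or singleton. Purely random 40-mers would produce a handful of
spurious cross-family 12-mer collisions per 500-sequence pool (pair collision
probability ≈ 29²·4⁻¹² ≈ 5·10⁻⁵ over ~1.25·10⁵ pairs), so without the guard
the planted partition would not be exactly recoverable and family-recovery
checks could not be sharp. The guard makes "clustering at the guard threshold
recovers the planted partition exactly" a designed property of the simulation,
not an accident of the seed.

Every generator output is a pure function of configuration and seed;
independent stages draw from independently derived generators, so running one
stage never perturbs another.

**What passing on synthetic data does not show:** the generator has no
SELEX enrichment dynamics (only the post-selection pool), no PCR or
sequencing-platform biases beyond NB dispersion, no batch effects between
cohorts, no correlated clinical covariates driving counts, and exact (not
degenerate) motifs. Calibration and recovery results on it validate the
pipeline's logic and statistics, not clinical performance on real cohorts —
cohort-specific AUCs from the original plasma data are not reproducible
without those data.

## Reference problem sizes

The validation experiments use a 500-aptamer pool with 25 families (~10
members each), 20% of families discriminative (≈10% of aptamers) at
|log2 FC| 1.0, NB dispersion 0.3, and two groups of 40 samples; DeLong
coverage uses 500 binormal replicates at true AUC 0.8 (n = 40/40); null
calibration uses 50 all-null replicates; family recovery uses the full
500-aptamer pool; MS recovery uses 20 aptamers × 20 seeds. Held-out scoring
AUCs are averaged over seeds because a single 40/40 AUC has Monte-Carlo sd
≈ 0.065 under the null. The study-shaped drivers under `analysis/` scale the
pool to 2000 aptamers over three cohorts (77/57/59 samples) with effects on
both the steatohepatitis and fibrosis contrasts.

## Known limitations

- Primer matching is exact-prefix/suffix (optional Hamming budget); no indel
  tolerance and no adapter discovery.
- Single-covariate OLS only; confounders (age, sex, cohort) are not adjusted
  for, matching the selection rule the pipeline implements.
- BH is applied per contrast; no cross-contrast multiplicity control.
- Family clustering is exact-substring single linkage; one chance collision
  in real data merges two families (raising the threshold refines the
  partition monotonically).
- The DeLong CI is Wald-type with clipping; near-boundary AUCs in small
  samples would be better served by the logit-scale option.
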