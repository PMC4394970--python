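# Methods

This note documents the models, conventions and numerical choices
behind each stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Reporter-ion quantification

**Model.** Within one 4-plex run, each protein's reporter intensity
in channel *c* is treated as (protein abundance in the pooled group
labelled by *c*) × (channel-specific efficiency) × multiplicative
noise. Channel efficiencies are nuisance parameters; they are
removed by median-ratio normalization: every channel is rescaled so
that the median over proteins of its ratio to the reference channel
(the channel carrying the healthy-control pool, conventionally
label 114) is 1. This is the standard robust choice for reporter
ions; it assumes the median protein is unchanged between groups, is
idempotent, and is invariant to rescaling any single channel.

**Ratios and calls.** Per run, the comparison ratio X:Y is the
normalized intensity of group X's channel over group Y's. Two runs
with swapped channel→group assignments control for label bias; the
reported ratio is the arithmetic mean of the two per-run ratios (a
geometric mean is available via `ratio_average="geometric"` but is
not the default, since the averaging convention for the reported
tables is a plain mean). Calls use inclusive thresholds: up at
ratio ≥ 1.5, down at ≤ 0.67. A protein is carcinoma-upregulated
when up in all three of R:H, R:C, R:M. Proteins quantified in only
one run are carried with their single-run values and flagged
(`runs_present = 1`).

## Differential expression

The test is Welch's unequal-variance t on log2(x + 1); the log
transform matches the multiplicative error structure of RPKM/RPM
data and the +1 offset keeps zeros finite. Mann-Whitney U is
available as a configured alternative for heavy-tailed data.
Fold change is always the plain ratio of raw group means,
optionally stabilized with a pseudocount (default 0; a plain ratio
reproduces published fold changes computed from printed group
means). Features with zero variance in both groups are assigned
p = 1. A feature "passes" when both the fold-change rule
(FC ≥ cutoff or ≤ 1/cutoff, default cutoff 2) and p ≤ 0.01 hold.
Group summaries report SD with the n−1 denominator and
SEM = SD/√n — the convention consistent with published SEM columns
(e.g. SEM 1.0893 for SD 6.0650 at n = 31).

The stage-trend statistic is the Spearman correlation between
per-sample expression and the group's ordinal rank
(normal = 0, T1..T4 = 1..4), with a two-sided p-value from a
seeded permutation null (default 10,000 permutations). A perfect
statistic of 1 is attainable only when the rank variable has no
ties, i.e. one sample per ordered group; with multiple samples per
group the statistic is bounded below 1 by the tied ranks. Flat
profiles return (0, 1) by definition rather than erroring.

## Clustering

Rows are median-centered (each gene's across-sample median
subtracted), so profiles are compared by shape; the operation is
idempotent. Clustering is agglomerative with centered-Pearson
distance (1 − r) and unweighted average linkage (UPGMA), the
conventions of the classic Cluster 3.0 defaults. Determinism is
guaranteed by an explicit tie rule: among candidate merges at the
minimal distance, the pair containing the lowest original item
index wins, then the lowest index on the other side; the left child
of a merge is the cluster with the smaller minimum original index.
The implementation updates distances by the size-weighted
Lance-Williams recurrence, which is algebraically identical to the
mean of original pairwise distances; the test suite cross-checks
the full merge sequence against a naive O(n³) oracle that
recomputes distances from scratch. Constant rows are rejected under
correlation distance (undefined r) with the offending item named.
CDT/GTR/ATR output encodes original row/column indices in the
GENE*i*X / ARRY*i*X labels, so the module's reader recovers the
trees and the original matrix exactly.

## Seed sites and functional pairs

Site types follow the TargetScan conventions on the UTR sense
strand: 7mer-m8 = reverse complement of mature bases 2–8; 8mer =
7mer-m8 followed by a literal A; 6mer = reverse complement of bases
2–7; 7mer-A1 = 6mer followed by A. The trailing A is a literal
adenosine requirement, not complementarity to mature base 1. U and
T are interchangeable (all sequences normalized to DNA); N never
matches (conservative for ambiguous bases); positions are 0-based,
half-open. Longest-match precedence applies at a locus: a
weaker-type match wholly contained in a reported stronger site's
interval is suppressed, so one physical site is never counted
twice. Context scores, conservation and non-canonical site types
are out of scope.

Functional pairs apply three criteria: (i) opposite differential
directions for the miRNA family and the candidate genes (default:
down-regulated families against up-regulated genes), (ii) a
predicted seed-site interaction of at least the configured minimum
type (default 7mer-A1), and (iii) target enrichment in the selected
gene list by the one-sided upper-tail hypergeometric test,
evaluated through the log-space survival function. The background
defaults to the detected-gene universe of the expression matrix
supplied by the caller — not a fixed genome-wide constant — because
enrichment against undetected genes conflates detection with
regulation; it is configurable. Families are tested independently
with BH-FDR reported alongside raw p; report rows order by
ascending p, then descending overlap, then name.

## Group statistics

One-way ANOVA is computed from sufficient statistics
(grand mean = Σnᵢmᵢ/Σnᵢ, SS_between = Σnᵢ(mᵢ−m̄)²,
SS_within = Σ(nᵢ−1)sᵢ²), so it applies equally to raw samples and
to published (n, mean, SD) tables, and the two routes agree
exactly by construction. The degenerate all-equal zero-variance
case returns F = 0, p = 1. Fisher LSD post-hoc comparisons are
unadjusted two-sided t-tests using the pooled within-group mean
square and the omnibus residual df; this convention reproduces all
six published footnote p-values from the corresponding summary
tables at three decimals. Chi-square is Pearson's without
continuity correction, df = (r−1)(c−1).

Two discrepancies with published values are documented rather than
"fixed": the cohort-age ANOVA from printed summaries gives
F = 6.269 where 6.272 was printed — perturbing the printed means/SDs
within half their printed precision spans F ∈ [6.260, 6.277], so the
printed value reflects unrounded raw data that is not available;
and the gender contingency statistic is 15.07 by Pearson (15.73 by
likelihood ratio) against a printed 14.92, whose exact variant is
not stated. Both are reported as computed.

## Synthetic data

The generators emulate the *structure* of the study inputs, with
defaults set to the cohort's stated conditions: a stage-group
layout of 31 normal / 197 T1 / 49 T2 / 162 T3 / 6 T4 samples,
log-normal expression with gene baselines uniform on log2 ∈ [2, 7]
and log2-noise SD 1 (a realistic RPKM-scale dispersion), planted
log2 effects applied in every tumor group, and monotone per-stage
increments for designated trend genes. UTRs are uniform random
ACGT with 8mer sites planted at stated fractions of up-regulated
and background genes at non-overlapping recorded positions;
accidental background matches are deliberately left unrecorded so
detection is tested from sequence alone. Reporter runs draw
per-run protein abundances log-normally, with per-channel
efficiency factors and per-cell multiplicative noise at given CVs;
unnamed proteins default to ratio 1 so the median-ratio assumption
holds. IOD tables draw normal samples per group; exact mode
affinely rescales each group to hit the requested (mean, SD) to
machine precision, letting printed-table F values reproduce from
raw samples.

What the generators do **not** emulate: count-level sampling noise
and mean-variance coupling of real RNA-seq, correlated genes and
batch structure, peptide-level missingness and ratio compression in
real iTRAQ data, and non-normal IOD distributions. Passing
recovery tests therefore demonstrates correctness of the
algorithms under the stated generative model, not performance on
real cohorts.

Test and acceptance problem sizes are deliberately desk-scale
choices: 2,000 genes with 100 planted effects at 30 vs 30 samples
for differential-expression checks, 3,000-gene backgrounds with
300 selected genes for enrichment recovery, 500-protein runs for
ratio recovery, 12-item matrices for clustering oracle comparison.
These sizes give stable statistics (binomial error on recovery
rates well inside the asserted bands) while keeping the full suite
fast.

## Numerical choices and degenerate inputs

* Floats are serialized via `repr` and parsed with pandas'
  round-trip parser, so every writer/reader pair is bit-exact.
* Inclusive threshold comparisons throughout (≥ 1.5, ≤ 0.67,
  p ≤ 0.01): boundary values count as calls.
* Hypergeometric p-values come from the survival function in log
  space; k = 0 returns exactly 1.
* Permutation p-values use the add-one estimator
  (hits + 1)/(B + 1), never exactly zero.
* Zero-variance features, flat trend profiles, empty selections and
  zero-count gene sets all degrade to defined neutral outputs
  (p = 1, statistic 0, skipped-with-notice) rather than errors;
  malformed files, inconsistent annotations, non-positive reporter
  intensities and invalid configs raise with the offending item
  named.

## Limitations

* The enrichment background is caller-defined; published target
  counts based on proprietary annotation databases are not
  reproducible and are treated as schema examples only.
* Gene-ontology term content is user-supplied via GMT; no
  annotation database ships with the package.
* The DE test operates on normalized abundance matrices (RPKM/RPM);
  count-model methods are out of scope.
* Only sense-strand 3′UTR seed sites are considered; no
  thermodynamics or conservation.
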