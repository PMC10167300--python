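# Methods

## Nomenclature and comparison rules

HLA alleles are parsed as `LOCUS*F1[:F2[:F3[:F4]]][suffix]` with digits
kept verbatim (leading zeros significant), an optional `HLA-` prefix and
case normalized away, and the expression suffixes N/L/S/C/A/Q retained.
G/P group names are rejected outright: resolving them needs an IMGT
database release, which is out of scope, and silently truncating one
would misstate the call's resolution.

Matching at field level *f* compares the full field prefix through *f*
and, by default, requires **both** alleles to be typed to at least *f*
fields (the *strict depth rule*). A 2-field call carries no claim about
field 3; crediting it at field 3 would inflate deep-field accuracy for
tools that never emit deep calls. The relaxed rule (agreement over the
fields both populate) is available via `require_full_depth=False` for
callers who prefer it.

## Success, accuracy, agreement

Predicted alleles are assigned one-to-one to ground-truth allele slots by
maximum-cardinality matching (exhaustive enumeration; genotypes are tiny).
The tally is:

- correct — matched predictions;
- incorrect — every unmatched prediction (it occupies a truth slot, or is
  a surplus call);
- absent — truth slots left with no prediction at all.

The tally sums to max(#pred, #truth), so a diploid locus scores accuracy
in {0, 0.5, 1} — one wrong prediction paired against one truth allele is
*incorrect*, not incorrect **and** absent. A homozygous truth {X, X} met
by a single {X} is one correct + one absent (accuracy 0.5): the matching
is over allele slots, of which a diploid locus always has two.

Success is undefined (not zero) when a tool called nothing at the locus;
undefined values are excluded from means rather than imputed. Summaries
are unweighted means over samples per genotyper × locus × field; loci a
genotyper never assesses are omitted, not scored zero (an
opt-in `score_unassessed_zero` mode exists for across-loci averages).
Agreement between two predictions is accuracy with the second prediction
as truth; two empty calls yield NaN, since there is nothing to compare.

## DRB345 copy number

Features are per-sample ratios of DRB3/4/5-mapped to DRB1-mapped reads;
a sample with zero DRB1 reads is flagged un-callable, never pseudocounted.
One kNN classifier per paralog (1-D feature, absolute-difference metric)
is the default, reflecting the per-paralog phrasing of the read-ratio
approach; a joint 3-feature mode is available. k is tuned over
{3, 5, 7, 9, 11} by stratified cross-validation (10 folds requested,
automatically reduced to the smallest class count when a class is rare)
on a 70% training split; the 30% holdout is scored with the Hand & Till
multiclass AUC, computed as the average over unordered class pairs of the
two one-vs-one rank-sum AUCs (ties counted half). Vote ties at prediction
time break toward the lower copy number — conservative against the
false-positive paralog calls that motivate the whole exercise. Predicted
vectors summing above 2 are reported as-is with a `biologically_valid`
flag; no automatic repair is attempted.

Copy-number similarity to truth is 1 − Manhattan/6, where 6 (two-allele
disagreement at each of three paralogs) is the maximum possible distance.

Filtering keeps the top *n* ranked alleles per paralog, *n* the predicted
copy number. The rank must come from the upstream genotyper; if a
truncation is needed and no ranking was supplied, the call errors rather
than guess.

## Composite genotyping

Selector instances are one per sample × locus × field; features are the
one-hot locus, the one-hot field level, and one availability bit per
genotyper ("produced a non-empty call with at least one allele typed to
this depth"). The label is the available genotyper with the highest
accuracy there; ties break by the fixed priority arcasHLA > OptiType >
PHLAT > HLAminer (fastest first), configurable. Labeling is per
sample × locus × field — the only granularity consistent with a feature
set that includes locus and field.

The tree (max depth 8, min leaf 5, defaults chosen to keep the model
interpretable at the feature granularity) is pruned by cross-validated
cost-complexity over its own alpha path on the 70% training split.
Holdout accuracy and Hand & Till AUC are recorded in the model metadata.
At assembly time the predicted genotyper is masked to available ones; if
the tree's probability mass sits on unavailable tools, the composite
falls back down the priority order. A slot where no tool called anything
stays absent (and scores accuracy 0 downstream). Composite calls are
truncated to the slot's field level, one output callset per field.

## ASE effect size

For one cell with biallelic counts (a, b), a against the reference
allele: total T = a + b, expected counts e = T/2 per allele, odds ratio
(a·e)/(b·e) = a/b, log-odds ln(a/b), variance 1/a + 1/b + 1/e + 1/e (the
standard 2×2 log-odds variance; the observed-vs-expected odds-ratio
variance is not spelled out in the literature this mirrors, so the 2×2
form is assumed). When any table cell is zero, 0.5 is added to all four
cells first (Haldane–Anscombe). Cells with zero total reads are excluded;
there is deliberately no further depth filter — low-count cells are
down-weighted by their large variances instead.

Pooling is DerSimonian–Laird: τ² = max(0, (Q − (n−1))/C) with
C = Σw − Σw²/Σw, random-effects weights 1/(v + τ²), SE = (Σw*)^{−1/2}.

Reference-allele convention: per cell, the dominant allele makes every
log-odds nonnegative but can flip alleles between cells, collapsing the
summary into a pure imbalance magnitude. The default *group* convention
references all cells of a group against the allele with the higher total
count across the group, preserving direction; the per-cell convention is
available behind `convention="cell"`. Neither is asserted as the only
defensible choice; the direction-preserving one is the default because a
signed effect is more useful downstream.

R² between genotyper-derived and truth-derived pooled log-odds is the
squared Pearson correlation over paired sample × group summaries
(minimum 3 pairs).

## Entropy profiles

Per-column Shannon entropy over A/C/G/T frequencies only; gaps are
missing data (published HLA references often cover partial exons), N and
other IUPAC ambiguity codes are likewise excluded, and an all-gap column
is NaN, not 0. The rolling mean (default window 100 positions) is
centered — the window's laterality is not dictated by anything upstream,
and a centered window keeps features aligned with their coordinates —
with shrunken partial windows at the edges so the profile length equals
the alignment length.

## Synthetic data

The generator's defaults are the study conditions the tests run under:

- **Cohort** (default n = 150): diploid genotypes at A, B, C, DRB1, DQA1,
  DQB1, DPA1, DPB1 from frequency-weighted pools of 3-field synthetic
  allele names (Dirichlet-drawn frequencies, allele groups 90–99 so no
  real IMGT name is implied). Each of the two DRB1 haplotypes carries at
  most one linked paralog allele via a hard-coded DRB1-group → {none,
  DRB3, DRB4, DRB5} table. That table is a simplified emulation of the
  real linkage structure — enough to guarantee drb3+drb4+drb5 ≤ 2 — and
  **not** a population-genetics model of real haplotype frequencies.
- **Callsets**: per allele, dropout (per-locus overridable) then per-field
  substitution; an error at field *f* re-draws field *f* and all deeper
  fields (an upstream mistyping at a shallow field makes deeper fields
  noise). Calls are truncated to each tool's field depth. Spurious DRB345
  alleles are appended after true-derived ones, giving a meaningful rank
  order for top-n filtering. The four default tool profiles span the
  quality range seen across real genotypers (a class-II-strong tool with
  frequent spurious DRB calls, an accurate class-I-only tool, a mid-range
  tool without DP, and a noisy tool).
- **Read counts**: DRB1 reads gamma-Poisson with mean 200 and dispersion
  0.3; paralog reads = DRB1 × (copies × 0.45 + N(0, 0.05)) clipped at 0 —
  class-conditional ratio means {0, 0.45, 0.9}, σ ≈ 0.05.
- **Cell counts**: per cell θ ~ N(μ, τ²), T ~ 1 + Poisson(mean − 1),
  allele-1 count ~ Binomial(T, logistic(θ)); defaults μ = ln 3, τ² = 0,
  200 cells, ~20 reads per cell.
- **Alignment**: a 600-column toy with a fully variable 200-column 5'
  block and a conserved remainder (some sequences gapped at the 3' end),
  echoing the concentration of real HLA polymorphism toward the 5' end.

All stages draw from independent `SeedSequence` children of the single
config seed, so identical config + seed reproduces byte-identical files.

What the generator does **not** emulate: real allele frequencies and
linkage disequilibrium, sequencing-platform coverage bias, read-level
error profiles, genotyper-specific failure modes (e.g. depth-dependent
dropout), or cell-type structure in ASE. Passing recovery tests therefore
demonstrates correctness of the estimators under their stated models, not
expected performance on any real cohort.

## Problem sizes and numerical choices

Recovery tests use cohorts of 200–300 samples, 200-cell ASE groups, and
3-field truth — sizes at which the planted signals are comfortably
identifiable while the full suite stays quick. Exhaustive oracles
(assignment enumeration, pairwise rank-sum AUC) run on ≤ 8-sample toys.
Train/test splits are stratified where class counts allow and plain
otherwise; a `train_fraction` of 1.0 is rejected because every model here
reports holdout quality. Probability ties in kNN voting resolve to the
lower copy number, tree-selector ties to the fixed priority order; both
are deterministic under a fixed seed.

## Known limitations

- Accuracy semantics treat each locus independently; no cross-locus
  haplotype consistency is enforced beyond the DRB copy-number filter.
- The kNN holdout AUC on well-separated synthetic ratios saturates at
  1.0; it exercises the machinery, not the difficulty of real read-ratio
  distributions.
- The selector can only be as good as its features: genotypers whose
  quality varies within a locus × field × availability stratum are
  indistinguishable to it.
- `compare_ase_to_truth` assumes paired summaries are aligned by the
  caller; no joining logic is provided.
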