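# Methods

This note documents the statistical model behind `coralstress`, the choices
made where the analysis design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Experimental design model

The pipeline assumes a factorial layout: `S` coral species × 2 treatments
(ambient, stress) × `T` timepoints × `k` replicate tanks, with one fragment
per species per tank per timepoint (the default emulates S = 3, T = 3,
k = 3, so n = 3 per treatment cell). One species may undergo polyp bail-out
— acute tissue loss under stress — and then contributes no stress samples
at the final timepoint; every stage tolerates that missing cell, and the
conservation logic only requires each species to be callable at one or more
post-baseline timepoints. TP0 (sampled before the temperature ramp) is
treated as a baseline that captures tank effects, not a stress contrast,
and is excluded from conservation collapsing by default.

Tank is *not* modeled as a random effect: with three tanks per treatment
and one fragment per tank, tank and biological replicate are confounded,
and the per-cell t-tests treat tanks as independent replicates. This is a
known limitation, and the reason the baseline timepoint is quarantined.

## Cleaning cascade

Order of operations, each recorded in the matrix lineage:

1. **Identity filters** (strict): unique peptides > 1, razor + unique > 1,
   group q-value < 0.01, no contaminant or decoy flag, requested database
   fraction only. The filter returns a per-criterion tally so losses are
   attributable.
2. **Cell-density normalization** (symbiont fraction only, optional): raw
   intensities divided by cell abundance (cells ml⁻¹ cm⁻²) per sample,
   *before* the floor — the abundance is a raw-scale scaling factor, and
   dividing log2 values would change the statistic. Samples with zero or
   missing abundance are excluded with a warning.
3. **Intensity floor 5** (strict "below"): raw values < 5 are set to the
   absent state. Absent is NaN throughout; zero never encodes missingness.
4. **log2 transform.**
5. **Outlier flagging** (advisory): per-sample completeness and distance
   from the PCA score centroid (features complete in all samples,
   column-centered, first two components). A sample is flagged when its
   distance exceeds the median by more than `k = 3` MAD-scaled deviations.
   Flagging never removes samples — removal is an explicit, logged call
   with sample ids, because this judgment is made per study by a human.
6. **Presence filter**: features present in ≥ 80% of the species' retained
   samples stay (inclusive ≥, evaluated per species after floor and sample
   drops). The complementary "missing from > 20%" phrasing is a removal
   rule for the same threshold; the inclusive presence form is what is
   implemented, with the threshold configurable.
7. **Imputation**: missForest-style. Features are variables; each feature
   with missing cells is regressed on all others with a random forest
   (ntree = 100), visiting features from most to least complete, cycling
   until the normalized squared difference between successive imputed
   matrices first increases (the round before the increase is returned) or
   `maxiter = 10` rounds. Seeded (default 124); per-column seeds derive
   from one `RandomState`, so results are bit-reproducible. Observed cells
   are never altered. The contract is algorithmic equivalence with
   reference forest imputers, not numerical identity: tree ensembles
   interpolate on observed support, so resolution is bounded by the spacing
   of observed values (the duplicate-donor test quantifies this at a
   replicate sd of 0.3 log2 units).
8. **Group-median normalization**: within each treatment × timepoint group,
   each sample is shifted additively on the log2 scale so all sample
   medians equal the group's grand median of sample medians (equivalent to
   a multiplicative per-sample factor on the raw scale). The anchor is a
   free choice — any common target removes per-sample offsets — and the
   within-group grand median keeps group locations untouched, which
   matters because between-group differences are the later signal.

## Differential abundance

`FC = mean(log2 stress) − mean(log2 ambient)` — the difference of log2
group means, so planted multiplicative effects are recovered directly.
Significance is a two-sided t-test: pooled-variance for proteins (n = 3 per
group), Welch for metabolites (n = 6 per group). A variance guard of 1e-12
keeps zero-spread groups finite; such rows are flagged. Benjamini–Hochberg
adjustment is computed across the features of each contrast and always
reported. Protein *classification* uses the unadjusted p: at n = 3 with
high biological variance no protein survives FDR control, so the
feature-level calls are deliberately liberal and the pathway vote supplies
the error-rate backstop (a coordinated ≥ 5% of a pathway moving in one
direction is unlikely under the null, which the recovery benchmark
quantifies). Metabolite classification uses the adjusted p. Classification
thresholds (|FC| > 0.5, p < 0.05) are strict inequalities; the pathway vote
threshold (≥ 5%) is inclusive.

## Pathway votes and conservation

The vote denominator is the number of *detected* proteins of a pathway —
annotated members present in that species' cleaned matrix — not the full
genomic roster; with single-digit-percent proteome coverage a roster
denominator would make the 5% threshold unreachable. A feature whose KO
sits under several B-level headings counts once in each pathway. Pathways
need strictly > 10 detected proteins in every species to be retained.

Conservation collapses each species' post-baseline calls into a direction
set (mixed contributes both directions, stable none), then:
all species exactly `{up}` → conserved_up; all exactly `{down}` →
conserved_down; any up/down opposition across or within species →
divergent; a single direction present in only a subset of species →
species_specific (the one-responder case is its special case); nothing
anywhere → none. These five categories partition all call sets.

## Physiology

Surface area: OLS of known standard areas on wax mass; a fragment's area is
predicted from its pre/post dipping mass difference. Cell density: mean of
8 hemocytometer quadrat counts × 1e4 cells/ml (standard Neubauer large-
square conversion; the chamber constant is configurable because chamber
math varies); abundance divides by surface area, keeping the
cells ml⁻¹ cm⁻² unit, and is log2-transformed for statistics. ANOVA is
one-way over the combined treatment × timepoint factor (df_between =
groups − 1, so 5 for a complete species and 3 after bail-out); Tukey HSD
runs over the full pairwise family and the ambient-vs-stress pair within
each timepoint is *extracted, not refit*, preserving the full-family
studentized-range adjustment. Shapiro–Wilk (on residuals) and Levene checks
are advisory: failures warn and the analysis proceeds. Physiology fold
changes use raw-scale group means then log2; percent change is
`100·(mean_ambient − mean_stress)/mean_ambient`, positive for a decline.

## Synthetic data: what it emulates, and what it does not

The generator draws per-feature baselines `N(20, 2)` on the log2 scale,
replicate noise `N(0, 0.3)` (a typical label-free between-replicate sd, and
the sd at which the recovery benchmarks are defined), and applies planted
effects as `2^shift` to the stress samples of the targeted species ×
timepoint. Dropout is intensity-dependent by default (logistic in log2
intensity, rescaled to the requested overall rate, default 10%) because an
intensity floor implies left-censoring; completely-at-random dropout is
available. Peptide-count metadata (unique ~ geometric on {1, 2, ...},
razor = unique + non-negative excess), q-values (85% of targets below 0.01,
15% in [0.01, 0.05), decoys uniform on [0, 1]), and contaminant/decoy rows
exist so each identity filter has non-trivial action at roughly the
retention fraction real studies report. Each output table uses an RNG
stream derived from the master seed by a fixed offset, so generating one
table never perturbs another.

Not emulated: correlated features (co-regulation), tank batch effects,
match-between-runs artifacts, peptide-level evidence, retention times, or
ITS2 community structure. Passing recovery benchmarks therefore shows the
pipeline's statistics are calibrated and its bookkeeping exact under the
declared noise model — not that real coral data meet that model.

## Benchmark problem sizes

The repeated-run benchmarks are sized to be informative yet quick: the
conserved-pathway recovery ensemble uses 200 proteins (focal pathway 100
members, ~half detected after filtering), complete observations (the
imputer is then the identity), and 100 seeded runs in the test suite (25 in
the acceptance script); a separate single run includes 10% dropout with
forest imputation in the loop (ntree = 30, 2 rounds) to exercise the full
pathology path. Null calibration and planted-shift recovery use 2000
features at n = 3 per group. With the 5%-vote threshold and unadjusted
feature tests, spurious "mixed" pathway calls become likely when pathways
are small (one false positive among ≤ 20 detected members already trips the
5% bar) — the benchmark's focal pathway is large enough that ≥ 3 false
positives in one direction would be needed, which is what makes ≥ 95%
end-to-end recovery achievable. The default-study pathways are smaller, so
its conservation table occasionally shows a planted pathway as divergent;
that is the metric's real behavior under sparse coverage, not a defect.

## Numerical conventions

Strict vs. inclusive boundaries follow the rules above exactly. All
tolerance-sensitive identities hold tightly: two-group ANOVA equals the
pooled t-test (F = t², same p) to 1e-10; median normalization leaves
within-group median spread below 1e-9; BH adjustment matches the textbook
step-up with running minimum to 1e-12 and is permutation-stable. Degenerate
inputs fail loudly and specifically: features with < 2 observed values name
themselves before imputation, constant data make normality checks
not-applicable rather than failing, empty normalization groups warn and are
skipped, and zero-abundance samples are excluded from cell-density
normalization with a warning.
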