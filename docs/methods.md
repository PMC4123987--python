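# Methods

## Similarity score and empirical null

Profiles are β-value vectors over the probes that are complete (no
missing value in any sample of the analysis set); incomplete probes are
dropped once, up front, mirroring array practice. The
methylation-similarity score of two profiles is the inverse of their
Manhattan (L1) distance. L1 on β values weights every probe equally and
is insensitive to a handful of extreme probes in a way L2 is not; the
inverse turns a dissimilarity into a similarity so that "higher = more
clonal".

The null model for "unrelated tumors in this cohort" is empirical: all
ordered cross combinations PT_i × REC_j, i ≠ j, of the cohort's m
complete pairs — n = m(m−1) scores. Within-role pairs (PT × PT,
REC × REC) are reported separately in the distance-group comparison and
are not pooled into the null. The threshold τ is the order statistic at
rank ⌈0.95·n⌉ of the sorted null scores — a plain empirical quantile with
no interpolation, so the procedure is reproducible to the bit across
software. A matched pair is called TR iff MS > τ, strictly; a score
exactly at τ is NP. Two identical profiles have infinite similarity;
this is returned as an explicit `inf` sentinel and always classified TR.

Caveats of this design, visible in both real and simulated data: the
null scores are dependent (each sample enters m−1 of them), so τ is an
estimate with non-trivial variance at m = 17; and when a fraction of the
cohort's recurrences is genuinely clonal, their genome-wide drift also
inflates their distance to every *unrelated* primary, pulling the null
down slightly and making the effective false-TR rate of matched
independent pairs a little above the nominal 5%.

## Statistical tests

*Paired signed-rank.* Per probe, recurrence-minus-primary differences
across pairs; zero differences are dropped (Wilcoxon's convention).
For n ≤ 25 informative pairs the exact two-sided p-value is computed by
dynamic programming over the doubled midranks (exact also under ties);
above that, the normal approximation with continuity and tie correction.
Two-sided p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)), capped at 1. The exact path
is cross-checked in the tests against full 2ⁿ enumeration.

*Unpaired rank-sum.* Mann–Whitney, exact for small tie-free groups,
otherwise asymptotic with tie and continuity correction (scipy).

*Multiplicity.* Benjamini–Hochberg step-up (statsmodels), checked
against the direct min-formula. "Significant at 5% FDR" is strict:
q < 0.05. DMP tables are ranked by adjusted p, then |Δβ| descending
(Δβ = mean recurrence-minus-primary difference on the raw β scale), then
probe id — a fully deterministic ordering.

*Discrimination null.* A pair-level random guesser is Binomial(n, ½);
the reported p is the one-sided tail P(X ≥ n_correct). Pair-level
scoring (both held-out samples correct) is primary; note its chance
level is ¼, not ½, so the per-sample accuracy is also reported.

*Concordance.* Agreement between two TR/NP label columns over pairs
where both are present, with a two-sided Fisher exact test on the 2×2
cross-tabulation.

## Supervised discrimination

A linear SVM separates primary from recurrence profiles under
leave-pair-out cross-validation: both samples of one patient are held
out per fold, so no patient contributes to both sides of a split.
Probe filtering (top-k by the paired signed-rank test) and the margin
parameter C (inner leave-pair-out over {10⁻², …, 10²}, ties resolved to
the smallest C) are recomputed from training pairs only. Features are
filtered once per outer fold and shared by the inner folds — selection
still never sees the held-out pair. β values are used unscaled (they
are already commensurate, in [0, 1]).

## Clustering and adjacency

Complete-linkage agglomerative clustering on pairwise Manhattan
distances (scipy). "A matched pair clusters together" is
operationalized as the two samples being each other's direct merge
partner — a two-leaf clade — which is deterministic and matches what one
reads off a dendrogram. Dendrograms are exported as Newick with merge
heights as cumulative branch lengths.

## Clinical rules

NP iff any trigger fires: recurrence ≥ 4 cm from the primary; distinct
histological type (a mixed ductal-lobular tumor is compatible with
either component); lower grade in the recurrence; or gain (− → +) of ER
or PR. Receptor *loss* and grade *increase* are compatible with
regrowth of a treated tumor and do not trigger; HER2 is not a hormonal
receptor and is ignored. Missing fields never fire a trigger, so added
information can only add triggers (NA-monotonicity, property-tested); a
pair with no usable feature at all is flagged indeterminate. This
operationalization reproduces all 17 printed clinical labels of the
packaged table and is the only reading we found that does.

## Survival

Kaplan–Meier product-limit curves with right-censoring; 5-year survival
is read off the step function by right-continuity. Two-group log-rank
with hypergeometric variance; Cox partial likelihood (lifelines, Efron
tie handling — simulated times are continuous, where Efron and Breslow
coincide) for crude and age/grade/ER-adjusted hazard ratios, with
explicit failure on non-convergence or a constant group indicator.
Metastasis-free survival is clocked from recurrence diagnosis; the time
origin is a convention, kept configurable by passing whichever time
column the caller prefers.

## Synthetic cohorts

The generator emulates the statistical structure the analysis needs, not
array chemistry:

- **Baseline**: each probe belongs permanently to a low (β ≈ 0.10–0.15)
  or high (β ≈ 0.85–0.90) methylation component — the bimodality of
  CpG-island vs non-island probes. Per-sample measurement noise is
  Gaussian, sd 0.015, clipped to [0, 1].
- **Tumors**: a fraction a = 0.10 of probes (fresh per tumor) shifts
  away from its component — low probes up (hypermethylation), high
  probes down (hypomethylation) — by Uniform(0.2, 0.4). Directed shifts
  keep clipping inert so E[distance to baseline] = n·a·E|shift| holds,
  which the tests exploit.
- **Clonal pairs**: the recurrence is the primary's tumor profile plus
  independent per-probe Gaussian drift with E|Δβ| = d (default
  d = 0.035), plus, in metastasis-like cohorts, a progression signature:
  a fixed signed effect at k designated probes. Non-clonal pairs are
  independent tumors on the same baseline.
- **Copy-number surrogate**: tumors carry small breakpoint sets drawn
  from a weighted locus universe; clonal recurrences retain 80% of the
  primary's breakpoints. The similarity is a rarity-weighted Jaccard —
  a deliberately simplified, synthetic stand-in for breakpoint-based
  partial-identity scoring, used only to give simulated cohorts a second
  score to correlate against.
- **Survival**: exponential event times with a configurable TR/NP hazard
  ratio and independent Uniform(0, 12 y) censoring.

Defaults were chosen so that at the array's 27,573 complete probes the
simulated MS scores land where the score lives on real profiles — clonal
pairs near 9×10⁻⁴, unrelated pairs near 5×10⁻⁴ (the closed forms:
clonal distance ≈ n·E|drift + noise|, unrelated ≈ n·(2a(1−a)E|shift| +
a²E|s₁−s₂| + E|noise|)). Everything is deterministic given the config
seed, including the probe-component assignment, which is cohort-level
state rather than sample-level.

What the generator does *not* model: batch and spatial array artifacts,
probe-specific error, inter-individual baseline variation (all patients
share component means, so unrelated samples are more exchangeable than
in reality), tumor purity, and subclonal structure. Passing recovery
tests therefore demonstrate the pipeline's correctness under its own
assumptions, not clinical performance.

## Problem sizes and experiment design

The packaged printed tables are analyzed at full scale (they are tiny).
Simulation experiments run at reduced probe counts (200–5,000 probes;
distances concentrate like 1/√n, so nothing qualitative changes) and
state their configs in the tests:

- *DMP recovery*: 20 pairs, 4,000 probes, a 50-probe signature of effect
  0.06 ≈ 1.2× the within-pair difference sd — chosen so the screen sits
  in the realistic "most but not quite all of the signature, plus an
  occasional BH false positive" regime (mean ≈ 46 of 50). With a much
  larger effect the count is exactly 50 plus ~2.5 expected BH false
  positives, which says nothing about power. Counts are averaged over 3
  cohorts; null cohorts (no signature) are checked over 20 seeds for FDR
  control.
- *MS parameter recovery*: sensitivity/specificity are means over 20
  cohorts of 17 pairs at small drift (d = 0.005) against a wide
  inter-individual spread (a = 0.2) — the regime the score is meant for.
  Single 17-pair cohorts have only ~9 independent pairs, so one
  expected-level false TR already costs 11 points of specificity; the
  mean over cohorts estimates the operating characteristic itself.
  Sensitivity degrades monotonically as d grows (checked over a d-grid).
- *Cox recovery*: true HR 2 at 500 subjects, geometric mean over 5
  replicates. *Log-rank calibration*: rejection rate at α = 0.05 over
  200 null simulations.

## Known limitations

- The printed PT/CL table has 10 rows though the accompanying text
  counts 11 pairs; the package carries what is printed and surfaces the
  discrepancy rather than inventing a row.
- The feasible-threshold interval for the printed labels is
  [6.11, 6.64)×10⁻⁴ under the strict "MS > τ" rule: closed at the top NP
  score (a score equal to τ is NP) and open at the bottom TR score.
- The empirical-null threshold is cohort-relative; scores and thresholds
  are not transferable across cohorts or platforms.
- PIS values are consumed as inputs; the breakpoint algorithm behind
  them is out of scope and the synthetic surrogate is not a
  reimplementation of it.
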