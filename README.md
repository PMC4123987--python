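# methclonal

Methylome-based clonality analysis of breast primary tumors and their
locoregional recurrences.

## The problem

After breast-conserving therapy, an ipsilateral local recurrence (LR) can
be either a **true recurrence** (TR) — regrowth of treatment-resistant
cells from the primary tumor (PT) — or a **new primary** (NP), an
independent de-novo cancer. The distinction matters clinically (NP carry a
better prognosis and call for different treatment), but rule-based clinical
criteria are fragile. Because DNA methylation is mitotically heritable,
two clonally related tumors should retain similar genome-wide methylation
profiles; this package implements that idea as a quantitative classifier
and everything needed to evaluate it.

Tumors are profiled as β-value vectors (per-CpG methylation fractions,
β ∈ [0, 1], 27,578 array probes). For two profiles x, y the
**methylation-similarity score** is

    MS(x, y) = 1 / Σ_p |x_p − y_p|

the inverse Manhattan distance over the complete probes. Within a cohort
of m matched PT/recurrence pairs, an empirical null is built from all
m(m−1) unrelated PT_i × REC_j combinations, and the decision threshold τ
is the 95% empirical quantile (the order statistic at rank ⌈0.95·n⌉) of
those null scores. A matched pair is called TR exactly when its MS score
is strictly above τ.

Around the score the package provides the full analysis pipeline:

- **io_annotations** (`methclonal.io`) — β-matrix and annotation I/O,
  complete-probe filtering, and packaged transcriptions of the study's
  printed clinico-histological and score tables (17 PT/LR, 10 PT/CL and
  20 PT/AM pairs).
- **synthetic_cohort** (`methclonal.simulate`) — cohorts with known clonal
  structure: bimodal normal baselines, sparse tumor alterations, clonal
  vs independent matched pairs, an optional progression signature,
  breakpoint surrogates and survival times.
- **dmp_analysis** (`methclonal.dmp`) — exact paired Wilcoxon signed-rank
  tests per probe, Benjamini–Hochberg correction, ranking and counting of
  differentially methylated probes (DMPs).
- **pair_discrimination** (`methclonal.discriminate`) — linear SVM with
  leave-pair-out cross-validation and in-fold feature filtering;
  binomial significance against pair-level random guessing.
- **clonality_scoring** (`methclonal.clonality`) — MS scores, the
  empirical null and τ, TR/NP calls, complete-linkage dendrograms with
  matched-pair adjacency, distance-group comparisons, concordance and
  correlation with copy-number (PIS) and clinical calls.
- **clinical_classifier** (`methclonal.clinical`) — the rule-based TR/NP
  classifier (location, histological type, grade, hormonal-receptor gain).
- **survival_analysis** (`methclonal.survival`) — Kaplan–Meier, log-rank,
  Cox hazard ratios and time-to-recurrence comparisons between groups.

## Worked example

The numbered drivers under `analysis/` run the whole study; each writes
its tables under `results/`. The clonality stage, for instance:

```sh
python analysis/01_simulate_cohorts.py --seed 1
python analysis/04_clonality_scoring.py
```

prints

```
PT/AM: tau=23.97e-4 over 380 unrelated pairs; 20/20 TR calls; 20/20 adjacent pairs in the dendrogram; real-vs-artificial p = 4.72e-14
PT/LR: tau=30.43e-4 over 272 unrelated pairs; 11/17 TR calls; 9/17 adjacent pairs in the dendrogram; real-vs-artificial p = 8.36e-08
PT/CL: tau=30.06e-4 over 110 unrelated pairs; 2/11 TR calls; 1/11 adjacent pairs in the dendrogram; real-vs-artificial p = 0.925
printed 17-pair table: 9/17 MS-TR, feasible tau in [6.11, 6.64)e-4, MS-PIS agreement 14/17 (divergent pairs ['4', '8', '14']), r = 0.507
```

Reading: in the simulated axillary-metastasis-like cohort every pair is
clonal — all 20 are called TR and every pair forms its own clade in the
dendrogram, and matched ("real") pairs are far closer than unmatched
("artificial") ones. The local-recurrence-like cohort is mixed (11 of 17
called TR against a truth of 8 clonal), the contralateral-like cohort is
essentially all NP and its matched pairs are statistically
indistinguishable from unrelated ones. On the packaged printed score
table, 9 of 17 pairs are methylation-TR, the printed labels are exactly
reproducible by a threshold in [6.11, 6.64)×10⁻⁴, and the methylation
calls agree with the copy-number calls on 14 of 17 pairs.

The same computations are available as a CLI
(`methclonal simulate|dmp|discriminate|clonality|clinical|survival|full-run`),
e.g. `methclonal full-run --outdir out --seed 1`.

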