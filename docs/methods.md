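# Methods

## Data model

Abundance tables are samples × taxa matrices of relative abundances in ppm
(parts per million of a sample's total mapped reads); after
`normalize_ppm` every row sums to 10⁶ within 1e-9 relative tolerance, and
an all-zero sample is rejected rather than silently normalized. Kingdom
annotations (bacteria / fungi / virus / other) ride along for simulation
and reporting but never enter classification. Group labels are binary:
HI (healthy implant, the negative class) and PI (peri-implantitis, the
positive class).

## Screening

Each taxon is tested with the two-tailed Mann–Whitney U statistic for the
PI-vs-HI abundance difference. For combined samples of at most 12 without
ties the p-value is computed by exact enumeration of the null U
distribution; otherwise the normal approximation with tie correction and
continuity correction is used (it matches `scipy.stats.mannwhitneyu`'s
asymptotic method to better than 1e-8, which the test suite checks).
Raw p < 0.05 defines significance — deliberately no multiple-testing
correction, matching common practice in small biomarker studies; a
Benjamini–Hochberg option exists but is off by default. Direction
(higher/lower in PI) comes from the group means; medians are available.
The test is rank-based, so per-taxon monotone transformations of the
abundances do not change it.

## Single-marker classifiers

A single-marker model is (taxon, direction, cutoff): predict PI when the
abundance strictly exceeds the cutoff (direction `higher_in_PI`) or falls
strictly below it (`lower_in_PI`); equality predicts HI. Candidate cutoffs
are the midpoints between consecutive sorted unique training values plus
the two extremes, which makes the optimum well defined and insensitive to
float jitter. The selection maximizes sensitivity; because the extreme
cutoff trivially reaches sensitivity 1, ties are broken by maximal
specificity, then by the cutoff farthest from the PI-group extreme (the
most conservative boundary), then by the smaller cutoff. Fitting and
evaluation use the full dataset by default, reflecting how such
single-taxon baselines are usually reported.

## Combination scoring

A panel of n taxa (2–4 by default) scores a sample as
S = Σᵢ 100·Wᵢ·(Nᵢ−Pᵢ)/(Pᵢ+Nᵢ), with Pᵢ and Nᵢ the absolute distances of
the sample's abundance from the PI and HI training medians of taxon i.
Each term is a bounded, dimensionless vote in [−100Wᵢ, +100Wᵢ]: positive
when the sample sits nearer the PI median. The degenerate case
Pᵢ = Nᵢ = 0 (coinciding medians at the sample's value) contributes 0, its
continuity limit.

The enrichment weight is Wᵢ = (fᵢ,PI + εPI)/(fᵢ,PI + fᵢ,HI + εPI + εHI)
with fᵢ,G the fraction of group-G training samples where taxon i is
detected (nonzero) and εG = 0.5/|G| half a sample of pseudocount — a
presence-frequency enrichment in [0, 1] that is 0.5 for equal prevalence
and approaches 1 for PI-exclusive taxa. A taxon undetected in all training
samples carries no information and gets W = 0.5 with a warning. A
mean-abundance-ratio alternative is available
(`weight_scheme="abundance_ratio"`).

The decision threshold τ defaults to 0 (the score's sign). When tuned
(`tune=True`, the default in fitting), τ is chosen among midpoints of
consecutive sorted training scores plus 0 to maximize min(sensitivity,
specificity) on the training samples, keeping 0 whenever it attains the
maximum. All statistics — medians, weights, τ — come from the training
samples only.

One consequence of scoring with linear distances deserves note: for a
taxon whose values vary log-normally with log-scale σ, a multiplicative
up-shift leaves roughly Φ(−ln 2/σ) of shifted values closer to the HI
median than the PI median no matter how large the multiplier (the
midpoint between medians sits near half the shifted median). Panels
therefore classify best when the within-group spread is moderate relative
to the effect, which shaped the synthetic calibration below.

## Evolutionary panel search

Each of `n_models` independent runs draws a stratified train/test split
(`train_fraction` = 0.4, constrained strictly below 0.5) and evolves a
population of 50 distinct-taxon panels for 100 generations: tournament
selection (k = 3), crossover that redraws a child from the parents'
pooled taxa, mutation that replaces one taxon, grows or shrinks the panel
within its size range, and elitism of 2, so the best-so-far fitness never
decreases. After the last generation the best panel is refitted on the
full training split and evaluated on the held-out test samples and the
whole cohort. Rerunning with the same seed reproduces everything exactly.

**Fitness.** The objective is the tuple (min(sens, spec), sens + spec,
margin), where the margin is the sum of the central gap (median PI score −
median HI score) and the worst-case gap (min PI score − max HI score) of
the scores, in raw score units. With only ~16 training samples, a naive
resubstitution estimate of these quantities saturates: among the ~10⁹
possible panels, many thousands separate any fixed 16 samples perfectly,
so a search driven by resubstitution fitness returns arbitrary panels
(the resubstitution mode is retained as
`EvoConfig(fitness_mode="resubstitution")`, and the null-cohort test
documents its overfitting). The default fitness therefore cross-validates
*inside* the training split: 12 repeated stratified sub-splits, each
fitting medians, weights and τ on 60% of the training samples and scoring
the rest, with all held-within-train predictions pooled. Test samples are
never touched before final reporting.

**Candidate prior.** New panel taxa are drawn, with probability 0.9, from
a shortlist of the 15 taxa whose training score terms best order the two
groups (per-taxon rank statistic |AUC − ½|), and uniformly otherwise.
This mirrors how the search space is actually tractable — candidate
alterations are ranked before being combined — and on signal-free data it
degrades gracefully to ordinary random search. Both knobs are exposed
(`candidate_pool_size`, `candidate_bias`; pool size 0 disables the
prior).

## Evaluation

Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) are computed with PI
as the positive class; a zero denominator raises an error rather than
returning 0. ROC curves sweep a decision threshold across the observed
score range at 5% steps (21 interior thresholds, read as threshold
spacing over the score range) plus open endpoints, classify score >
threshold as PI, and integrate trapezoidally; `interval=None` sweeps all
distinct scores, in which limit the AUC equals the Mann–Whitney
U/(n₁·n₂). Binary-rule models get ROC curves from their underlying
continuous quantity (abundance, or the panel score S), never from binary
outputs. Models are ranked by 100·(sensitivity + specificity + AUC), ties
broken by sensitivity, specificity, then model id. Performance classes
bin by the weaker of sensitivity and specificity: poor < 70% ≤ reasonable
< 80% ≤ good < 90% ≤ excellent.

## Synthetic cohorts

The generator emulates sparse metagenomic relative-abundance tables with
a zero-inflated log-normal model: per-taxon log-means drawn uniformly
from `log_mean_range` (default (0, 4)), per-cell log-normal noise with
`log_sd` (default 0.5), and a Bernoulli absence mask with probability
`zero_inflation` (default 0.3); rows are then ppm-normalized. Two
presets mirror the study cohorts (biofilm 40 HI / 20 PI; saliva 20 / 20)
over 596 + 52 + 586 taxa.

Planted single markers multiply (up) or divide (down) the affected
taxon's values in PI samples; an up-shift also forces the taxon to be
detected in PI samples (a hurdle-model view: enrichment implies
presence), without which a multiplicative effect on a zero-inflated taxon
has no power. Planted combination panels up-shift each member in an
overlapping subset of PI samples: every PI sample shifts k of the m panel
taxa, with k ∈ {⌊m·ρ⌋, ⌈m·ρ⌉} mixed to give per-taxon penetrance ρ
(default 0.9), so each taxon alone misses ~10% of PI samples but any two
members jointly cover nearly all of them. The default effect multiplier
is 12.

These defaults were calibrated once, before being frozen, against three
requirements at the study's sample sizes: a ×8 single marker should be
detected in ≥95% of 20/20 replicates; the planted panel fitted on <50% of
the cohort should classify held-out samples in the excellent class; and
the search should recover ≥2 of 3 planted taxa in most runs. The
geometric argument above is why the defaults pair a moderate log-scale
spread (0.5) with strong multiplicative effects — the regime of real
disease-associated oral taxa, which often differ between groups by
presence/absence or orders of magnitude. What the generator does *not*
emulate: taxon co-occurrence structure, per-taxon prevalence
heterogeneity, compositional correlations beyond the closure constraint,
and read-level sequencing noise. Passing recovery tests therefore show
the machinery works under its stated model, not that real cohorts of this
size would yield equally clean panels.

## Numerical and degenerate-input conventions

Values exactly at a cutoff or threshold predict HI (strict inequalities
throughout). Exact Mann–Whitney refuses tied data. Normalization rejects
all-zero samples; a generated sample that would be all-zero re-seats its
largest baseline taxon. All randomness flows from `numpy` Generators
seeded from a single integer; independent runs use
`SeedSequence.spawn`. Pipeline outputs avoid timestamps so reruns are
byte-identical (the log file and the manifest's output path are the only
run-specific artifacts).

## Known limitations

- With ~16 training samples, any train-only fitness — including the
  cross-validated one — retains optimistic bias under selection over many
  panels; held-out metrics of the winning panel remain the only honest
  performance estimate, and on signal-free data they hover near chance
  while training fitness saturates.
- Panel recovery depends on the realized cohort: when one planted taxon
  happens to be a near-perfect marker on its own, search runs may settle
  for it plus incidental partners, and the recovery rate drops toward
  ~two-thirds of runs.
- The score's linear-distance geometry caps performance at large
  within-group spread (σ ≳ 1 in log scale), independent of effect size.
- Whole-cohort ("full") metrics for evolved models reuse their training
  samples and are reported for comparability with ranked model tables,
  not as unbiased estimates.
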