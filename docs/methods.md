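# Methods

## Data model

The unit of analysis is a **response set**: the set of acupoints one
rater prescribed for one clinical case. A study is a collection of
response sets partitioned by case and by rater group, together with a
closed vocabulary of 361 standard WHO acupoint codes and each group's
*declared* panel size (the number of raters the study intended per case,
e.g. 80 clinicians and 10 LLM runs).

Free-text or mixed-terminology input is reconciled before analysis.
Each recorded item may carry up to three alternative spellings of one
intended acupoint. A single spelling resolves directly through the
code/alias table (clinician free text usually carries one terminology);
with two or more spellings, at least two must resolve to the same code —
a majority rule that screens machine output which mixes terminologies
and often corrupts one of them. Items that fail reconciliation, and
codes outside the vocabulary, are dropped and the response flagged.
Flagged responses — including those whose final set size leaves the
instructed 3–5 range — are **retained**: dropping them would silently
change the declared denominators, and the denominator convention (below)
already accounts for attrition. This retention rule is a package design
choice for an edge case whose handling is rarely reported in studies of
this design.

## Agreement statistics

Selection probabilities divide per-code rater counts by the **declared**
group size by default, not the observed row count; a missing response
therefore lowers probabilities rather than renormalising the remaining
panel (`divisor="observed"` switches to the observed count).

Percentage overlap is asymmetric by design: it asks what fraction of the
*reference* group's consensus (codes at or above the cutoff) the test
group also reaches. Thresholding is inclusive (≥). When no reference
code clears the cutoff the statistic is undefined for that cutoff and
reported as missing; missing values are excluded from cutoff averages
and group means rather than coerced to zero, since "no consensus to
compare against" is not evidence of disagreement. The default cutoff
grid is {0.10, 0.20, 0.30, 0.40, 0.50}.

Spearman's ρ is computed over the union of acupoints selected at least
once by either group (codes selected by neither are uninformative and
excluded), with average ranks for ties and a two-sided p-value from the
t approximation on `n_items − 2` degrees of freedom. Fewer than three
items, or a constant profile, yields a missing result with a warning
flag instead of a spurious coefficient.

Top-k ranking sorts by probability descending with lexicographic
tie-breaks, so output is deterministic.

## Variability analysis

Within-group heterogeneity is the mean Jaccard dissimilarity over all
unordered within-group pairs of response sets (two empty sets count as
identical). The distance matrix is built once per case over both groups.

**Bootstrap.** The group difference in mean pairwise dissimilarity gets
a 95% percentile CI from 2,000 replicates. Each replicate resamples
*responses* (not distances) with replacement within each group and
recomputes both group means; with size-matching (the default) both
groups are resampled at the smaller group's size, so interval width
reflects a common panel size rather than the 80-vs-10 imbalance. A
replicate in which a resampled group collapses to a single distinct
response defines no pairs and is redrawn; at the default sizes this is
vanishingly rare and the redraw rule only matters for tiny panels.

**PERMDISP.** Dispersion homogeneity is tested by embedding the Jaccard
matrix with classical PCoA (Gower double-centering of −d²/2, full
eigendecomposition). Jaccard matrices are generally non-Euclidean, so
negative eigenvalues appear; axes are kept for every |λ| above
`1e-8 · max|λ|` and split by sign. The distance of response *i* to its
group centroid is `√max(0, Δ²₊ − Δ²₋)` — squared distances on the
real axes minus those on the imaginary axes, floored at zero
(Anderson's correction). The observed statistic is the one-way ANOVA F
on these distances; significance comes from permuting the raw group
labels, **re-deriving the group centroids under every permutation**, and
counting permuted F values at or above the observed one:
`p = (b + 1)/(n_perm + 1)`, so the smallest attainable p is
`1/(n_perm + 1)`. The default `n_perm = 9999` resolves p-values down to
1e-4. Permuted statistics analytically tied with the observed one can
differ from it by floating-point noise, so the comparison uses a
relative tolerance of 1e-8 — without it the test is anti-conservative on
small, highly symmetric inputs where exact ties are common. Centroid
(not spatial-median) dispersion is used, and group labels (not
residuals) are permuted: the simplest exchangeable scheme for a
two-group design with no covariates.

## Synthetic study generator

The generator emulates the design the pipeline targets: per-case
selection tendencies with a few **major acupoints** (SP6, LR3, LI4,
ST36) shared across all cases, a handful of case-specific codes, and a
long tail of rarely used points; every rater draws a set of 3–5 distinct
codes; and the two groups differ only in a heterogeneity knob η.

- Each rater's private weights are `w · exp(η · Laplace(0, 1))`.
  η = 0 reproduces the shared profile exactly; larger η makes raters
  individually idiosyncratic. The log-Laplace law was chosen over a
  lognormal because its heavier tails let a strongly heterogeneous rater
  occasionally promote a rare tail acupoint into their personal top
  ranks — the signature of individual clinical style — while leaving a
  near-homogeneous group essentially untouched. With light-tailed
  log-noise the two groups' heterogeneity stays too close together at
  any base-weight profile, which does not match how a large clinician
  panel and a fixed-prompt LLM behave.
- Sets are drawn by sequential weighted sampling without replacement
  (draw, remove, renormalise). Inclusion probabilities are therefore
  *not* exactly proportional to weights; `exact_inclusion_probabilities`
  computes the true values by enumeration (feasible for ≤ ~10 positive
  codes) and is the ground truth for parameter-recovery tests.
- Default base weights: majors 8.0, six case-specific codes 2.0, a
  200-code tail at 0.025, all other codes zero. These tiers were fixed
  at design time so that the default η gap (1.2 for the clinician group
  vs 0.2 for the LLM group, 80 vs 10 raters) produces clinician mean
  pairwise dissimilarities around 0.84–0.91 with the LLM group clearly
  lower — the regime reported for real clinician-vs-LLM panels — and so
  that the ordering is essentially always recovered at these sample
  sizes. The LLM group's absolute level (≈0.75) sits slightly above
  real fixed-prompt LLM runs, which are more repetitive than any
  weighted-sampling model of this form; the generator is calibrated for
  the *contrast*, not for matching either group's absolute level.

What the generator does **not** emulate: diagnostic reasoning or
meridian theory (selection tendencies are abstract weights), correlation
between a rater's choices across cases (each response is independent),
and the near-deterministic repetition of LLM runs. Passing tests on
synthetic data therefore demonstrate the statistical machinery — not
clinical validity of any rater group.

## Worked-example data

`acupanel.worked_example` bundles the published per-case percentage
overlap values (10% cutoff and cutoff-averaged) and the disease grouping
from a real 80-clinician-vs-GPT-4 comparison over 10 cases. Aggregating
them reproduces the published overall mean (51.3% at the 10% cutoff) and
the six disease-group means. The mean of the *rounded* cutoff-averaged
row is 48.5; the study's own headline of 48.9 was evidently computed
from unrounded per-case values, so the package reports what the printed
row yields and does not force the headline figure. Raw per-rater
responses were not published, so every statistic that needs them
(correlations, dissimilarities, PERMDISP) is exercised on synthetic
panels instead.

## Test problem sizes

The statistical test suite uses: 200 random instances (n ≤ 8) for the
Spearman brute-force cross-check; complete enumeration of the 20
labelings at n = 6 for the PERMDISP oracle; 500 simulated cases with
`n_perm = 199` for null calibration of the type-I error (the permutation
test is exact under exchangeability, so 199 permutations only coarsen
the attainable p-values, not the calibration); 200 simulated cases at
the default study size for the heterogeneity-direction check; and 2,000
raters at η = 0 for parameter recovery against the enumeration oracle.

## Known limitations

- The percentage overlap ignores *how far* above the cutoff codes sit;
  two groups can overlap 100% with very different probability profiles.
  The Spearman profile correlation is the complementary view.
- PERMDISP compares dispersions around group centroids; with strongly
  unbalanced groups its power is limited and location differences
  (PERMANOVA territory, out of scope) can masquerade as dispersion
  effects in pathological cases.
- The bootstrap treats responses within a group as exchangeable; any
  rater-level clustering across cases is ignored.
- Terminology reconciliation is exact lookup; no fuzzy matching or typo
  correction is attempted beyond the alias table supplied by the user.
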