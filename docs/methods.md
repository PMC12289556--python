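# Methods

This note documents the statistical model, the synthetic-data design, the
numerical choices, and the known limitations of `comorbnet`.

## Unit of analysis

All co-occurrence and association statistics are computed on the
**patient-year**: the set of ICD-10 codes (primary and secondary positions
alike) recorded for one patient within one calendar year. Twelve-month
windows are calendar years (Jan 1–Dec 31); a rolling window anchored per
patient would be an alternative reading of "12-month windows" but is
deliberately not implemented — calendar years are the only windowing
consistent with both per-year deduplicated pair counting and yearly trend
series. A patient observed in two years contributes two observations;
duplicating claim rows never changes any count (verified by property test).

Codes are compared as exact normalized strings (uppercase, dot removed).
There is no ICD-10 hierarchy rollup: J44.9 and J44.1 are distinct nodes, as
in code-level claims analyses.

## Association testing

For each unordered code pair, binary presence vectors over patient-year
observations are correlated with Spearman's ρ, computed as the Pearson
correlation of mid-ranks (tie-corrected). On binary data this equals the phi
coefficient of the 2×2 contingency table — a useful cross-check that the
test suite enforces to 1e−12.

p-values are two-sided. For n ≥ 30 the t approximation
`t = ρ·sqrt((n−2)/(1−ρ²))` on n−2 degrees of freedom is used. Below n = 30
a permutation test replaces it: the distinct orderings of the y-ranks are
enumerated exhaustively when there are at most 10,000 of them (a multiset
count, `n!/∏ tᵢ!`, so heavily tied binary vectors enumerate exactly at
larger n than untied ones), otherwise a seeded 10,000-draw Monte-Carlo
permutation with the add-one estimator `(hits+1)/(draws+1)`. Constant
columns have no ranking to correlate; such pairs are flagged *degenerate*,
logged, and excluded from edges rather than aborting a run — rare codes
should not kill an analysis.

Significance defaults to raw p < 0.05, uncorrected. The
Benjamini–Hochberg step-up adjustment is implemented and can drive the edge
rule (`use_adjusted=True`), but the default follows common practice in
claims-network studies of reporting uncorrected associations with the
multiplicity caveat stated. With ~45 pairs at α = 0.05 roughly two spurious
edges are expected per run; the hub ranking is robust to this because
planted hubs separate by several degrees.

## Observation universe and Berkson conditioning

A subtle denominator question: presence vectors need a row for every
*enrolled* patient-year, but bare claims only reveal patient-years that
generated at least one claim. Conditioning on utilization induces a mild
negative dependence between otherwise independent conditions (Berkson's
bias); we measured induced ρ of −0.02 to −0.06 in cohorts of ~10,000
patients, large enough to be "significant" at those sample sizes.
`pairwise_associations` therefore accepts the enrollment universe size when
it is known (`n_universe`): missing patient-years enter as all-zero rows and
correlations then refer to the enrolled population. The pipeline passes the
roster size automatically for synthetic cohorts (it is part of the design);
for real claims the default remains utilizer-only, and users with
eligibility files should pass the member-year count. This choice is why
planted-structure recovery is clean in the validation experiments; without
it the recovered networks saturate with weak negative edges.

## Synthetic cohort generator

The generator exists so that every downstream stage can be validated against
known ground truth; real claims sit behind data-use agreements.

**Dependence model.** Disease indicators per patient-year are drawn by
thresholding a multivariate normal: code *j* is present when its latent
coordinate exceeds Φ⁻¹(1 − prevalenceⱼ). For each planted pair the latent
correlation r is solved so that the implied 2×2 distribution has exactly the
requested odds ratio: the target joint cell comes from the Plackett
quadratic, and r is found by Brent root-finding on the bivariate-normal
orthant probability (SciPy's bivariate CDF; solver tolerance 1e−12 in r,
verified to 1e−6 in the joint cell). At prevalences 0.5/0.5 the closed form
P(both) = 1/4 + arcsin(r)/2π gives r = 0.5 for OR = 4, which the solver
reproduces and the tests pin. Unplanted pairs have latent correlation 0
(independence). The completed matrix must be positive definite; an
indefinite one fails loudly listing the planted pairs, with optional repair
by eigenvalue clipping at 1e−8 and diagonal rescaling (`repair=True`).

**Claim emission.** Presence and utilization are separate layers. Each
present condition emits a Poisson number of claims per year with mean
`encounters_per_condition × disruption[year]`, each claim carrying that
single code in the primary slot and a uniform random date within the year.
Deriving comorbidity therefore *requires* the patient-year aggregation —
no single claim row ever shows two codes together. The default
`encounters_per_condition = 2.0` reflects a managed chronic condition
generating a handful of billable encounters a year; the default disruption
multiplier for a shocked year is 0.6 (a noticeable but partial dip). A
present condition can emit zero claims in a year (presence without claims),
which is exactly the care-gap phenomenon the disruption analysis measures.

**Demographics.** Age is drawn once per patient from a normal with mean
53.8 and SD 21.7 truncated to [0, 90] (top-coded, as in de-identified
extracts), sex is F with probability 0.574 else M, both held fixed across
years. Yearly presence is re-drawn i.i.d. given prevalences: there is no
incidence/progression dynamic and no care-seeking selection model. Passing
tests on these cohorts therefore demonstrates correctness of the counting
and testing machinery, not robustness to coding error, under-reporting, or
selection — all of which real claims exhibit.

## Trends and disruption

Yearly pair counts feed per-pair trend series. Partial years (e.g. a final
year observed only through June, coverage 0.5) are either flagged and
excluded from change statistics (default) or linearly annualized
(`count/coverage`, rounded, marked estimated). A dip year has relative
change ≤ −20%, a rebound year ≥ +20% after some dip; both thresholds are
config keys. Relative rather than absolute change makes pairs of very
different magnitude commensurable. Years following a zero count are skipped
rather than yielding infinities. Detection needs at least three usable
years.

## Determinism

Every stochastic component is seeded: the cohort seed splits into
independent streams for indicators and claim emission via `SeedSequence`
spawning, permutation tests take an explicit seed, and the force-directed
layout runs a fixed 100 iterations from seeded positions. Two pipeline runs
with the same config and seed produce byte-identical artifacts, which the
manifest's SHA-256 checksums make checkable. The config hash covers analysis
parameters only (not the output path).

## Validation problem sizes

The validation experiments use cohorts sized to make ground-truth recovery
statistically decisive while keeping a full run in tens of seconds: 50,000
patient-years for copula odds-ratio fidelity (sampling SD of log OR ≈ 0.02);
20 replicates of 10,000 patients × 10 codes for hub recovery (planted hub
degree 5 vs. second-ranked degree ≤ 3 in pilots); 20 cohorts of 2,000
patients × 5 years for dip detection (expected 2022 relative change ≈ −45%
against a ±20% threshold); 2,000 null pairs of n = 500 for type-I
calibration.

## Known limitations

- Edges are associational; no directionality, causality, or temporal
  ordering within a year is inferred.
- Uncorrected p < 0.05 is the default edge rule; expect false-positive
  edges in proportion to the number of pairs tested.
- The generator does not model disease progression across years, seasonal
  claim timing, coding noise, or demographic-dependent prevalence.
- Real-claims runs without an enrollment denominator inherit Berkson-type
  conditioning on utilization (see above).
- Interactive visualization is out of scope; exports are machine-readable
  (GraphML, CSV) with layout coordinates included.
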