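# Methods

## Model and procedure

`teharm` tests, window by window, whether the number of mutations an
element carries inside a fixed-size window of the family consensus is
negatively correlated with the element's transpositional activity. The
procedure is deliberately model-free: no regression of activity on mutation
counts is fitted. The statistic per window is Pearson's ρ between the
window's per-element mutation counts and the activity-fraction vector, and
the null hypothesis per window is "mutations in this window are not
negatively related to activity".

The null distribution is generated by permutation: in each iteration every
column of the mutation matrix is shuffled independently across elements and
the per-window correlations with the fixed activity vector recorded. Per
window this is the uniform distribution over permutations of that column
against the activity vector; shuffling columns independently (rather than
applying one row permutation to the whole matrix) makes no difference to
any per-window marginal, which is all the test uses. The test is strictly
one-sided on the left tail: positive correlations — which can arise when
the consensus is not ancestral to the younger, more active elements — are
never called significant.

Significant windows (q below the confidence threshold λ) are merged into
regions when their spans share at least one consensus position; windows
that merely touch end-to-start are kept separate. Each region reports the
unweighted mean q-value of its member windows. Merged regions are therefore
disjoint, sorted, and at least one window long.

## Coordinates and units

All positions are 1-based and inclusive on the consensus; window *i* spans
[*i*, *i* + *wsize* − 1]. Only BED import/export converts to 0-based
half-open coordinates. Activity fractions are percentages of a reference
element's activity and are kept on that scale throughout (they may exceed
100); percent identity is a fraction in [0, 1].

## Mutation calling

Elements are aligned to the consensus with global Needleman–Wunsch using
affine gap penalties (defaults match +1, mismatch −1, gap open −2, gap
extend −1; a gap of length k scores open + (k−1)·extend). Ties in the
traceback are broken by the aligner's deterministic enumeration order, so
runs are reproducible across platforms. Differences are projected onto
consensus coordinates: substitutions and deleted consensus positions count
at their own position; an insertion run in the element counts once, at the
consensus position on its left flank (position 1 for a left-end run). This
keeps every mutation on the consensus coordinate system the windowing
needs, and stops a single long insertion from inflating one window's
count. Percent identity divides identical columns by the gapped alignment
length — a fixed, documented convention rather than an inference about how
any particular assay counted changes. A precomputed mutation table can
replace the alignment stage entirely, for mutation calls that come from
curated data.

## Empirical p-values and q-values

The default p-value estimator is the add-one form
(1 + #{ρ_null ≤ ρ_obs}) / (n + 1), the standard for permutation tests: it
is never exactly zero, which the q-value estimator requires. A `raw` mode
reports the plain count fraction, rendering a zero count as "< 1/n". With
raw p-values selected, the q-values are still computed from the add-one
estimates.

q-values use the Storey machinery: q_j = π₀ · min over p_k ≥ p_j of
(p_k · m / rank(p_k)), enforced monotone. The pipeline default fixes
π₀ = 1, which reduces exactly to Benjamini–Hochberg (verified against
SciPy's BH implementation in the test suite). This default is deliberate:
overlapping windows share wsize − 1 positions, so neighbouring p-values are
strongly positively dependent — effectively only about L/wsize of the nw
tests are independent. Under that dependence the data-driven π₀ estimate
(π₀(λ) = #{p > λ} / (m(1 − λ)) on the grid λ ∈ {0.05, …, 0.95},
extrapolated to λ → 1 with a cubic smoothing spline and clipped into
(0, 1]) has very high variance: on a complete-null synthetic family the
upper tail of the p-distribution is occasionally empty by chance, π̂₀
collapses toward 0, and the resulting q-values declare hundreds of false
windows. BH needs no π₀ estimate and remains valid under positive
dependence, and in simulation it both holds the false discovery rate on
disjoint windows and recovers planted regions slightly better (the
deflated π̂₀ was promoting marginal flank windows). The smoother estimate
stays available (`pi0=None` in the library, `--pi0 storey` on the CLI) for
weakly dependent inputs; it falls back to the conservative π₀ = 1 for
fewer than eight p-values or a non-finite smoother output, and is floored
at 1/m. Windows whose mutation counts are
constant across elements have an undefined correlation: they are flagged
(NaN), excluded from π₀ and q estimation, reported as NA, and never called
significant. A constant activity vector is a hard error — every correlation
would be undefined.

## Coverage simulation

Coverage of a functional annotation by a region set is the fraction of
annotation positions overlapped. The null redraws the detected regions:
intervals with exactly the observed lengths are placed on [1, L] without
mutual overlap (touching allowed), by sequential rejection sampling — the
length list is shuffled, each interval start is drawn uniformly among the
currently feasible starts, and the whole configuration is retried (cap
1000) on a dead end. For a single interval this is exactly uniform over
placements; for several it is approximately uniform over non-overlapping
configurations, an approximation that is immaterial at the region densities
involved but documented here. The reported probability
P(cov_harm < cov_rand) counts strict exceedances; ties count toward "not
less".

## Activity groups and the mutation partition

Activity groups partition [0, ∞): inactive [0, 5), low [5, 40), moderate
[40, 66.6), high [66.6, ∞). The 66.6% boundary is assigned to the high
group so the classification is total. Neutral sites are the union of
mutation positions over high-activity elements. The partition report bins
elements by percent identity (user-supplied half-open bins on [0, 1]) and
tabulates, per (bin, activity group), the percentage of that cell's
mutations (with multiplicity across elements) inside harmful regions and
inside neutral sites. A mutation may count in both columns when a neutral
site lies inside a harmful region — exclusivity is deliberately not forced
— and zero-mutation cells report 0% rather than NA.

## Synthetic families

The generator emulates an activity-assayed TE family. The consensus is
uniform over {A, C, G, T}; each element draws a Poisson number of mutations
at uniform positions without replacement; activity is
max(0, base − effect·h + ε) where h is the element's number of mutations
inside the planted harmful regions and ε ~ N(0, noise_sd²). Noise is
unbounded above, so activities above 100% occur, as in assay data.

Defaults are the regime the method is designed for, AluY scale: N = 52
elements, L = 282, wsize = 10, two planted 20 bp regions (40–59 and
160–179), 12 expected mutations per element (≈4% divergence — the range in
which assayed elements remain active; elements beyond ~10% divergence are
essentially never active), a 30-percentage-point penalty per harmful
mutation, base activity 100% and 5 points of noise. Mutations are
substitutions by default (`indel_fraction` realises a fraction as 1 bp
indels, exercising the alignment attribution rules); with no indels,
re-aligning the generated elements recovers the ground-truth profiles
exactly, which the tests assert.

What the generator does not emulate: phylogenetic structure (subfamilies,
master genes), CpG hypermutability, position-dependent mutation rates, and
nonlinear activity responses. Passing recovery tests therefore show the
statistical machinery works when the generating model matches the method's
assumptions — not that any particular real family satisfies them.

## Numerical and design choices

* Window counting uses the cumulative-sum form of the telescoping
  recurrence m_{i+1} = m_i − [i mutated] + [i+wsize mutated]; tests check
  it against a naive per-window recount.
* The permutation null is generated column-by-column from a single seeded
  generator; the pipeline derives independent sub-seeds per randomized
  stage from the master seed, so adding a stage never perturbs another
  stage's stream. Identical inputs and seed give byte-identical outputs.
* Significance uses strict q < λ. The alternative reading (q ≤ λ) differs
  only on exact ties, which have measure zero for continuous q;
  `strict=False` is available.
* The average q of a region is the unweighted mean over member windows.
* Default n = 10,000 permutation iterations and λ = 0.05 for interactive
  use. The test suite and the acceptance script use n = 2,000 iterations,
  10 seeds for recovery and 20 for null calibration, sizes at which the
  binomial error of the empirical p-values is already far below the
  decision threshold.
* Null calibration is asserted on disjoint (non-overlapping) windows only:
  overlapping windows share positions and are strongly correlated, so the
  5% type-I level applies per disjoint test.

## Known limitations

* The exact region tables of the original AluY/Alu/L1 analyses cannot be
  re-derived here: the underlying assayed element sequences and activity
  values are not redistributable, and the exact q-value-package settings
  used then are unrecorded. The acceptance script instead recomputes the
  published coverage percentages from the printed region tables and totals,
  and demonstrates recovery and calibration on synthetic families.
* Percent-identity bin boundaries for the partition report are
  user-supplied; no defaults are meaningful.
* The coverage null's multi-interval placement is approximately, not
  exactly, uniform over configurations (see above).
* How the original assays counted indels is unknown; the indel conventions
  here are declared, not inferred.
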