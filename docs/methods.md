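# Methods

`kinbias` implements a pipeline for asking whether adult male primates
in a fission–fusion community bias association and interaction toward
their own infants, and whether associating with a mother pays off as
future paternity.  The analyses it encodes are the ones used in
long-term chimpanzee field studies: dyadic association indices with
per-male z-standardization, observed-versus-expected kin-category
interaction statistics with a permutation null, Elo dominance ranks,
and mixed models.  Because the long-term observational data such
studies rest on are not publicly released, the package ships a
synthetic fission–fusion generator that emulates the study system, so
that every downstream stage is exercised end to end and its
statistical behaviour (type-I error, power, sign recovery) can be
measured rather than assumed.

## Units and kin categories

The analytic unit of association is the mother–infant (MI) pair: a
minute counts as co-association only when the mother *and* her infant
are both in the focal male's party.  Infancy spans seven half-open
six-month age bins covering [0, 42) months; "six months" is always
calendar-month addition (an infant born 1 January occupies bin 0
through 30 June).  Each adult male (≥ 12 years) is classified relative
to each infant as FATHER, MATERNAL_KIN (the infant's adult maternal
brothers, maternal uncles and maternal cousins, i.e. matriline chains
meeting at the mother or the maternal grandmother), NON_KIN (paternity
known, no such matriline link), or UNKNOWN (paternity unassigned).
FATHER takes precedence over a coincidental maternal relation.  A
configuration switch widens MATERNAL_KIN to any shared matrilineal
ancestor; the default stops at the three named relations.

## Association index and standardization

For male *m* and MI pair *p* in window *w*:

    A(m, p, w) = co-minutes(m, p, w) / follow-minutes(m, w | p present)

Within each (male, window), proportions across **all** MI pairs present
in the community — maternal-kin, unknown-paternity and other-age father
dyads included — are z-standardized (n−1 denominator), which controls
for temporal changes in demography and community gregariousness.  A
standardization set with fewer than two pairs or zero spread yields
z = 0 with a degeneracy flag (a sensitivity switch drops such rows
instead).

One deliberate refinement: each pair's denominator counts the male's
follow minutes *on days the pair was analytically present* (infant
alive and under 42 months, mother alive).  For pairs present throughout
the window — every father–own-offspring row, and the common case — this
is identical to dividing by all of the male's follow minutes.  For
partially present pairs the plain denominator mechanically deflates the
proportion, and since a father's own pair is always fully present in
its own anchored window, that deflation would bias the father-versus-
non-kin contrast upward even when the generator contains no bias at
all.  With the exposure-corrected denominator the null contrast is
centred on zero (verified by the Monte-Carlo suite), so partial-window
pairs can stay in the standardization set.

Two comparison datasets are built, both filtered to males with ≥ 30 h
(1800 min, boundary inclusive) of focal observation in the window:

* **within-period** — for each father and each six-month bin of each of
  his offspring, his z with the offspring's pair versus his z with every
  non-kin pair present in the *same calendar window*; windows are
  anchored at the offspring's birth date.  A window contributes only if
  both a FATHER row and at least one NON_KIN row survive.
* **between-period** — his z with non-kin pairs occupying the *same age
  bin* in their own (possibly calendar-disjoint) windows; a male enters
  a bin only with both row kinds present.

## Interaction rates

From 1-minute family-follow point samples, the dyadic interaction rate
of infant *i* with male *m* in a period is grooming-or-playing minutes
with *m* over sample minutes spent in the same party as *m* (direction-
agnostic, GROOM and PLAY pooled; a male's sample minutes count only
while he is alive and adult).  Periods are EARLY [0, 6) and LATE
[6, 42) months with ≥ 10 h / ≥ 60 h observation filters.  Rates are
summed over males into the infant's total strength; the observed
proportion of a kin category is its rate-sum over total strength (all
categories contribute to the denominator; infants with zero strength
are excluded).  The expected proportion is the fraction of adult males
alive in each category at a reference date — the period start (birth,
or the six-month anniversary) by default, with a midpoint option, since
the only anchored convention in the field literature is the birthday
example.  Per-infant observed−expected differences are tested with a
one-sample sign-flip permutation test: statistic = mean, two-sided
p = share of resampled |mean| ≥ observed |mean|, default B = 10 000,
seed mandatory; all 2^n sign patterns are enumerated exactly whenever
2^n ≤ B.

## Dominance and the paternity model

Elo ratings use the standard logistic update (expected score
`1/(1+10^((R_l−R_w)/400))`, winner gains `k(1−E_w)`, loser loses the
same, so the rating sum is conserved).  Start rating 1000 and k = 100
follow common animal-dominance convention; both are configurable and
recorded in output metadata because no canonical values exist.  Ordinal
rank 1 is the top-rated adult male alive at the query date; ties break
by earlier first contest, then id, so ranks are deterministic and
piecewise-constant between contests.

For each (mother, prior infant) conception case, the father's
z-standardized association with the mother's pair over the prior
infant's first 18 months (males filtered at ≥ 90 h of observation in
that window) and his ordinal rank at conception enter a binomial
logit model of whether the same male sired the next offspring, with
mother and father random intercepts.  Estimation is delegated: the
Gaussian association model uses statsmodels `MixedLM` (REML, three
crossed variance components; a factor with one level is dropped), and
the binomial model uses the Laplace/MAP fit of statsmodels
`BinomialBayesMixedGLM` with a diffuse fixed-effect prior (sd 100),
falling back to a fixed-effects logit and then to a Firth
(Jeffreys-penalized) fit when the mixed fit is unstable, a random
factor is degenerate, or the response separates.

Term tests are Wald: F = χ²/q with a residual-type denominator df
(n − p) for the Gaussian model — at the row counts this pipeline
produces (hundreds to thousands) this is indistinguishable from the
χ² scale, and the null Monte-Carlo confirms the interaction test holds
its level.  Father-versus-non-kin contrasts within each age bin form
one family of (up to) seven comparisons; the family-wise adjustment is
the single-step max-|Z| multivariate-normal method over the contrasts'
estimated correlation (100 000 fixed-seed draws), floored at the
unadjusted p.  A studentized-range ("Tukey") adjustment does not
literally apply to non-pairwise contrasts; the single-step method is
what multcomp-style software computes for such families.

A known small-sample limitation, measured rather than hidden: with
study-scale case counts (roughly 12–25 conceptions) and a ~0.2
repeat-sire base rate, the Wald χ² test of the paternity model is
conservative — its null rejection rate at α = 0.05 is ≈ 0.01, reaching
the nominal level only near 80 cases.  The calibration suite reports
this honestly; the Wald statistic is kept because it is the field's
reporting convention for this model.

## Synthetic community

The generator emulates the study system at desk scale.  Defaults: 12
adult males, 16 mothers, 7 simulated years.  Mothers' gregariousness
(per-male baseline co-party probability per 30-minute segment) is drawn
per mother from [0.04, 0.12], so time fully alone spans roughly a
quarter to two-thirds of observation, matching the low sociability of
east-African mothers.  Party composition is piecewise-constant in
30-minute segments for speed; minutes are exact within segments.  The
father's co-party odds with his own infant's pair are multiplied by
`father_bias^(2^(−age/τ))` — ×3 at birth decaying with a 6-month
half-life by default, which reproduces the early-infancy concentration
of the father bias.  Infants groom/play with co-present males at
0.004/min in late infancy (×4 for fathers), ≈ 0 in early infancy;
these rates were set so the simulated overall late-infancy interaction
proportion (~0.005) and the near-absence of early interactions match
the reported scale of infant–male interaction.  Sires come from a
rank-skewed lottery (weight 0.65 per rank step), implying a ~21%
repeat-sire probability and a ~35% top-male share — the repeat-
paternity level reported for this community.  Inter-birth intervals
are compressed (mean 40 months versus the real ~5.5 years) so that a
7-year span yields sample sizes near the reported ones (~32 infants,
~20 known conception cases) without simulating 25 years.  A
configurable `paternity_link` γ shifts the repeat-sire log-odds by
γ × the father's *latent* expected z-association (computed from the
same odds model, so no circular dependence on realized follows);
γ = 0 — the default — is the null.  One master seed drives everything;
replicate streams derive from (seed, replicate) so each replicate is
independently reproducible, and equal seeds give byte-identical CSVs.

What the generator does **not** emulate: spatial ranging and border
risk, male death/immigration, seasonal birth pulses, observation gaps,
behaviour codes beyond groom/play, and real inter-birth intervals.
Passing tests therefore show that the estimators and tests behave
correctly under a faithful-in-structure null and under known injected
bias — not that any particular wild community shows these effects.

## Monte-Carlo problem sizes

Calibration and recovery suites run scaled-down replicates chosen once:
permutation-test calibration uses 1000 replicates of a 10-male /
12-mother / 5-year community (B = 2000); model calibration uses 200
replicates and recovery 100 replicates of a 12-male / 14-mother /
6-year community with reduced follow effort.  Measured behaviour:
permutation and LMM-interaction null rejection rates fall inside
[0.03, 0.07]; the paternity Wald test is conservative as discussed
above; with `father_bias=3, τ=6` the bin-0 adjusted contrast is
significant in ≥ 80% of replicates with significance concentrated in
bins 0–2, and with γ = 2 the coefficient sign is recovered in ≥ 90%.

## Numerical conventions

Zero-spread z sets are flagged, not dropped; undefined proportions
(zero exposure) are excluded from standardization sets; permutation
ties count as exceedances (p includes the observed-equal patterns);
hour filters compare at minute precision, boundary inclusive (30 h =
1800 min); date arithmetic is whole-day with calendar-month windows;
rank ties and all random draws are deterministic given the seed.
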