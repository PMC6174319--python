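# Methods

This note documents the statistical model, the estimators, the synthetic
data the package uses in place of restricted genealogical records, and the
design choices made where the design was genuinely open.

## Data model and sample construction

An individual carries integer calendar years only: birth year, and a death
year or a last-known-alive year (censoring).  All ages are year differences
(attained age = death or last-alive year minus birth year); no month or day
resolution exists anywhere in the package, so every age is accurate to
about half a year.  Sibships are sets of full siblings keyed by the ordered
(mother_id, father_id) pair; a person missing either parent id becomes a
singleton, because an unknown parent cannot confirm full sibship
(mother-only keying is available via `derive_sibships(key="mother")`).

Two filters reproduce a genealogical-database study design:

* **Inclusion** (whole sibships kept or dropped atomically): every sibling
  born on or before the cap year (default 1910), every sibling with a death
  or last-alive year, and both parents resolvable with such years.
* **Score eligibility** (individuals): adoptees are removed, as is anyone
  whose attained age is below the conditioning age (default 40).  "Died
  before 40" is strict — death at exactly 40 stays eligible; it scores 0
  anyway because S(40 | 40) = 1.

Individuals removed by a filter move to an `externals` registry and remain
resolvable as parent references.  This makes both filters idempotent: a
retained child sibship can still prove its parents' information on a second
pass even though the parents' own (founder) sibship was dropped.

## Conditional cohort life tables

Life tables are estimated per sex and 10-year birth cohort (one pooled
open cohort before 1850; the terminal band spans 1900–1910 so 1910 does not
form a one-year cohort).  The estimator is the product-limit (Kaplan–Meier)
estimator left-truncated at the base age 40: only people who attained 40
enter the risk set, deaths are events, last-alive-only records are censored
at their last-alive age, and tied deaths are processed before censorings.
A death at exactly the base age is the conditioning boundary and
contributes nothing.  Survival is stored on an integer age grid with
S(40) = 1; queries between grid ages interpolate log S linearly (piecewise
exponential), and ages beyond the grid carry the last value forward flat.
Where the table reaches 0, scores are truncated at the last strictly
positive tabulated value so record-age individuals stay finite.  A simple
death-count mode (`table_method="empirical"`, deaths only, no censoring
handling) is available as a sensitivity check.

The core estimator accepts continuous ages
(`CohortLifeTable.from_records`); the pedigree-facing builder feeds it
integer year differences.  The package's calibration check builds a table
from 10,000 uncensored draws of the closed-form conditional Gompertz law
through the continuous path, so its < 0.02 sup-norm bound measures
estimator error rather than year-discretization bias.

## The score

With S the matching sex/cohort table, a member with attained age *a*
contributes the exceedance u = −log S(a | 40).  If lifespans follow the
scoring table, u is exactly unit-exponential (the package's null sampler
inverts the same piecewise-exponential interpolation the scorer uses, so
this holds to machine precision up to the table's smallest positive value).
Member contributions are centered and bonused:

    contribution = u − size_penalty + alive_bonus · 1{alive},

with both constants defaulting to 1.  The penalty is the null mean of u, so
a sibship of any size has null-mean FLoSS 0 and the exceedance sum over k
deceased members carries a Gamma(k, 1) null; the alive bonus is
E[u(T) − u(a) | T > a] = 1 under that null (memorylessness), which is what
makes very old *living* siblings raise the score by their expected eventual
exceedance.  The centering is what puts the conventional threshold 7 about
2.5 null standard deviations out for 4-member sibships (a ≈ 2% tail here)
and gives the score a genuine negative tail (FLoSS ≤ −4.5), matching the
reported distribution of the score in large genealogical samples; setting
`size_penalty=0` recovers a plain non-negative exceedance sum in which
larger sibships score mechanically higher.  No other sibship-size
normalization is applied.

Scoring against a reference year recomputes each member's age and vital
status as of that year: someone who died later is treated as alive then
(and receives the bonus); someone censored before the year contributes the
exceedance at their last-alive age without the bonus, since survival to
that age is known but aliveness in the reference year is not.  Members
below the base age as of the reference year are excluded from the sum.

## Survival comparison

All estimation runs on the age scale with delayed entry.  The risk set at
age t comprises records with entry < t ≤ exit, so a subject contributes
only from the age at which they came under observation (their age in the
study year), avoiding immortal-time bias.  The two-sample log-rank test
uses the same truncation-aware risk sets with the tie-corrected
hypergeometric variance and a χ²(1) reference.  Group curves are rescaled
conditional on age 80 and summarized by the restricted mean survival time
RMST(80→95), the exact integral of the step curve (flat carry-forward past
the last event).  Records exiting at or before the conditioning age drop
out, which is the correct conditioning on survival past 80.

**Group construction.**  At the study year (default 1980), everyone alive
and aged 80+ belongs to the comparison; members of sibships with
FLoSS ≥ 7 form the exceptional group and everyone else the ordinary group
(a partition, asserted every run).  The FLoSS used here is by default the
whole-sample score computed from complete lifespans — the score that
defines the selected-family sample — with age and vital status, not the
score, recomputed at the study year.  An `as-of-year` mode that rescores
sibships using only information available at the study year is provided;
note that at a few thousand subjects its ~2%-tail exceptional groups are
small enough that the delayed-entry product-limit curve can collapse when
an early death meets a one- or two-person risk set, so the complete-lifespan
mode is the default.  Offspring born after 1900 are grouped by their
parents' sibship scores (either parent ≥ 7 → exceptional; both < 7 →
ordinary; any parent unscored → excluded rather than defaulted to ordinary,
to avoid contaminating the comparison).  Comparisons are computed per sex
and pooled; the headline numbers are pooled because sex is randomized 50/50
in both groups and the per-sex exceptional groups are small.

## Synthetic data

The generator emulates the structure of a large multigenerational
genealogy with birth years 1779–1910 and mortality follow-up through 2013:

* **Mortality**: Gompertz hazard z·a·e^{bt} from birth with a = 1e-4 per
  year and b = ln 2 / 8 (eight-year mortality doubling), giving a modal
  adult age at death near 80 for the frailty-1 female baseline; males carry
  a 1.35 hazard ratio.
* **Familial clustering**: siblings share a gamma frailty z (mean 1,
  variance 0.3 by default).  An offspring sibship's frailty is
  0.5 × mid-parent frailty + 0.5 × a fresh gamma draw, so sibling lifespan
  correlation (~0.2) clearly exceeds the parent–offspring correlation
  (~0.06), the ordering reported for real genealogies.
* **Structure**: index sibships born 1850–1880 (zero-truncated Poisson
  sizes, rate 4 — matching the ~4.1 members per scored sibship implied by
  published sample counts), their founder parents (so the index generation
  passes the parental-information criterion), and offspring born from
  mother's age 21–40, capped at 1910.  Couples pair index members across
  families.
* **Observation process**: exponential loss to follow-up at rate 0.003 per
  year (~10–20% censored), administrative censoring at 2013, adoption flags
  at 1%, missing vital years at 0.5%.  Death years are birth + round(age),
  so year arithmetic is unbiased to ±0.5 year.

A per-person frailty truth table accompanies every sample for validation
(selection really does pick low-frailty families; increasing the frailty
variance really does spread the score distribution).

What the generator does *not* emulate: child mortality and period shocks
(wars, epidemics), fertility/marriage structure, migration, cohort trends
in the Gompertz parameters, and record-linkage noise.  Passing tests
therefore show that the estimators and the selection logic behave correctly
under the assumed frailty model at realistic scale — not that the model
captures every feature of real genealogical data.

## Numerical and scale choices

* Default analysis scale is 5,000 families (~64,000 individuals, ~1,700
  alive 80+ at the 1980 cross-section, ~8,000 scoreable offspring), chosen
  so a full run takes a few seconds and Monte-Carlo error leaves the
  qualitative contrasts (gap signs, attenuation ordering) stable across
  seeds.
* Null calibration uses 50,000 table-sampled lifespans (standard error
  ~0.0045 on a mean of 1); the life-table limit check uses 10,000 draws
  (binomial sup-norm error well under 0.02).
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the parameter objects; a run is reproducible byte for byte.
* Degenerate inputs: zero-length survival records (exit = entry) are
  discarded with a warning; strata with nobody past the base age raise;
  all-censored strata yield the degenerate S ≡ 1 table; summaries require
  at least two sibships and positive spread.

## Known limitations

* The score form delegates nothing to recruitment logistics: availability
  of living siblings, catchment areas, and enrollment probabilities are out
  of scope.
* No covariate adjustment (no Cox or parametric frailty fitting) and no
  confidence bands on curves; p-values come from the χ²(1) upper tail only.
* Integer-year ages blur every boundary (e.g. "alive at the study year")
  by up to a year relative to exact-date data.
* The `as-of-year` grouping mode is statistically fragile at small
  exceptional-group sizes, as described above.
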