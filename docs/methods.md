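# Methods

## Model and procedure

`trialspend` quantifies public funding of phased clinical development by
record linkage rather than by trial-level budgets, which are rarely public.
The unit of attribution is the *project year*: one fiscal year of funding
for one project, credited when a publication linked to that project appears
in that year.  The procedure has four stages.

1. **Search and classification.**  Drug-synonym matches define applied
   research; target-synonym matches, after excluding any publication also
   matched by a drug search, define basic research (the exclusion makes the
   two sets disjoint by construction).  Trial reports are detected by
   publication-type metatags (any trial/phase tag, not a review, with the
   *human* subject-heading) or by an extractable registry identifier
   (`NCT` + exactly 8 digits; a longer digit run is not an identifier).
   Development research is the phased subset of applied research; trial-like
   publications found only by target searches remain basic research, since
   trial counts are computed over the drug-search corpus.

2. **Phase assignment.**  Candidate phases are pooled from phase metatags
   and from registry lookups of every cited NCT number; the label is the
   maximum under P1 < P2 < P3 < P4.  Registry entries with no phase
   designation — and NCT numbers absent from the registry, which behave
   like unresolvable trials — contribute no candidate; if no candidate
   exists the label is `NCT_OTHER` when an NCT number was cited and
   `UNASSIGNED` otherwise.  `UNASSIGNED` trials are counted as clinical
   trials but excluded from development totals.  The same maximum rule sets
   the phase of a ledger key from its contributing publications; ties
   cannot occur under a total order.

3. **Attribution.**  Publication year `y` against a project funded
   `[start, end]`: `y < start` → excluded (the publication cannot stem from
   funding that had not begun); `start ≤ y ≤ end` → credited to year `y`;
   `end < y ≤ end + L` → credited to year `end` (publication lag);
   `y > end + L` → excluded.  The lag window `L` defaults to 4 years and is
   configurable; totals are monotone non-decreasing in `L`.  Fiscal years
   are modeled as calendar publication years; an integer offset
   (`fiscal_year_offset`) is available for funders whose fiscal year is
   shifted.  Duplicates are eliminated at totalling time: within each
   reported scope a (project, fiscal-year) key counts once.  Per-drug
   tables deduplicate within each drug, so a project year serving two drugs
   appears once per drug but once in the overall total; this is the only
   reading under which per-drug averages over "funded project years only"
   are consistent with a partitioned overall table.  Links whose project
   has no cost row for the assigned year are kept in the audit with status
   `no_cost_row` and contribute zero.  Costs attributed after a drug's
   first approval are included.

4. **Statistics.**  Per-drug profiles exist only for drugs with at least
   one funded development project-year; per-phase means divide by the
   drugs funded *in that phase* (no zero-imputation for unfunded drugs).
   The paired industry comparison is restricted to funded drugs with an
   industry benchmark; within those, a phase with no public funding
   contributes zero — an observed absence, not missing data.  The paired
   *t* reports the mean difference (industry − public) with a 95% interval
   on n−1 degrees of freedom.  Mann-Whitney uses exact enumeration when
   both groups have ≤ 8 untied observations and the tie-corrected normal
   approximation with continuity correction otherwise; a comparison with
   all values identical is vacuous and reported as p = 1.  Detector
   validation treats the consensus of two manual readers as gold
   (disagreements are dropped from sensitivity/specificity; Cohen's κ
   between the readers quantifies them) — the spec-level signature names
   the first argument "truth", and we interpret the automated labels as the
   thing being validated, since readers are the only source of truth
   available in practice.

## Synthetic corpus: what it emulates and what it does not

The generator emulates the *structure* the pipeline consumes: collision-free
drug/target synonyms planted in titles/abstracts, trial signal via metatags
or registered NCT identifiers (a configurable fraction signal their phase
only through the registry), multi-phase tagging at a configurable rate to
exercise the highest-phase rule, review-tagged decoys, project pools with
per-fiscal-year costs, publication years drawn conditionally on the linked
project to realize a configured lag distribution, per-drug industry
benchmarks, designation flags, and an annual inflation index.  It does not
mimic real literature statistics — vocabulary, journal fields, citation
structure, synonym ambiguity (hit-rate collisions exist only in the
optional stress mode), or correlated funding across drugs sharing targets.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic, not the field performance of the search terms, whose
sensitivity/specificity must be validated against manual review on real
corpora (the validation-metrics machinery exists for exactly that).

Ground truth is accumulated independently of the pipeline, by direct
per-link bookkeeping from the generator's own records; per-drug truth sums
exactly to the corpus-wide development total because project pools are
disjoint between drugs and between the drug and target sides.  Real corpora
can violate the corresponding basic+applied conservation when one project
funds publications in both categories; published analyses have had to
exclude drugs for precisely such contamination.

### Default conditions

Rates that published corpus compositions pin down are used as defaults:
9.1% of drug publications report trials; 49.7% of trials are phased; the
phase mix of phased reports is P1 15.2%, P2 27.1%, P3 34.7%, P4 3.6%, and
19.4% registry-only (`NCT_OTHER`); 10.8% of publications carry funder
links; designation prevalences 36/43/13/20/37/54% (first-in-class/orphan/
accelerated/breakthrough/fast-track/priority); industry per-phase benchmark
scales (mean, SD in 2018 M$): phase 1 (54.9, 56.9), phase 2 (103.6, 110.1),
phase 3 (298.3, 272.2), drawn lognormal; base year 2018.

Values no published source states are fixed once as plausible for the
domain: corpus span 1999–2021 with project periods 2002–2014 (duration 3–5
years, so every lag offset up to +7 stays inside the span); 40 drugs × ~200
publications and 25 targets × ~100 publications (desk-scale versions of
corpora three orders of magnitude larger); lag mix 5% before-start, 70%
within-period, 8/6/4/3% at lags 1–4, 4% beyond; per-project-year cost
uniform on (0.5, 5.5) M$ (matching the few-M$ per project-year scale of
published development totals); 15% of funded publications linked to a
second project (exercising multi-link dedup); 10% multi-phase tagging; 40%
registry-only phase signal; 5% review decoys; 2% trial-like target
publications; industry coverage for 60% of drugs.  The inflation index is a
2%-per-year geometric series normalized at 2018 — an input table like any
other, never a built-in deflator.

Noise injection flips the trial signal symmetrically: false negatives strip
all trial metatags and NCT strings; false positives add a phase metatag
(with *human*, dropping *review*).  The detector's expected operating point
under rates (fp, fn) is exactly (1−fn, 1−fp), which is what validation on a
labeled sample recovers up to binomial error.

## Numerical choices

* Currency is carried in millions of USD; inflation adjustment is
  `amount × index(base)/index(year)`, exact at the base year and linear in
  the amount.
* "Exact" recovery is asserted to relative 1e-12: the pipeline sums via
  pandas groupby while the ground truth accumulates in plain dicts, so
  results agree up to float summation order only.
* Percent-of-industry ratios are reported to one decimal; per-phase sums of
  printed one-decimal means are compared at one decimal.
* Mann-Whitney switches from exact enumeration to the normal approximation
  above n = 8 per group; the two agree within 0.02 in that regime (verified
  by full rank-assignment enumeration in the tests).
* Degenerate inputs: empty candidate sets fall through to
  `NCT_OTHER`/`UNASSIGNED`; zero-variance paired differences report p = 1
  (vacuous) rather than NaN; undefined sensitivity/specificity denominators
  are reported as absent with a warning; empty activity codes are input
  errors.
* Problem sizes in the stochastic suites — 1000 replicates of 60 pairs for
  paired-t coverage, 2000 null replicates at n = 50 per group for the
  Mann-Whitney size — give standard errors of about 0.7 and 0.5 percentage
  points, small against the ±2 and ±1.5 point acceptance bands.

## Known limitations

* One project year per publication understates costs of multi-year trials;
  within-period publication lags are not modeled (only the post-period lag
  window), matching the attribution rule as stated.
* The matcher is whole-token and case-insensitive; it does not reproduce
  any particular search engine's Boolean query semantics, stemming, or
  field weighting.  Users can substitute their own hit tables.
* Activity-code categories cover the standard U/P/M01/R/K/T/F families;
  unusual codes fall into `other`.
* The per-drug industry table is a user-supplied input; the package does
  not attempt to reconstitute any published per-drug benchmark set, nor
  does it apply cost-of-failure or cost-of-capital adjustments to industry
  estimates (the comparison is actual spending vs actual spending).
* Absolute headline totals of published analyses require the real
  publication/funding corpora and are out of scope; acceptance rests on
  arithmetic over printed table inputs plus synthetic-recovery and
  calibration properties.
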