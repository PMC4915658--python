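# Methods

## The disproportionality model

Each spontaneous report is reduced to three term sets (drugs, reactions,
indications); every statistic is a function of report counts under boolean
term queries. A report contributes at most one count to any contingency
cell, however many times a term repeats inside it. Terms are canonicalized
by uppercase-folding and whitespace-stripping; matching is exact on the
canonical string. Drugname cleaning, RxNorm/UNII resolution and MedDRA
hierarchy aggregation are deliberately out of scope: they are upstream data
curation problems, and silently fuzzy matching would make counts
irreproducible.

The 2×2 table for a (drug query, event query) pair is derived from four
counts — N, D, E and DE — with the remaining cells obtained by
subtraction. This is not just an optimization: it is the only construction
a count-only backend (the openFDA API) can answer, and using it for the
local store too makes local/remote equivalence hold by construction rather
than by test luck. Cells always sum to the (masked) store size; reports
with empty drug sets stay in the store by default and count toward N, d and
e, because dropping them silently shrinks the background. A
`drop_undrugged` option applies the opposite policy for sensitivity
analysis.

On the table: rate = DE/D, ROR = DE·de/(dE·De), PRR = DE·d/(dE·D),
RRR = DE·N/(E·D), and the Yates-corrected χ². Any division by zero yields a
typed undefined marker (`None`) which propagates — the Evans flag is
undefined whenever PRR or χ² is. No continuity correction is applied to the
ratios by default; a Haldane +0.5 mode exists behind a flag for users who
want finite estimates on zero cells, but it changes the estimand and stays
off.

### Numerical choices

- χ² is evaluated in exact integer arithmetic as
  `N·(2|DE·de − dE·De| − N)² / (4·E·e·D·d)`, so the N/2 continuity term
  never suffers float or integer-division error; the final division is the
  only floating-point step.
- The continuity term is clamped at zero when |DE·de − dE·De| < N/2
  (standard Yates practice; otherwise near-balanced tables would get a
  spurious positive χ²). The unclamped textbook expression is available via
  `clamp=False` for parity experiments.
- The Evans thresholds (PRR > 2, χ² > 4, DE > 3, all strict) are
  configuration with those defaults; none of the screening cut-offs in this
  package is a validated clinical decision limit.

## Clinical screens

**Ranking** sorts a medication list by RRR (descending), ties by rate then
name; undefined RRRs (drug absent) sort last. With a single drug the entry
is numerically identical to the pairwise analysis.

**Profile comparison** excludes combination reports from *both* single-drug
populations — including the event-level counts — so each RRR describes one
drug used without the other; E and N still come from the whole masked
store. The event universe is the union of reactions co-reported with either
combination-excluded population (an event seen only in combination reports
belongs to the interaction screen, not here). The percentage difference is
`(RRR₁ − RRR₂) / mean(RRR₁, RRR₂) × 100`, bounded in ±200 and antisymmetric;
when exactly one RRR is zero the bound ±200 is reported, and when both are
zero (or either undefined) the row carries an undefined marker and is never
selected by cut-offs. Asymmetric cut-offs are supported because different
drug pairs legitimately warrant different screens; ±75 % is the default.

**DDI screen** compares each event's combination rate with the sum of the
single-drug rates, `rate_diff = (rate_D1 + rate_D2) − rate_D1D2`. The sign
convention is fixed: negative = observed above additive expectation
(synergy candidate). Note the additive expectation is biased high for null
events (it approaches twice the baseline rate), so positive rate_diffs of
roughly baseline magnitude are the screen's noise floor — another reason
the default cut-offs (−0.03 / +0.035 on the rate scale) are screening
conventions, not inference. Rows sort by |rate_diff| descending; with zero
combination reports every combination rate is undefined and the result is
flagged instead of silently empty.

**Background correction** conjoins an indication restriction into the mask
of any analysis, restricting N, E, D and DE alike (PRR-by-therapeutic-area
style). The two-stratum test fixture makes the mechanism exact: within each
stratum drug and event are independent (RRR = 1 by construction) while the
pooled RRR is 3.39. **Confounder screening** ranks concomitant drugs and
indications by frequency within the DE subpopulation.

Cut-offs (`min_de`, percentage and rate cut-offs) default to keeping
everything (`min_de=1`) so small offline stores are not silently emptied;
the count-cap phenomenon of the public API is emulated explicitly with
`truncate_counts`, which cuts each per-drug event list at the given rank
and flags the result — demonstrating how real signals vanish below a
backend's term cap.

## Query engine

The store keeps one inverted index per field; conjunctive queries run as
set intersections/differences and are property-tested against an index-free
linear scan. Query conjunction is total: conjoining queries that contradict
each other (a term required by one, forbidden by the other) yields the
unsatisfiable query, which matches nothing — the correct count of a
contradictory restriction is 0, not an exception. Duplicate report ids keep
the last occurrence (the API serves versioned reports); the replaced
version is fully unindexed.

## openFDA client

Search strings are rendered deterministically (sorted terms, each term
explicitly field-qualified, multi-term fields parenthesized, exclusions as
`+AND+NOT+(field:"term")`, `.exact` on reaction/indication fields but not
on substance names — all overridable via `FieldMap`). The service's hard
caps (limit ≤ 100, skip ≤ 5000, ≤ 100 count terms) are enforced at request
construction, and count truncation is surfaced as a flag that propagates
into analysis results. Zero-match searches arrive as HTTP 404 with a
NOT_FOUND body and are interpreted as count 0. The live transport uses the
standard library's HTTP machinery with 3 retries and exponential backoff;
the fixture transport replays recorded JSON responses keyed by the
canonical query string and is the path all tests use. `simulate_fixtures`
fabricates API-shaped responses from a local store — a synthetic stand-in
for recorded live traffic — which is exactly what the dual-backend
equivalence tests need: the claim under test is that the adapter plumbing
is lossless, not that the public database holds particular numbers.

## Synthetic generator

The generator draws reports independently: indications first (Bernoulli per
term), then drugs (marginal probability, multiplied by the drug-multiplier
of present confounder indications), then events (baseline probability times
the multiplier of every present planted-association drug, times confounder
event-multipliers, times the interaction multiplier when both drugs of a
planted pair are present), all probabilities clamped to [0, 1]. Identical
config + seed reproduce the collection byte for byte (single seeded PCG64
stream, fixed draw order).

The multiplicative risk model makes RRR targets plantable analytically:
RRR = P(event|drug)/P(event) = ρ / (1 + P(drug)(ρ − 1)), which approaches
the planted ρ only when the *exposure* is rare, not just the event. The
recovery conditions therefore use P(drug) = 0.02 with a baseline-0.01
event: at ρ = 5 the analytic RRR is 4.63, and the median over 20 seeds at
n = 50,000 is required to fall in [4, 6] (per-seed estimates scatter with
DE ≈ 50). Null calibration uses baseline ≥ 0.02 events so that DE is large
enough for the estimate to concentrate near 1. Probability clamping biases
recovered RRR downward for non-rare events, which is why recovery tests use
rare ones. Drug co-occurrence is independent by default; the only
correlation mechanism is indication-mediated confounding, keeping the null
model clean.

What the generator does *not* emulate: demographics, dates, outcomes,
dosages, duplicate and incomplete reports, reporting waves, and
under-reporting dynamics. Passing recovery tests therefore shows the
estimators and screens are correct under the stated generative model — not
that real FAERS data satisfies that model.

## Problem sizes

Deterministic checks use the two 90/100-report model populations. Oracle
equivalences run on 1,000 random tables (χ² vs an established routine) and
100 random store/query/mask triples (≤ 500 reports). Stochastic recovery
uses 50,000-report collections across 20 seeds, which keeps every
ground-truth event count in the tens-to-hundreds while the full suite runs
in well under a minute for the statistical parts.

## Known limitations

- Exact-string matching means synonymous drugnames count as different
  drugs; this mirrors the raw data's behavior and is intentional.
- The remote backend answers report *counts* only; fetch-based workflows
  (retrieving full report documents beyond the 5,100-report window) are out
  of scope.
- Live openFDA parity of the `+AND+NOT+` dialect is best-effort: the
  emitted dialect is pinned by fixtures, not by a recorded live snapshot.
- No Bayesian shrinkage measures (BCPNN, EBGM) and no confidence intervals
  for ROR/PRR; the package implements the frequentist ratio toolkit only.
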