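# pvsignal

Disproportionality analysis and clinical signal screening for spontaneous
adverse-event report collections (FAERS / openFDA drug-event schema).

Spontaneous reporting systems collect reports that each carry a set of
drugs, a set of MedDRA preferred-term reactions, and the indications the
drugs were given for. Because nobody knows how many exposed patients never
filed a report (the open-world problem), absolute risks cannot be computed —
but *disproportionality* can: is a drug-event pair reported more often than
the rest of the database predicts? `pvsignal` is aimed at
pharmacovigilance analysts and clinical pharmacologists who want these
screens as a scriptable library (and a small CLI) rather than a web form.

## The statistics

Reports are cross-classified by drug usage and event occurrence into a 2×2
table with cells DE, De, dE, de, margins D = DE+De, d = dE+de, E = DE+dE,
e = De+de and total N. On these counts:

- rate = DE / D — event rate among users of the drug
- ROR = (DE·de) / (dE·De) — reporting odds ratio
- PRR = (DE·d) / (dE·D) — proportional reporting ratio
- RRR = (DE·N) / (E·D) — relative reporting ratio (observed / expected)
- χ²(Yates) = N·(|DE·de − dE·De| − N/2)² / (E·e·D·d)

with the conventional Evans signal rule PRR > 2, χ² > 4 (≈ p < 0.05) and
DE > 3. On top of the 2×2 core sit three clinical screens:

1. **Drug ranking** — for one adverse event and a medication list, rank
   drugs by RRR; the top entry is the first discontinuation candidate.
2. **Safety-profile comparison** — for two drugs (combination reports
   excluded from both populations), compare per-event RRRs as
   `(RRR₁ − RRR₂) / mean(RRR₁, RRR₂) × 100 %`, keeping extremes beyond
   configurable cut-offs (±75 % by default).
3. **DDI screen** — per event, `rate_diff = (rate_D1 + rate_D2) −
   rate_D1D2`; strongly negative values (observed combination rate far above
   the additive expectation) flag candidate synergistic interactions.

All analyses accept a background-correction mask (typically an indication)
restricting every cell to a therapeutic subpopulation, which removes
confounding by the treated disease; a confounder screen ranks concomitant
drugs and indications inside the DE subpopulation.

Backends are interchangeable: an in-memory indexed store loaded from
openFDA JSON / NDJSON files, or a count-only remote store that speaks the
openFDA `search`/`count` dialect (live over HTTP, or offline by replaying
recorded fixture responses). A synthetic generator produces collections
with planted associations, confounders and interactions so every screen has
a recoverable ground truth.

## Worked example

```python
from pvsignal import analyze_pair, fixture_model_case
from pvsignal.io import render_text

store = fixture_model_case(2)   # 90 reports, textbook disproportionate table
print(render_text(analyze_pair(store, "DRUGX", "EVENTY")))
```

prints

```
2x2 contingency (reports):
              event E   no-event e   total
  drug D            2            8      10
  no-drug d         8           72      80
  total            10           80      90

rate (DE/D)   = 0.2
ROR           = 2.25
PRR           = 2
RRR           = 1.8
chi2 (Yates)  = 0.1723
Evans signal  = no
```

EVENTY occurred in 20 % of DRUGX users versus 10 % of other-drug users, so
the event is twice as frequent under the drug (PRR = 2) and reported 1.8×
more often than independence predicts (RRR = 1.8); with only DE = 2
co-reports the Evans rule nevertheless stays quiet. The `examples/`
directory has one short script per capability (ranking, profile comparison,
DDI screening, background correction, the API backends), each printing the
numbers it computes and what they mean. The same analyses are available
from the shell:

```sh
pvsignal synth --preset model-case-2 --out case2.ndjson
pvsignal --reports case2.ndjson dpa --drug DRUGX --event EVENTY
```

## Caveats

Disproportionality statistics on spontaneous reports are
hypothesis-generating only: reporting is incomplete, biased and sometimes
miscoded, and no measure here is a population risk. Drugname cleaning and
MedDRA ontology aggregation are out of scope — terms match exactly after
case folding.
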