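"""Pairwise safety-profile comparison of two drugs.

Two drugs with mirror-image planted risks: DRUG1 drives OEDEMA, DRUG2
drives QT PROLONGED.  Reports containing both drugs are excluded from both
single-drug populations, per-event RRRs are compared as a percentage
difference relative to their mean, and only differences beyond +/-75% are
kept — large values point to events tied to one drug but not the other.
"""

from pvsignal import PlantedAssociation, SyntheticConfig, compare_drug_profiles, generate

config = SyntheticConfig(
    n_reports=50_000,
    drug_vocab=(("DRUG1", 0.03), ("DRUG2", 0.03)),
    event_vocab=(("OEDEMA", 0.01), ("QT PROLONGED", 0.01), ("HEADACHE", 0.02)),
    associations=(
        PlantedAssociation("DRUG1", "OEDEMA", 6.0),
        PlantedAssociation("DRUG2", "QT PROLONGED", 6.0),
    ),
    seed=7,
)
store = generate(config)

cmp_ = compare_drug_profiles(store, "DRUG1", "DRUG2", cutoff_lo=-75, cutoff_hi=75)
print(f"{cmp_.drug1} (n={cmp_.d1_total}) vs {cmp_.drug2} (n={cmp_.d2_total}), "
      f"{cmp_.combo_total} combination reports excluded")
for r in cmp_.rows:
    print(f"  {r.event:<14} RRR1={r.rrr1:6.2f}  RRR2={r.rrr2:6.2f}  "
          f"perc_diff={r.perc_diff:+7.1f}%")
print()
print("Positive perc_diff: stronger association with DRUG1; negative with")
print("DRUG2.  HEADACHE (no planted difference) falls inside the cut-offs.")
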