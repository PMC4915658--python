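"""Which drug of a medication list to discontinue first?

Generates a synthetic collection in which DRUGA carries a planted 5x risk
for RASH while DRUGB and DRUGC are null, then ranks the medication list by
relative reporting ratio (RRR) for the event.
"""

from pvsignal import PlantedAssociation, SyntheticConfig, generate, rank_drugs_for_event

config = SyntheticConfig(
    n_reports=50_000,
    drug_vocab=(("DRUGA", 0.02), ("DRUGB", 0.02), ("DRUGC", 0.02)),
    event_vocab=(("RASH", 0.01), ("NAUSEA", 0.02)),
    associations=(PlantedAssociation("DRUGA", "RASH", 5.0),),
    seed=42,
)
store = generate(config)

ranking = rank_drugs_for_event(store, ["DRUGC", "DRUGA", "DRUGB"], "RASH")
print(f"event: {ranking.event}")
for e in ranking.entries:
    print(f"  {e.drug:<8} DE={e.DE:<4} D={e.D:<5} rate={e.rate:.4f}  RRR={e.rrr:.2f}")
print()
print("The drug with the highest RRR is the first candidate to stop:")
print(f"  -> {ranking.entries[0].drug} (planted 5x risk, recovered above)")
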