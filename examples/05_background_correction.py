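"""Confounding by indication, and removing it with background correction.

LEUKEMIA (the indication) drives both SUSPECTDRUG usage and MARROWDAMAGE,
so the global RRR of the drug-event pair is inflated although the drug does
nothing.  Restricting every cell of the 2x2 table to reports carrying the
indication (PRR-by-therapeutic-area style correction) removes the artifact,
and the confounder screen points at the indication.
"""

from pvsignal import (
    PlantedConfounder,
    SyntheticConfig,
    analyze_pair,
    background_corrected,
    confounder_screen,
    generate,
)

config = SyntheticConfig(
    n_reports=50_000,
    drug_vocab=(("SUSPECTDRUG", 0.01),),
    event_vocab=(("MARROWDAMAGE", 0.005),),
    indication_vocab=(("LEUKEMIA", 0.02), ("COLD", 0.10)),
    confounders=(
        PlantedConfounder("LEUKEMIA", "SUSPECTDRUG", "MARROWDAMAGE",
                          drug_multiplier=30.0, event_multiplier=30.0),
    ),
    seed=3,
)
store = generate(config)

naive = analyze_pair(store, "SUSPECTDRUG", "MARROWDAMAGE")
corrected = background_corrected(
    store, analyze_pair, "LEUKEMIA", "SUSPECTDRUG", "MARROWDAMAGE"
)
print(f"global RRR    = {naive.rrr:.2f}   (confounded: looks like a strong signal)")
print(f"corrected RRR = {corrected.rrr:.2f}   (within the LEUKEMIA stratum)")
print()
screen = confounder_screen(store, "SUSPECTDRUG", "MARROWDAMAGE", top_k=3)
print(f"co-indications within the {screen.n_de} drug+event reports:")
for term, count, frac in screen.co_indications:
    print(f"  {term:<10} {count:>4} reports  ({frac:.0%} of DE)")
print()
print("The corrected RRR near 1 shows the association is carried by the")
print("underlying disease, not the drug.")
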