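"""Basic 2x2 disproportionality analysis on a textbook population.

Builds the 90-report model population in which 20% of DRUGX users but only
10% of other-drug users experienced EVENTY, and runs the full analysis.
"""

from pvsignal import analyze_pair, fixture_model_case
from pvsignal.io import render_text

store = fixture_model_case(2)
result = analyze_pair(store, "DRUGX", "EVENTY")
print(render_text(result))
print()
print("RRR > 1 means the pair is reported more often than independence")
print("would predict; here the event is about twice as frequent among")
print("DRUGX users (PRR = 2), but DE <= 3 so the Evans rule stays quiet.")
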