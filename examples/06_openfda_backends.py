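"""Running the same analysis against a local store and an API-style backend.

Shows the openFDA search strings the client constructs, records simulated
API responses for them into a fixture directory, and verifies that the
count-only remote backend reproduces the local contingency table exactly.
Point RemoteStore at an HttpTransport instead to query the live service.
"""

import tempfile

from pvsignal import (
    FixtureTransport,
    Query,
    RemoteStore,
    SyntheticConfig,
    build_contingency,
    build_search_string,
    generate,
    simulate_fixtures,
)
from pvsignal.openfda import dpa_query_set

q = Query.drugs("diazepam", "haloperidol") & Query.reactions("pain")
print("constructed search string:")
print(" ", build_search_string(q))
print()

store = generate(SyntheticConfig(
    n_reports=10_000,
    drug_vocab=(("DIAZEPAM", 0.05), ("HALOPERIDOL", 0.04)),
    event_vocab=(("PAIN", 0.03),),
    seed=1,
))

with tempfile.TemporaryDirectory() as fixtures:
    transport = FixtureTransport(fixtures)
    simulate_fixtures(transport, store, queries=dpa_query_set("DIAZEPAM", "PAIN"))
    remote = RemoteStore(transport)
    local_table = build_contingency(store, "DIAZEPAM", "PAIN")
    remote_table = build_contingency(remote, "DIAZEPAM", "PAIN")

print("local backend :", local_table)
print("remote backend:", remote_table)
print("identical     :", local_table == remote_table)
print()
print("The remote backend needs only four total-count requests per 2x2")
print("table (N, D, E, DE); the other cells follow by subtraction.")
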