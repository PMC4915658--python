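"""Shared fixtures: randomized stores, brute-force oracles, constructed strata."""

from __future__ import annotations

import random

import pytest

from pvsignal import Query, ReportStore, SafetyReport

DRUG_TERMS = [f"DRUG{c}" for c in "ABCDEF"]
EVENT_TERMS = [f"EVENT{c}" for c in "ABCDEF"]
IND_TERMS = [f"IND{c}" for c in "ABC"]


def make_random_store(rng: random.Random, n_reports: int) -> ReportStore:
    reports = []
    for i in range(n_reports):
        reports.append(
            SafetyReport(
                report_id=f"R{i:05d}",
                drugs=frozenset(t for t in DRUG_TERMS if rng.random() < 0.25),
                reactions=frozenset(t for t in EVENT_TERMS if rng.random() < 0.25),
                indications=frozenset(t for t in IND_TERMS if rng.random() < 0.2),
            )
        )
    return ReportStore(reports)


def make_random_query(rng: random.Random) -> Query:
    """A valid random query: per field, required and forbidden terms disjoint."""
    kwargs = {}
    for fld, vocab in (("drug", DRUG_TERMS), ("reaction", EVENT_TERMS),
                       ("indication", IND_TERMS)):
        pool = list(vocab)
        rng.shuffle(pool)
        n_all = rng.randint(0, 2)
        n_none = rng.randint(0, 2)
        kwargs[f"{fld}_all"] = frozenset(pool[:n_all])
        kwargs[f"{fld}_none"] = frozenset(pool[n_all:n_all + n_none])
    return Query(**kwargs)


def brute_count(store: ReportStore, query: Query, mask: Query | None = None) -> int:
    """Index-free linear scan; the oracle the indexed engine must match."""
    return sum(
        1
        for r in store
        if (mask is None or mask.matches(r)) and query.matches(r)
    )


def stratified_store() -> ReportStore:
    """Two-stratum collection with exact within-stratum independence.

    Stratum CANCER (200 reports): drug and event both at 90%, independent —
    180 drug users, 180 events, 162 overlapping.  Stratum HEADACHE (800
    reports): both at 5% — 40, 40, 2 overlapping.  Within each stratum the
    RRR is exactly 1, but pooling the strata inflates the global RRR to
    164*1000/(220*220) = 3.39: textbook confounding by indication.
    """
    reports = []

    def emit(n, ind, has_drug, has_event):
        for _ in range(n):
            reports.append(
                SafetyReport(
                    report_id=f"S{len(reports):04d}",
                    drugs=frozenset({"DRUGZ"} if has_drug else {"OTHERDRUG"}),
                    reactions=frozenset({"EVENTQ"} if has_event else {"OTHEREVENT"}),
                    indications=frozenset({ind}),
                )
            )

    # CANCER stratum: DE=162, De=18, dE=18, de=2
    emit(162, "CANCER", True, True)
    emit(18, "CANCER", True, False)
    emit(18, "CANCER", False, True)
    emit(2, "CANCER", False, False)
    # HEADACHE stratum: DE=2, De=38, dE=38, de=722
    emit(2, "HEADACHE", True, True)
    emit(38, "HEADACHE", True, False)
    emit(38, "HEADACHE", False, True)
    emit(722, "HEADACHE", False, False)
    return ReportStore(reports)


@pytest.fixture
def simpson_store() -> ReportStore:
    return stratified_store()
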