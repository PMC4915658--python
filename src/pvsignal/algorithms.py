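"""Clinical decision algorithms built on disproportionality analysis.

Three screening questions, each answered with rates and relative reporting
ratios (RRR) extracted from a report store:

1. **Drug ranking** — given one adverse event and a medication list, which
   drug should be considered for discontinuation first?  The drug with the
   highest RRR (observed/expected reporting) for the event ranks first.
2. **Safety-profile comparison** — given two drugs of similar indication,
   which events are disproportionately tied to one of them?  Reports with
   the *combination* of both drugs are excluded from both single-drug
   populations, then per-event RRRs are compared as a percentage difference
   relative to their mean, so an RRR pair (1, 2) is a large difference
   (-66.7%) while (100, 101) is chance-level (-1%).
3. **Drug-drug-interaction screen** — is an event with the combination more
   or less frequent than the sum of the single-drug rates?  A combination
   rate far above the additive expectation (negative ``rate_diff``) flags
   candidate synergy; far below, antagonism.

All of these accept a background-correction mask (typically an indication),
restricting every count — N, D, E, DE — to a therapeutic subpopulation to
blunt confounding by the treated disease.  Cut-offs are configuration: there
is no consensus on clinically significant thresholds, so the defaults are
conventional screening values, not validated decision limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

from .contingency import build_contingency, rate, rrr
from .reports import Query, TermCounts, normalize_term

logger = logging.getLogger("pvsignal")

__all__ = [
    "DrugRankingEntry",
    "DrugRanking",
    "ProfileRow",
    "ProfileComparison",
    "DdiRow",
    "DdiScreen",
    "ConfounderScreen",
    "rank_drugs_for_event",
    "compare_drug_profiles",
    "ddi_screen",
    "background_corrected",
    "confounder_screen",
    "rrr_perc_diff",
]

#: Default percentage-difference cut-offs for profile comparison.
DEFAULT_PERC_CUTOFFS = (-75.0, 75.0)
#: Default rate-difference cut-offs for the DDI screen (rate scale).
DEFAULT_RATE_CUTOFFS = (-0.03, 0.035)


# ---------------------------------------------------------------------------
# Algorithm 1: which drug to discontinue first
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugRankingEntry:
    drug: str
    DE: int
    D: int
    rate: float | None
    rrr: float | None


@dataclass(frozen=True)
class DrugRanking:
    """Per-drug event association strengths, strongest candidate first."""

    event: str
    entries: tuple[DrugRankingEntry, ...]


def rank_drugs_for_event(
    store,
    drugs: Sequence[str],
    event: str,
    mask: Query | None = None,
) -> DrugRanking:
    """Rank a medication list by RRR for one adverse event.

    For each drug a 2x2 table against the event is built within ``mask`` and
    rate and RRR computed; entries are sorted by RRR descending, ties broken
    by rate descending then drug name ascending.  Drugs with undefined RRR
    (absent from the store) sort last.
    """
    if not drugs:
        raise ValueError("at least one drug is required")
    event = normalize_term(event)
    if not event:
        raise ValueError("event term must be non-empty")
    entries = []
    for drug in drugs:
        t = build_contingency(store, Query.drugs(drug), Query.reactions(event), mask)
        entries.append(
            DrugRankingEntry(
                drug=normalize_term(drug), DE=t.DE, D=t.D, rate=rate(t), rrr=rrr(t)
            )
        )
    entries.sort(
        key=lambda en: (
            en.rrr is None,
            -(en.rrr if en.rrr is not None else 0.0),
            en.rate is None,
            -(en.rate if en.rate is not None else 0.0),
            en.drug,
        )
    )
    return DrugRanking(event=event, entries=tuple(entries))


# ---------------------------------------------------------------------------
# Algorithm 2: safety-profile comparison of two drugs
# ---------------------------------------------------------------------------

def rrr_perc_diff(rrr1: float | None, rrr2: float | None) -> float | None:
    """Percentage difference of two RRRs relative to their mean.

    ``(rrr1 - rrr2) / mean(rrr1, rrr2) * 100`` — bounded in [-200, +200] and
    antisymmetric.  When exactly one RRR is 0 the formula's limit ±200 is
    returned; when both are 0 or either is undefined, None.
    """
    if rrr1 is None or rrr2 is None:
        return None
    if rrr1 == 0 and rrr2 == 0:
        return None
    return (rrr1 - rrr2) / ((rrr1 + rrr2) / 2.0) * 100.0


@dataclass(frozen=True)
class ProfileRow:
    event: str
    DE1: int
    DE2: int
    rate1: float | None
    rate2: float | None
    rrr1: float | None
    rrr2: float | None
    perc_diff: float | None


@dataclass(frozen=True)
class ProfileComparison:
    drug1: str
    drug2: str
    rows: tuple[ProfileRow, ...]
    d1_total: int  #: reports with drug1 but not drug2 (combination excluded)
    d2_total: int  #: reports with drug2 but not drug1
    combo_total: int  #: reports with both drugs
    truncated: bool = False  #: event universe was cut at a count limit

    def __iter__(self) -> Iterator[ProfileRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def _event_universe(store, restricts: list[Query], mask, limit) -> tuple[list[str], bool]:
    events: set[str] = set()
    truncated = False
    for q in restricts:
        tc: TermCounts = store.list_terms("reaction", q & mask if mask else q, limit=limit)
        truncated |= tc.truncated
        events.update(t for t, _ in tc)
    return sorted(events), truncated


def compare_drug_profiles(
    store,
    drug1: str,
    drug2: str,
    mask: Query | None = None,
    *,
    min_de: int = 1,
    cutoff_lo: float = DEFAULT_PERC_CUTOFFS[0],
    cutoff_hi: float = DEFAULT_PERC_CUTOFFS[1],
    include_all: bool = False,
    truncate_counts: int | None = None,
) -> ProfileComparison:
    """Compare the adverse-event safety profiles of two drugs.

    Reports with the drug combination are excluded from both single-drug
    populations (and from the event-level counts), so each RRR reflects one
    drug used without the other; RRR denominators (E, N) come from the whole
    masked store.  The event universe is the union of reactions co-reported
    with either drug.  Rows with ``DE1 + DE2 < min_de`` are dropped; unless
    ``include_all``, only rows with ``perc_diff <= cutoff_lo`` or
    ``>= cutoff_hi`` are returned (asymmetric cut-offs are legitimate —
    different drug pairs warrant different screens).  ``truncate_counts``
    emulates a backend that caps term lists (openFDA's 100), demonstrating
    how real signals can vanish below the cap.
    """
    drug1, drug2 = normalize_term(drug1), normalize_term(drug2)
    if drug1 == drug2:
        raise ValueError("drug1 and drug2 must differ")
    d1q = Query.drugs(drug1, exclude=[drug2])
    d2q = Query.drugs(drug2, exclude=[drug1])
    comboq = Query.drugs(drug1, drug2)
    d1_total = store.count(d1q, mask)
    d2_total = store.count(d2q, mask)
    combo_total = store.count(comboq, mask)
    events, truncated = _event_universe(store, [d1q, d2q], mask, truncate_counts)

    rows = []
    for ev in events:
        evq = Query.reactions(ev)
        t1 = build_contingency(store, d1q, evq, mask)
        t2 = build_contingency(store, d2q, evq, mask)
        if t1.DE + t2.DE < min_de:
            continue
        r1, r2 = rrr(t1), rrr(t2)
        rows.append(
            ProfileRow(
                event=ev,
                DE1=t1.DE,
                DE2=t2.DE,
                rate1=rate(t1),
                rate2=rate(t2),
                rrr1=r1,
                rrr2=r2,
                perc_diff=rrr_perc_diff(r1, r2),
            )
        )
    if not include_all:
        rows = [
            r
            for r in rows
            if r.perc_diff is not None
            and (r.perc_diff <= cutoff_lo or r.perc_diff >= cutoff_hi)
        ]
    rows.sort(
        key=lambda r: (
            r.perc_diff is None,
            -abs(r.perc_diff) if r.perc_diff is not None else 0.0,
            r.event,
        )
    )
    return ProfileComparison(
        drug1=drug1,
        drug2=drug2,
        rows=tuple(rows),
        d1_total=d1_total,
        d2_total=d2_total,
        combo_total=combo_total,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Algorithm 3: drug-drug-interaction screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdiRow:
    event: str
    DE1: int
    DE2: int
    DE_combo: int
    rate_d1: float | None
    rate_d2: float | None
    rate_combo: float | None

    @property
    def expected(self) -> float | None:
        """Additive expectation: sum of the single-drug rates."""
        if self.rate_d1 is None or self.rate_d2 is None:
            return None
        return self.rate_d1 + self.rate_d2

    @property
    def rate_diff(self) -> float | None:
        """Expected minus observed combination rate.

        Negative when the combination exceeds the additive expectation
        (synergy candidate); positive when it falls short (antagonism
        candidate).
        """
        exp = self.expected
        if exp is None or self.rate_combo is None:
            return None
        return exp - self.rate_combo


@dataclass(frozen=True)
class DdiScreen:
    drug1: str
    drug2: str
    rows: tuple[DdiRow, ...]
    d1_total: int
    d2_total: int
    combo_total: int
    truncated: bool = False

    def __iter__(self) -> Iterator[DdiRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def no_combination_reports(self) -> bool:
        """True when the two drugs are never co-reported; every combination
        rate (hence every rate_diff) is then undefined."""
        return self.combo_total == 0


def ddi_screen(
    store,
    drug1: str,
    drug2: str,
    mask: Query | None = None,
    *,
    min_de: int = 1,
    cutoff_lo: float = DEFAULT_RATE_CUTOFFS[0],
    cutoff_hi: float = DEFAULT_RATE_CUTOFFS[1],
    include_all: bool = False,
    truncate_counts: int | None = None,
) -> DdiScreen:
    """Screen a drug pair for interaction candidates, event by event.

    Single-drug rates are computed on the combination-excluded populations,
    the combination rate on reports carrying both drugs; ``rate_diff =
    (rate_d1 + rate_d2) - rate_combo`` per row.  Unless ``include_all``,
    rows are kept when rate_diff <= ``cutoff_lo`` or >= ``cutoff_hi``
    (defaults -0.03 / +0.035 on the rate scale), sorted by \\|rate_diff\\|
    descending.  With zero combination reports all combination rates are
    undefined and all rows are returned, flagged via
    :attr:`DdiScreen.no_combination_reports`.
    """
    drug1, drug2 = normalize_term(drug1), normalize_term(drug2)
    if drug1 == drug2:
        raise ValueError("drug1 and drug2 must differ")
    d1q = Query.drugs(drug1, exclude=[drug2])
    d2q = Query.drugs(drug2, exclude=[drug1])
    comboq = Query.drugs(drug1, drug2)
    d1_total = store.count(d1q, mask)
    d2_total = store.count(d2q, mask)
    combo_total = store.count(comboq, mask)
    events, truncated = _event_universe(store, [d1q, d2q, comboq], mask, truncate_counts)

    rows = []
    for ev in events:
        evq = Query.reactions(ev)
        de1 = store.count(d1q & evq, mask)
        de2 = store.count(d2q & evq, mask)
        dec = store.count(comboq & evq, mask)
        if de1 + de2 < min_de:
            continue
        rows.append(
            DdiRow(
                event=ev,
                DE1=de1,
                DE2=de2,
                DE_combo=dec,
                rate_d1=de1 / d1_total if d1_total else None,
                rate_d2=de2 / d2_total if d2_total else None,
                rate_combo=dec / combo_total if combo_total else None,
            )
        )
    if not include_all and combo_total > 0:
        rows = [
            r
            for r in rows
            if r.rate_diff is not None
            and (r.rate_diff <= cutoff_lo or r.rate_diff >= cutoff_hi)
        ]
    rows.sort(
        key=lambda r: (
            r.rate_diff is None,
            -abs(r.rate_diff) if r.rate_diff is not None else 0.0,
            r.event,
        )
    )
    return DdiScreen(
        drug1=drug1,
        drug2=drug2,
        rows=tuple(rows),
        d1_total=d1_total,
        d2_total=d2_total,
        combo_total=combo_total,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Background correction and confounder screening
# ---------------------------------------------------------------------------

def background_corrected(
    store,
    analysis: Callable,
    indication: str | Query,
    *args,
    mask: Query | None = None,
    **kwargs,
):
    """Run ``analysis`` restricted to reports carrying an indication.

    The correction (PRR-by-therapeutic-area style) restricts N, E, D and DE
    alike to the therapeutic subpopulation, removing confounding by the
    treated disease: if the drug and event are independent *within* the
    indication, the corrected RRR is ~1 even when the global RRR is
    inflated.  ``analysis`` is any of this package's analysis callables
    taking ``(store, ..., mask=...)``; an explicit ``mask`` is conjoined
    with the indication restriction.  A warning is logged when the
    indication matches no report (every measure will be undefined).
    """
    if isinstance(indication, Query):
        ind_mask = indication
    else:
        ind_mask = Query.indications(indication)
    if store.count(ind_mask) == 0:
        logger.warning(
            "background-correction mask %r matches no report; results will be undefined",
            indication,
        )
    return analysis(store, *args, mask=ind_mask & mask, **kwargs)


@dataclass(frozen=True)
class ConfounderScreen:
    """Concomitant drugs and indications inside the DE subpopulation.

    Each list holds ``(term, report_count, fraction_of_DE)`` ranked by
    frequency.  A co-medication or shared indication appearing in most DE
    reports is a confounding candidate: it, rather than the index drug, may
    drive the event.
    """

    drug: str
    event: str
    n_de: int
    co_drugs: tuple[tuple[str, int, float], ...]
    co_indications: tuple[tuple[str, int, float], ...]

    @property
    def empty(self) -> bool:
        return self.n_de == 0


def confounder_screen(
    store,
    drug: str,
    event: str,
    top_k: int = 10,
    mask: Query | None = None,
) -> ConfounderScreen:
    """Rank concomitant drugs / indications within the drug+event reports."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    drug = normalize_term(drug)
    event = normalize_term(event)
    de_query = Query(drug_all=frozenset({drug}), reaction_all=frozenset({event}))
    n_de = store.count(de_query, mask)
    if n_de == 0:
        return ConfounderScreen(drug, event, 0, (), ())

    restrict = de_query & mask if mask else de_query

    def top(field_name: str, exclude: str | None) -> tuple[tuple[str, int, float], ...]:
        terms = store.list_terms(field_name, restrict)
        ranked = [
            (t, n, n / n_de) for t, n in terms if t != exclude
        ]
        return tuple(ranked[:top_k])

    return ConfounderScreen(
        drug=drug,
        event=event,
        n_de=n_de,
        co_drugs=top("drug", drug),
        co_indications=top("indication", None),
    )
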