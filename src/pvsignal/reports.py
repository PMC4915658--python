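"""Safety-report data model, indexed store and boolean query engine.

A spontaneous safety report is reduced to three term sets: the normalized
substance names of the drugs taken, the MedDRA preferred terms (PTs) of the
reactions observed, and the PTs of the indications the drugs were given for.
Every disproportionality statistic downstream is a function of *report
counts* under boolean term queries, so the store keeps inverted indexes from
term to report id and answers conjunctive queries with set algebra.

Terms are canonicalized on ingest and on query construction: uppercase-folded
and stripped of surrounding whitespace (openFDA reaction PTs are
conventionally uppercase, user input is mixed-case). Matching is exact on
the normalized string; no fuzzy matching or drugname cleaning is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger("pvsignal")

#: Queryable term fields of a report.
FIELDS = ("drug", "reaction", "indication")


def normalize_term(term: str) -> str:
    """Canonical form of a drug/reaction/indication term."""
    return term.strip().upper()


def _normset(terms: Iterable[str] | None) -> frozenset[str]:
    if terms is None:
        return frozenset()
    out = frozenset(normalize_term(t) for t in terms)
    return out - {""}


@dataclass(frozen=True)
class SafetyReport:
    """One spontaneous report: an id plus drug / reaction / indication sets.

    ``indications`` is the union over the report's drug entries.  Any of the
    three sets may be empty — source data contains reports without a cleaned
    drugname, and they still count toward the complementary cells of a
    contingency table unless explicitly dropped.

    ``uncleaned_drugs`` marks drug names that were taken verbatim from
    ``medicinalproduct`` because no cleaned ``substance_name`` was available.
    """

    report_id: str
    drugs: frozenset[str] = frozenset()
    reactions: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()
    uncleaned_drugs: frozenset[str] = frozenset()
    raw: Mapping | None = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        object.__setattr__(self, "drugs", _normset(self.drugs))
        object.__setattr__(self, "reactions", _normset(self.reactions))
        object.__setattr__(self, "indications", _normset(self.indications))
        object.__setattr__(self, "uncleaned_drugs", _normset(self.uncleaned_drugs))

    def terms(self, field_name: str) -> frozenset[str]:
        if field_name == "drug":
            return self.drugs
        if field_name == "reaction":
            return self.reactions
        if field_name == "indication":
            return self.indications
        raise ValueError(f"unknown field {field_name!r}; expected one of {FIELDS}")


@dataclass(frozen=True)
class Query:
    """Conjunctive boolean filter over report term sets.

    A report matches when every term in each ``*_all`` set is present in the
    corresponding field and every term in each ``*_none`` set is absent.  An
    empty query matches every report.  A term may not be both required and
    forbidden in the same field.
    """

    drug_all: frozenset[str] = frozenset()
    drug_none: frozenset[str] = frozenset()
    reaction_all: frozenset[str] = frozenset()
    reaction_none: frozenset[str] = frozenset()
    indication_all: frozenset[str] = frozenset()
    indication_none: frozenset[str] = frozenset()
    #: set only by :meth:`__and__` when two satisfiable queries contradict
    #: each other; an unsatisfiable query matches nothing.
    unsat: bool = False

    def __post_init__(self) -> None:
        for fld in FIELDS:
            pos = _normset(getattr(self, f"{fld}_all"))
            neg = _normset(getattr(self, f"{fld}_none"))
            clash = pos & neg
            if clash:
                raise ValueError(
                    f"terms {sorted(clash)} both required and forbidden on field {fld!r}"
                )
            object.__setattr__(self, f"{fld}_all", pos)
            object.__setattr__(self, f"{fld}_none", neg)

    # -- constructors ------------------------------------------------------
    @classmethod
    def drugs(cls, *terms: str, exclude: Iterable[str] = ()) -> "Query":
        return cls(drug_all=frozenset(terms), drug_none=frozenset(exclude))

    @classmethod
    def reactions(cls, *terms: str, exclude: Iterable[str] = ()) -> "Query":
        return cls(reaction_all=frozenset(terms), reaction_none=frozenset(exclude))

    @classmethod
    def indications(cls, *terms: str, exclude: Iterable[str] = ()) -> "Query":
        return cls(indication_all=frozenset(terms), indication_none=frozenset(exclude))

    # -- algebra -----------------------------------------------------------
    def __and__(self, other: "Query | None") -> "Query":
        """Conjunction of two queries (used to fold masks into queries).

        Total: when the two queries contradict each other (a term required
        by one and forbidden by the other), the result is the unsatisfiable
        query, which matches no report, rather than an error — the count of
        a contradictory conjunction is legitimately 0.
        """
        if other is None:
            return self
        if self.unsat or other.unsat:
            return Query(unsat=True)
        for fld in FIELDS:
            if (getattr(self, f"{fld}_all") & getattr(other, f"{fld}_none")) or (
                getattr(self, f"{fld}_none") & getattr(other, f"{fld}_all")
            ):
                return Query(unsat=True)
        return Query(
            drug_all=self.drug_all | other.drug_all,
            drug_none=self.drug_none | other.drug_none,
            reaction_all=self.reaction_all | other.reaction_all,
            reaction_none=self.reaction_none | other.reaction_none,
            indication_all=self.indication_all | other.indication_all,
            indication_none=self.indication_none | other.indication_none,
        )

    def is_empty(self) -> bool:
        return not self.unsat and not any(
            getattr(self, f"{fld}_{kind}") for fld in FIELDS for kind in ("all", "none")
        )

    def matches(self, report: SafetyReport) -> bool:
        """Direct (index-free) evaluation; the oracle the indexes must agree with."""
        if self.unsat:
            return False
        for fld in FIELDS:
            have = report.terms(fld)
            if not getattr(self, f"{fld}_all") <= have:
                return False
            if getattr(self, f"{fld}_none") & have:
                return False
        return True


class TermCounts(list):
    """``list`` of ``(term, report_count)`` with a truncation flag.

    ``truncated`` is True when the list was cut at a backend or caller limit
    (e.g. the openFDA count-endpoint cap of 100 terms), meaning rarer terms
    are silently missing.
    """

    def __init__(self, items: Iterable[tuple[str, int]] = (), truncated: bool = False):
        super().__init__(items)
        self.truncated = truncated


class ReportStore:
    """In-memory indexed collection of :class:`SafetyReport`.

    Maintains an inverted index per field (term -> set of report ids) so
    conjunctive counting queries run as set intersections/differences rather
    than linear scans.  Duplicate report ids keep the last occurrence (a
    warning is logged); openFDA serves versioned reports and deeper
    deduplication is out of scope.

    Parameters
    ----------
    reports:
        Initial reports to add.
    drop_undrugged:
        When True, reports whose drug set is empty are excluded instead of
        counting toward N, d and e.  Both policies are legitimate: uncleaned
        reports distort the complementary cells, but dropping them shrinks
        the background.
    """

    def __init__(
        self,
        reports: Iterable[SafetyReport] = (),
        *,
        drop_undrugged: bool = False,
    ) -> None:
        self.drop_undrugged = drop_undrugged
        self._reports: dict[str, SafetyReport] = {}
        self._index: dict[str, dict[str, set[str]]] = {f: {} for f in FIELDS}
        for r in reports:
            self.add(r)

    # -- mutation ----------------------------------------------------------
    def add(self, report: SafetyReport) -> None:
        if self.drop_undrugged and not report.drugs:
            return
        if report.report_id in self._reports:
            logger.warning(
                "duplicate safetyreportid %s: keeping last occurrence", report.report_id
            )
            self._unindex(self._reports[report.report_id])
        self._reports[report.report_id] = report
        for fld in FIELDS:
            idx = self._index[fld]
            for term in report.terms(fld):
                idx.setdefault(term, set()).add(report.report_id)

    def _unindex(self, report: SafetyReport) -> None:
        for fld in FIELDS:
            idx = self._index[fld]
            for term in report.terms(fld):
                ids = idx.get(term)
                if ids:
                    ids.discard(report.report_id)
                    if not ids:
                        del idx[term]

    # -- introspection -----------------------------------------------------
    def __len__(self) -> int:
        return len(self._reports)

    def __iter__(self) -> Iterator[SafetyReport]:
        return iter(self._reports.values())

    def __contains__(self, report_id: str) -> bool:
        return report_id in self._reports

    def get(self, report_id: str) -> SafetyReport | None:
        return self._reports.get(report_id)

    def index_ids(self, field_name: str, term: str) -> frozenset[str]:
        if field_name not in FIELDS:
            raise ValueError(f"unknown field {field_name!r}; expected one of {FIELDS}")
        return frozenset(self._index[field_name].get(normalize_term(term), ()))

    # -- queries -----------------------------------------------------------
    def _match_ids(self, query: Query, mask: Query | None = None) -> set[str]:
        q = query & mask
        if q.unsat:
            return set()
        ids: set[str] | None = None
        for fld in FIELDS:
            idx = self._index[fld]
            for term in getattr(q, f"{fld}_all"):
                hit = idx.get(term, set())
                ids = set(hit) if ids is None else ids & hit
                if not ids:
                    return set()
        if ids is None:  # no positive conjunct: start from everything
            ids = set(self._reports)
        for fld in FIELDS:
            idx = self._index[fld]
            for term in getattr(q, f"{fld}_none"):
                ids -= idx.get(term, set())
        return ids

    def count(self, query: Query, mask: Query | None = None) -> int:
        """Number of reports matching ``query`` (within ``mask`` when given)."""
        return len(self._match_ids(query, mask))

    def fetch(self, query: Query, mask: Query | None = None) -> list[SafetyReport]:
        """The matching reports themselves, in insertion order."""
        ids = self._match_ids(query, mask)
        return [r for r in self._reports.values() if r.report_id in ids]

    def list_terms(
        self,
        field_name: str,
        restrict: Query | None = None,
        *,
        limit: int | None = None,
    ) -> TermCounts:
        """Distinct terms of a field with their report counts.

        Sorted by count descending, ties by ascending term.  ``restrict``
        narrows the counted population; ``limit`` truncates the list (the
        result's ``truncated`` flag records that rarer terms were dropped,
        mirroring the openFDA count cap).
        """
        if field_name not in FIELDS:
            raise ValueError(f"unknown field {field_name!r}; expected one of {FIELDS}")
        if restrict is None or restrict.is_empty():
            pairs = [(t, len(ids)) for t, ids in self._index[field_name].items()]
        else:
            pop = self._match_ids(restrict)
            pairs = [
                (t, n)
                for t, ids in self._index[field_name].items()
                if (n := len(ids & pop)) > 0
            ]
        pairs.sort(key=lambda tc: (-tc[1], tc[0]))
        truncated = limit is not None and len(pairs) > limit
        if truncated:
            pairs = pairs[:limit]
        return TermCounts(pairs, truncated=truncated)


# -- module-level operation aliases (store-agnostic call style) -------------

def count_reports(store, query: Query, mask: Query | None = None) -> int:
    """``store.count`` for any backend honoring the store contract."""
    return store.count(query, mask)


def list_terms(store, field_name: str, restrict: Query | None = None, **kw) -> TermCounts:
    return store.list_terms(field_name, restrict, **kw)


# -- openFDA JSON ingest ----------------------------------------------------

def parse_openfda_report(obj: Mapping) -> SafetyReport | None:
    """Build a :class:`SafetyReport` from one openFDA drug-event result object.

    Drugs come from ``patient.drug[].openfda.substance_name`` (a drug entry
    may map to several substances — all are kept); when an entry has no
    cleaned substance name, ``medicinalproduct`` is used verbatim and flagged
    uncleaned.  Reactions come from ``patient.reaction[].reactionmeddrapt``,
    indications from ``patient.drug[].drugindication``.  Returns None (after
    logging) when ``safetyreportid`` is missing.
    """
    rid = obj.get("safetyreportid")
    if rid is None or str(rid).strip() == "":
        logger.warning("skipping report without safetyreportid: %.80r", obj)
        return None
    patient = obj.get("patient") or {}
    drugs: set[str] = set()
    uncleaned: set[str] = set()
    indications: set[str] = set()
    for entry in patient.get("drug") or []:
        if not isinstance(entry, Mapping):
            continue
        names = (entry.get("openfda") or {}).get("substance_name") or []
        if isinstance(names, str):
            names = [names]
        if names:
            drugs.update(names)
        elif entry.get("medicinalproduct"):
            drugs.add(entry["medicinalproduct"])
            uncleaned.add(entry["medicinalproduct"])
        # generic_name is a secondary cleaned field; merge it when present
        generics = (entry.get("openfda") or {}).get("generic_name") or []
        if isinstance(generics, str):
            generics = [generics]
        drugs.update(generics)
        if entry.get("drugindication"):
            indications.add(entry["drugindication"])
    reactions = {
        rx["reactionmeddrapt"]
        for rx in patient.get("reaction") or []
        if isinstance(rx, Mapping) and rx.get("reactionmeddrapt")
    }
    return SafetyReport(
        report_id=str(rid),
        drugs=frozenset(drugs),
        reactions=frozenset(reactions),
        indications=frozenset(indications),
        uncleaned_drugs=frozenset(uncleaned),
    )


def _iter_objects_from_document(path: Path) -> Iterator[Mapping]:
    text = path.read_text()
    if path.suffix in {".ndjson", ".jsonl"}:
        for i, line in enumerate(text.splitlines(), 1):
            if not line.strip():
                continue
            try:
                yield json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed JSON in {path} line {i}: {exc}") from exc
        return
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON in {path}: {exc}") from exc
    if isinstance(doc, Mapping) and "results" in doc:
        yield from doc["results"]
    elif isinstance(doc, list):
        yield from doc
    elif isinstance(doc, Mapping):
        yield doc
    else:
        raise ValueError(f"{path}: expected a results object or array of reports")


def load_openfda_json(
    source: str | Path | Sequence[str | Path],
    *,
    drop_undrugged: bool = False,
) -> ReportStore:
    """Load openFDA drug-event JSON into a :class:`ReportStore`.

    ``source`` may be a single file (an openFDA response with a ``results``
    array, a bare JSON array of report objects, or newline-delimited JSON
    with one report per line), a directory of such files, or a sequence of
    paths.  Malformed JSON raises :class:`ValueError` naming the file;
    reports without a ``safetyreportid`` are skipped with a warning.
    """
    if isinstance(source, (str, Path)):
        sources: list[Path] = [Path(source)]
    else:
        sources = [Path(s) for s in source]
    paths: list[Path] = []
    for src in sources:
        if src.is_dir():
            paths.extend(
                sorted(
                    p
                    for p in src.iterdir()
                    if p.suffix in {".json", ".ndjson", ".jsonl"}
                )
            )
        else:
            paths.append(src)
    store = ReportStore(drop_undrugged=drop_undrugged)
    for path in paths:
        for obj in _iter_objects_from_document(path):
            report = parse_openfda_report(obj)
            if report is not None:
                store.add(report)
    return store
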