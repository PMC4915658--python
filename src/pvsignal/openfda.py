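"""openFDA drug-event endpoint client: query strings, paging limits, fixtures.

The openFDA service answers Lucene-style ``search`` expressions with either
matching report documents (paged via ``limit``/``skip``) or term frequency
tables (``count``).  The service enforces hard caps — ``limit`` <= 100,
``skip`` <= 5000 (so at most 5100 reports are retrievable per search) and at
most 100 terms per count — which silently truncate result sets; the client
surfaces truncation as flags instead of hiding it, because associations
falling below the count cap are exactly the signals a screen would miss.

Every outbound query string is logged at INFO so the constructed query can
be manually inspected.  Tests and offline work run against a
:class:`FixtureTransport` replaying recorded JSON responses keyed by the
canonical query string; :class:`HttpTransport` (stdlib urllib, no extra
dependency) talks to the live service with retry/backoff.

:class:`RemoteStore` adapts the count endpoints to the same
``count``/``list_terms`` contract as the local in-memory store, so every
analysis in this package runs unchanged against either backend.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .reports import Query, TermCounts, normalize_term

logger = logging.getLogger("pvsignal")

__all__ = [
    "MAX_LIMIT",
    "MAX_SKIP",
    "COUNT_CAP",
    "ApiQuery",
    "FieldMap",
    "TransportError",
    "ResponseParseError",
    "build_search_string",
    "canonical_key",
    "FixtureTransport",
    "HttpTransport",
    "fetch_total",
    "fetch_count",
    "RemoteStore",
    "simulate_fixtures",
]

#: Service-enforced caps on retrieval.
MAX_LIMIT = 100
MAX_SKIP = 5000
COUNT_CAP = 100

DEFAULT_BASE_URL = "https://api.fda.gov/drug/event.json"


class TransportError(RuntimeError):
    """The backend could not be reached or kept refusing after retries."""


class ResponseParseError(ValueError):
    """A response did not follow the expected openFDA schema."""


@dataclass(frozen=True)
class ApiQuery:
    """One request against the drug-event endpoint."""

    search: str | None = None
    count: str | None = None
    limit: int | None = None
    skip: int | None = None

    def __post_init__(self) -> None:
        if self.limit is not None and not (1 <= self.limit <= MAX_LIMIT):
            raise ValueError(f"limit must be in [1, {MAX_LIMIT}], got {self.limit}")
        if self.skip is not None and not (0 <= self.skip <= MAX_SKIP):
            raise ValueError(f"skip must be in [0, {MAX_SKIP}], got {self.skip}")
        if self.search is not None and not self.search:
            raise ValueError("search, when given, must be non-empty")

    def params(self) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        if self.search is not None:
            out.append(("search", self.search))
        if self.count is not None:
            out.append(("count", self.count))
        if self.limit is not None:
            out.append(("limit", str(self.limit)))
        if self.skip is not None:
            out.append(("skip", str(self.skip)))
        return out


def canonical_key(query: ApiQuery) -> str:
    """Stable human-readable identity of a request (fixture lookup key)."""
    return "&".join(f"{k}={v}" for k, v in query.params()) or "(unconstrained)"


@dataclass(frozen=True)
class FieldMap:
    """openFDA field names per query dimension.

    ``.exact`` suffixes query the unanalyzed keyword copy of a field —
    needed for multi-word MedDRA preferred terms; substance names are left
    analyzed by convention, matching common usage.  Count fields always use
    ``.exact`` so term tables are whole preferred terms, not tokens.
    """

    drug: str = "patient.drug.openfda.substance_name"
    reaction: str = "patient.reaction.reactionmeddrapt"
    indication: str = "patient.drug.drugindication"
    exact_drug: bool = False
    exact_reaction: bool = True
    exact_indication: bool = True

    def search_field(self, dimension: str) -> str:
        base = getattr(self, dimension)
        exact = getattr(self, f"exact_{dimension}")
        return f"{base}.exact" if exact else base

    def count_field(self, dimension: str) -> str:
        return f"{getattr(self, dimension)}.exact"


def _clause(field_name: str, term: str) -> str:
    return f'{field_name}:"{term.lower()}"'


def build_search_string(query: Query, field_map: FieldMap = FieldMap()) -> str:
    """Render a :class:`~pvsignal.reports.Query` in openFDA search syntax.

    Deterministic: terms are emitted sorted, each explicitly field-qualified
    (never relying on the service scoping bare terms to the previous field),
    multi-term fields parenthesized, conjuncts joined with ``+AND+`` and
    exclusions as ``+AND+NOT+(field:"term")``.  An empty query is refused —
    an unconstrained search is an API misuse (request without ``search``
    instead).
    """
    if query.is_empty():
        raise ValueError("refusing to build a search string for an empty query")
    if query.unsat:
        raise ValueError("unsatisfiable query has no search-string rendering")
    positives: list[str] = []
    negatives: list[str] = []
    for dimension in ("drug", "reaction", "indication"):
        fld = field_map.search_field(dimension)
        required = sorted(getattr(query, f"{dimension}_all"))
        if required:
            group = "+AND+".join(_clause(fld, t) for t in required)
            positives.append(f"({group})" if len(required) > 1 else group)
        for term in sorted(getattr(query, f"{dimension}_none")):
            negatives.append(f"+AND+NOT+({_clause(fld, term)})")
    body = "+AND+".join(positives)
    if not body:
        # exclusion-only query: anchor on the universe via existence is not
        # expressible portably; require at least one positive conjunct
        raise ValueError("openFDA search needs at least one positive term")
    return body + "".join(negatives)


# ---------------------------------------------------------------------------
# Transports
# ---------------------------------------------------------------------------

class FixtureTransport:
    """Replay (and record) JSON responses from a directory of fixtures.

    Files are named by a hash of the canonical query string; an
    ``index.json`` in the directory maps canonical strings to file names so
    fixture sets stay human-navigable.  Replay is bit-reproducible.
    """

    def __init__(self, directory: str | Path) -> None:
        self.directory = Path(directory)

    def _path(self, key: str) -> Path:
        digest = hashlib.sha1(key.encode()).hexdigest()[:20]
        return self.directory / f"{digest}.json"

    def get(self, query: ApiQuery) -> Mapping:
        key = canonical_key(query)
        logger.info("openFDA fixture query: %s", key)
        path = self._path(key)
        if not path.exists():
            raise TransportError(f"no recorded fixture for query: {key}")
        return json.loads(path.read_text())

    def record(self, query: ApiQuery, response: Mapping) -> None:
        self.directory.mkdir(parents=True, exist_ok=True)
        key = canonical_key(query)
        path = self._path(key)
        path.write_text(json.dumps(response, indent=1, sort_keys=True))
        index_path = self.directory / "index.json"
        index = json.loads(index_path.read_text()) if index_path.exists() else {}
        index[key] = path.name
        index_path.write_text(json.dumps(index, indent=1, sort_keys=True))


class HttpTransport:
    """Live client for the drug-event endpoint (stdlib urllib).

    Zero-match searches come back as HTTP 404 with a NOT_FOUND error body;
    that body is returned for the fetch helpers to interpret as count 0.
    Rate-limit (429) and server errors are retried with exponential backoff,
    then raised as :class:`TransportError`.
    """

    def __init__(
        self,
        base_url: str = DEFAULT_BASE_URL,
        api_key: str | None = None,
        retries: int = 3,
        backoff: float = 1.0,
        timeout: float = 30.0,
    ) -> None:
        self.base_url = base_url
        self.api_key = api_key
        self.retries = retries
        self.backoff = backoff
        self.timeout = timeout

    def _url(self, query: ApiQuery) -> str:
        params = query.params()
        if self.api_key:
            params.append(("api_key", self.api_key))
        safe_chars = '+:()"'
        encoded = "&".join(
            f"{k}={urllib.parse.quote(v, safe=safe_chars)}" for k, v in params
        )
        return f"{self.base_url}?{encoded}" if encoded else self.base_url

    def get(self, query: ApiQuery) -> Mapping:
        logger.info("openFDA query: %s", canonical_key(query))
        url = self._url(query)
        last_error: Exception | None = None
        for attempt in range(self.retries + 1):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return json.loads(resp.read().decode())
            except urllib.error.HTTPError as exc:
                body = exc.read().decode(errors="replace")
                if exc.code == 404:
                    try:
                        return json.loads(body)
                    except json.JSONDecodeError:
                        raise ResponseParseError(
                            f"unparseable 404 body from {self.base_url}"
                        ) from exc
                last_error = exc
                if exc.code not in (429, 500, 502, 503, 504):
                    break
            except (urllib.error.URLError, TimeoutError) as exc:
                last_error = exc
            if attempt < self.retries:
                time.sleep(self.backoff * 2**attempt)
        raise TransportError(f"openFDA request failed: {last_error}")


def _is_no_match(response: Mapping) -> bool:
    error = response.get("error")
    return bool(error) and error.get("code") == "NOT_FOUND"


def fetch_total(transport, search: str | None) -> int:
    """Total matching-report count (``meta.results.total``); 0 on no match.

    ``search=None`` asks for the whole-database total (no search clause).
    """
    response = transport.get(ApiQuery(search=search, limit=1))
    if _is_no_match(response):
        return 0
    try:
        return int(response["meta"]["results"]["total"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ResponseParseError(f"missing meta.results.total in response: {exc}") from exc


def fetch_count(transport, search: str | None, count_field: str) -> TermCounts:
    """Term frequency table for a field; truncation flagged at the 100 cap.

    Zero-match searches yield an empty table, not an error.
    """
    response = transport.get(ApiQuery(search=search, count=count_field))
    if _is_no_match(response):
        return TermCounts()
    try:
        pairs = [
            (normalize_term(str(item["term"])), int(item["count"]))
            for item in response["results"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ResponseParseError(f"malformed count results: {exc}") from exc
    pairs.sort(key=lambda tc: (-tc[1], tc[0]))
    return TermCounts(pairs, truncated=len(pairs) >= COUNT_CAP)


class RemoteStore:
    """Count-only store backed by the openFDA endpoint (live or fixtures).

    Satisfies the ``count``/``list_terms`` contract of the local store, so
    contingency tables and every clinical algorithm run against it
    unchanged; on fixtures the behavior is bit-reproducible.  Term-list
    truncation at the service's 100-term cap is surfaced via the
    ``truncated`` flag and propagates into analysis results.
    """

    def __init__(self, transport, field_map: FieldMap = FieldMap()) -> None:
        self.transport = transport
        self.field_map = field_map

    def count(self, query: Query, mask: Query | None = None) -> int:
        q = query & mask
        if q.unsat:
            return 0
        search = None if q.is_empty() else build_search_string(q, self.field_map)
        return fetch_total(self.transport, search)

    def list_terms(
        self,
        field_name: str,
        restrict: Query | None = None,
        *,
        limit: int | None = None,
    ) -> TermCounts:
        count_field = self.field_map.count_field(field_name)  # validates name
        if restrict is not None and restrict.unsat:
            return TermCounts()
        search = None
        if restrict is not None and not restrict.is_empty():
            search = build_search_string(restrict, self.field_map)
        terms = fetch_count(self.transport, search, count_field)
        truncated = terms.truncated or (limit is not None and len(terms) > limit)
        if limit is not None:
            return TermCounts(terms[:limit], truncated=truncated)
        return TermCounts(terms, truncated=truncated)


# ---------------------------------------------------------------------------
# Fixture fabrication (synthetic responses; no live snapshot required)
# ---------------------------------------------------------------------------

def simulate_fixtures(
    transport: FixtureTransport,
    store,
    queries: list[Query | None] = (),
    term_lists: list[tuple[str, Query | None]] = (),
    field_map: FieldMap = FieldMap(),
) -> int:
    """Fabricate openFDA-shaped responses from a local store and record them.

    These are *simulated* fixtures — synthetic stand-ins for recorded live
    traffic, built by evaluating each query against ``store`` and wrapping
    the counts in the service's response schema.  ``queries`` become total
    fixtures (None = whole-database total); ``term_lists`` are ``(field,
    restrict)`` pairs that become count-endpoint fixtures (truncated at the
    service's 100-term cap, as the live service would).  Returns the number
    of fixture files recorded.
    """
    recorded = 0
    for q in queries:
        if q is None or q.is_empty():
            api = ApiQuery(search=None, limit=1)
            total = store.count(Query())
        else:
            api = ApiQuery(search=build_search_string(q, field_map), limit=1)
            total = store.count(q)
        if total == 0 and api.search is not None:
            transport.record(
                api, {"error": {"code": "NOT_FOUND", "message": "No matches found!"}}
            )
        else:
            transport.record(
                api,
                {
                    "meta": {"results": {"total": total, "limit": 1, "skip": 0}},
                    "results": [],
                },
            )
        recorded += 1
    for field_name, restrict in term_lists:
        search = None
        if restrict is not None and not restrict.is_empty():
            search = build_search_string(restrict, field_map)
        api = ApiQuery(search=search, count=field_map.count_field(field_name))
        pairs = store.list_terms(field_name, restrict)[:COUNT_CAP]
        transport.record(
            api,
            {"results": [{"term": t, "count": c} for t, c in pairs]},
        )
        recorded += 1
    return recorded


def dpa_query_set(
    drug_query: Query | str,
    event_query: Query | str,
    mask: Query | None = None,
) -> list[Query | None]:
    """The four count queries a 2x2 analysis issues (N, D, E, DE).

    Useful for pre-recording exactly the fixtures a
    :func:`~pvsignal.contingency.analyze_pair` call will need.
    """
    dq = Query.drugs(drug_query) if isinstance(drug_query, str) else drug_query
    eq = Query.reactions(event_query) if isinstance(event_query, str) else event_query
    return [mask, dq & mask, eq & mask, dq & eq & mask]
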