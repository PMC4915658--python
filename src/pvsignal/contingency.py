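"""2x2 contingency tables and measurements of disproportionality.

Disproportionality analysis (DPA) asks whether a drug-event pair is reported
more often than the rest of the database would predict.  The report
collection is cross-classified by drug usage (D / d) and event occurrence
(E / e):

    =========  =========  =========
               event E    no event e
    drug D     DE         De
    no drug d  dE         de
    =========  =========  =========

with margins D = DE+De, d = dE+de, E = DE+dE, e = De+de and N the grand
total.  On these counts the module computes

* rate           = DE / D                      (event rate among drug users)
* ROR            = (DE * de) / (dE * De)       (reporting odds ratio)
* PRR            = (DE * d) / (dE * D)         (proportional reporting ratio)
* RRR            = (DE * N) / (E * D)          (relative reporting ratio,
                                                observed over expected)
* Yates chi^2    = N * (|DE*de - dE*De| - N/2)^2 / (E * e * D * d)

and the conventional Evans signal rule PRR > 2, Yates chi^2 > 4 (~ p < .05)
and DE > 3.  Because spontaneous reports cover an unknown fraction of true
exposures (the open-world problem), these are hypothesis-generating report
statistics, not population risks.

Division by zero is encoded as ``None`` (a typed undefined marker), never
raised and never papered over with a continuity correction; an optional
Haldane 0.5 correction exists but defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .reports import Query

__all__ = [
    "ContingencyTable",
    "SignalThresholds",
    "DpaResult",
    "build_contingency",
    "rate",
    "ror",
    "prr",
    "rrr",
    "chi2_yates",
    "evans_signal",
    "analyze_pair",
]


@dataclass(frozen=True)
class ContingencyTable:
    """The four report counts of a drug-by-event 2x2 table.

    Cells are report counts: a report contributes at most 1 to one cell no
    matter how many drug entries or reaction terms it repeats.
    """

    DE: int
    De: int
    dE: int
    de: int

    def __post_init__(self) -> None:
        for name in ("DE", "De", "dE", "de"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def D(self) -> int:
        return self.DE + self.De

    @property
    def d(self) -> int:
        return self.dE + self.de

    @property
    def E(self) -> int:
        return self.DE + self.dE

    @property
    def e(self) -> int:
        return self.De + self.de

    @property
    def N(self) -> int:
        return self.DE + self.De + self.dE + self.de

    def with_haldane(self) -> "ContingencyTable":
        """Not used by default; see :func:`ror`/:func:`prr` ``haldane`` flag."""
        return self  # placeholder for symmetry; correction applied in measures

    def scaled(self, k: int) -> "ContingencyTable":
        return replace(
            self, DE=self.DE * k, De=self.De * k, dE=self.dE * k, de=self.de * k
        )


def rate(table: ContingencyTable) -> float | None:
    """Event rate among drug users, DE/D; None when no drug users."""
    return table.DE / table.D if table.D else None


def _corrected_cells(table: ContingencyTable, haldane: bool) -> tuple[float, float, float, float]:
    if haldane:
        return table.DE + 0.5, table.De + 0.5, table.dE + 0.5, table.de + 0.5
    return float(table.DE), float(table.De), float(table.dE), float(table.de)


def ror(table: ContingencyTable, *, haldane: bool = False) -> float | None:
    """Reporting odds ratio DE*de/(dE*De); None when dE*De = 0."""
    DE, De, dE, de = _corrected_cells(table, haldane)
    return (DE * de) / (dE * De) if dE * De else None


def prr(table: ContingencyTable, *, haldane: bool = False) -> float | None:
    """Proportional reporting ratio DE*d/(dE*D); None when dE*D = 0."""
    DE, De, dE, de = _corrected_cells(table, haldane)
    d = dE + de
    D = DE + De
    return (DE * d) / (dE * D) if dE * D else None


def rrr(table: ContingencyTable, *, haldane: bool = False) -> float | None:
    """Relative reporting ratio DE*N/(E*D); None when E*D = 0."""
    DE, De, dE, de = _corrected_cells(table, haldane)
    E = DE + dE
    D = DE + De
    N = DE + De + dE + de
    return (DE * N) / (E * D) if E * D else None


def chi2_yates(table: ContingencyTable, *, clamp: bool = True) -> float | None:
    """Yates-corrected chi-squared for the 2x2 table.

    Computed exactly in integer arithmetic as
    ``N * (2|DE*de - dE*De| - N)^2 / (4 * E * e * D * d)`` so the N/2
    continuity term never suffers integer truncation.  With ``clamp`` (the
    default and standard practice) the continuity term is floored at zero,
    so near-balanced tables yield 0 rather than a spurious positive value;
    ``clamp=False`` evaluates the textbook expression literally.  None when
    any margin is zero.
    """
    denom = table.E * table.e * table.D * table.d
    if denom == 0:
        return None
    twice_diff = 2 * abs(table.DE * table.de - table.dE * table.De)
    adj = twice_diff - table.N
    if clamp and adj < 0:
        return 0.0
    return table.N * adj * adj / (4 * denom)


@dataclass(frozen=True)
class SignalThresholds:
    """Cut-offs of the Evans disproportionality-signal rule (all strict >)."""

    min_prr: float = 2.0
    min_chi2: float = 4.0
    min_de: int = 3


def evans_signal(
    table: ContingencyTable, thresholds: SignalThresholds = SignalThresholds()
) -> bool | None:
    """Evans rule: PRR > 2 and Yates chi^2 > 4 and DE > 3 (strict).

    None (undefined) when PRR or chi^2 is undefined for this table.
    """
    p = prr(table)
    c = chi2_yates(table)
    if p is None or c is None:
        return None
    return p > thresholds.min_prr and c > thresholds.min_chi2 and table.DE > thresholds.min_de


@dataclass(frozen=True)
class DpaResult:
    """All DPA measures for one drug-event pair; None marks undefined."""

    table: ContingencyTable
    rate: float | None
    ror: float | None
    prr: float | None
    rrr: float | None
    chi2_yates: float | None
    is_signal: bool | None


def _as_drug_query(q: Query | str) -> Query:
    return Query.drugs(q) if isinstance(q, str) else q


def _as_event_query(q: Query | str) -> Query:
    return Query.reactions(q) if isinstance(q, str) else q


def build_contingency(
    store,
    drug_query: Query | str,
    event_query: Query | str,
    mask: Query | None = None,
) -> ContingencyTable:
    """Cross-classify the (masked) store by drug usage and event occurrence.

    Bare strings are accepted as single-term drug / reaction queries.  The
    four cells are derived from the four counts N, D, E and DE — the same
    four retrievals a count-only backend (the openFDA API) can answer — so
    local and remote backends produce identical tables by construction.
    Cells always sum to the masked store size.
    """
    dq = _as_drug_query(drug_query)
    eq = _as_event_query(event_query)
    n = store.count(Query(), mask)
    d_ct = store.count(dq, mask)
    e_ct = store.count(eq, mask)
    de_ct = store.count(dq & eq, mask)
    return ContingencyTable(
        DE=de_ct, De=d_ct - de_ct, dE=e_ct - de_ct, de=n - d_ct - e_ct + de_ct
    )


def analyze_pair(
    store,
    drug_query: Query | str,
    event_query: Query | str,
    mask: Query | None = None,
    *,
    thresholds: SignalThresholds = SignalThresholds(),
) -> DpaResult:
    """Full 2x2 DPA for one drug-event pair: table, rate, ROR, PRR, RRR,
    Yates chi^2 and the Evans signal flag.  Pure: identical inputs give an
    identical result."""
    t = build_contingency(store, drug_query, event_query, mask)
    return DpaResult(
        table=t,
        rate=rate(t),
        ror=ror(t),
        prr=prr(t),
        rrr=rrr(t),
        chi2_yates=chi2_yates(t),
        is_signal=evans_signal(t, thresholds),
    )
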