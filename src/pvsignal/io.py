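"""Serialization of analysis results (CSV / JSON) and report collections.

CSV output is RFC-4180 with a header row; JSON mirrors the result
dataclasses field for field at full float precision.  Undefined measures
render as empty CSV cells and JSON ``null`` — never as 0 or textual NaN,
which would be silently wrong numbers.  Human-readable tables round ratios
to 4 significant digits; row order is identical across the three renderings.

Report collections are written back out as openFDA-style JSON (a ``results``
array) or newline-delimited JSON so generated synthetic stores round-trip
through :func:`~pvsignal.reports.load_openfda_json`.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

from .algorithms import ConfounderScreen, DdiScreen, DrugRanking, ProfileComparison
from .contingency import DpaResult
from .reports import ReportStore, SafetyReport

__all__ = [
    "result_rows",
    "result_to_obj",
    "write_csv",
    "write_json",
    "render_text",
    "report_to_openfda",
    "write_reports_ndjson",
    "write_reports_json",
]


def _sig4(x: Any) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "yes" if x else "no"
    if isinstance(x, float):
        return f"{x:.4g}"
    return str(x)


def result_rows(result) -> tuple[list[str], list[dict]]:
    """``(header, rows)`` tabular view of any analysis result."""
    if isinstance(result, DpaResult):
        t = result.table
        header = [
            "DE", "De", "dE", "de", "D", "d", "E", "e", "N",
            "rate", "ror", "prr", "rrr", "chi2_yates", "is_signal",
        ]
        return header, [{
            "DE": t.DE, "De": t.De, "dE": t.dE, "de": t.de,
            "D": t.D, "d": t.d, "E": t.E, "e": t.e, "N": t.N,
            "rate": result.rate, "ror": result.ror, "prr": result.prr,
            "rrr": result.rrr, "chi2_yates": result.chi2_yates,
            "is_signal": result.is_signal,
        }]
    if isinstance(result, DrugRanking):
        header = ["drug", "DE", "D", "rate", "rrr"]
        return header, [
            {"drug": e.drug, "DE": e.DE, "D": e.D, "rate": e.rate, "rrr": e.rrr}
            for e in result.entries
        ]
    if isinstance(result, ProfileComparison):
        header = ["event", "DE1", "DE2", "rate1", "rate2", "rrr1", "rrr2", "perc_diff"]
        return header, [
            {
                "event": r.event, "DE1": r.DE1, "DE2": r.DE2,
                "rate1": r.rate1, "rate2": r.rate2,
                "rrr1": r.rrr1, "rrr2": r.rrr2, "perc_diff": r.perc_diff,
            }
            for r in result.rows
        ]
    if isinstance(result, DdiScreen):
        header = [
            "event", "DE1", "DE2", "DE_combo",
            "rate_d1", "rate_d2", "rate_combo", "expected", "rate_diff",
        ]
        return header, [
            {
                "event": r.event, "DE1": r.DE1, "DE2": r.DE2,
                "DE_combo": r.DE_combo, "rate_d1": r.rate_d1,
                "rate_d2": r.rate_d2, "rate_combo": r.rate_combo,
                "expected": r.expected, "rate_diff": r.rate_diff,
            }
            for r in result.rows
        ]
    if isinstance(result, ConfounderScreen):
        header = ["kind", "term", "count", "fraction_of_DE"]
        rows = [
            {"kind": "drug", "term": t, "count": c, "fraction_of_DE": f}
            for t, c, f in result.co_drugs
        ] + [
            {"kind": "indication", "term": t, "count": c, "fraction_of_DE": f}
            for t, c, f in result.co_indications
        ]
        return header, rows
    raise TypeError(f"no tabular rendering for {type(result).__name__}")


def result_to_obj(result) -> dict:
    """JSON-ready dict mirroring the result type field for field."""
    header, rows = result_rows(result)
    obj: dict[str, Any] = {"kind": type(result).__name__, "rows": rows}
    for attr in (
        "drug", "event", "drug1", "drug2", "n_de",
        "d1_total", "d2_total", "combo_total", "truncated",
    ):
        if hasattr(result, attr):
            obj[attr] = getattr(result, attr)
    return obj


def write_csv(result, destination) -> None:
    """RFC-4180 CSV with header; undefined values become empty cells."""
    header, rows = result_rows(result)
    own = isinstance(destination, (str, Path))
    fh = open(destination, "w", newline="") if own else destination
    try:
        writer = csv.writer(fh, lineterminator="\r\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(["" if row[k] is None else row[k] for k in header])
    finally:
        if own:
            fh.close()


def write_json(result, destination) -> None:
    obj = result_to_obj(result)
    text = json.dumps(obj, indent=1, sort_keys=True)
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text + "\n")
    else:
        destination.write(text + "\n")


def render_text(result) -> str:
    """Aligned plain-text table (ratios at 4 significant digits)."""
    if isinstance(result, DpaResult):
        t = result.table
        lines = [
            "2x2 contingency (reports):",
            f"              event E   no-event e   total",
            f"  drug D      {t.DE:>7}   {t.De:>10}   {t.D:>5}",
            f"  no-drug d   {t.dE:>7}   {t.de:>10}   {t.d:>5}",
            f"  total       {t.E:>7}   {t.e:>10}   {t.N:>5}",
            "",
            f"rate (DE/D)   = {_sig4(result.rate)}",
            f"ROR           = {_sig4(result.ror)}",
            f"PRR           = {_sig4(result.prr)}",
            f"RRR           = {_sig4(result.rrr)}",
            f"chi2 (Yates)  = {_sig4(result.chi2_yates)}",
            f"Evans signal  = {_sig4(result.is_signal) or 'undefined'}",
        ]
        return "\n".join(lines)
    header, rows = result_rows(result)
    cells = [[_sig4(r[k]) for k in header] for r in rows]
    widths = [
        max(len(header[i]), *(len(c[i]) for c in cells)) if cells else len(header[i])
        for i in range(len(header))
    ]
    out = ["  ".join(h.ljust(w) for h, w in zip(header, widths)).rstrip()]
    out.append("  ".join("-" * w for w in widths))
    for c in cells:
        out.append("  ".join(v.ljust(w) for v, w in zip(c, widths)).rstrip())
    return "\n".join(out)


# ---------------------------------------------------------------------------
# Report-collection writers (openFDA result schema)
# ---------------------------------------------------------------------------

def report_to_openfda(report: SafetyReport) -> dict:
    """One report as an openFDA drug-event result object.

    Drugs flagged uncleaned are emitted with ``medicinalproduct`` only (no
    ``openfda`` block), so the uncleaned status survives a round trip;
    indications are distributed over the drug entries (schema stores them
    per drug entry), with drug-less entries appended when a report carries
    more indications than drugs.
    """
    drugs = sorted(report.drugs)
    indications = sorted(report.indications)
    entries: list[dict] = []
    for i, name in enumerate(drugs):
        entry: dict[str, Any] = {"medicinalproduct": name}
        if name not in report.uncleaned_drugs:
            entry["openfda"] = {"substance_name": [name]}
        if i < len(indications):
            entry["drugindication"] = indications[i]
        entries.append(entry)
    for extra in indications[len(drugs):]:
        entries.append({"drugindication": extra})
    return {
        "safetyreportid": report.report_id,
        "patient": {
            "drug": entries,
            "reaction": [{"reactionmeddrapt": t} for t in sorted(report.reactions)],
        },
    }


def write_reports_ndjson(store: ReportStore, path: str | Path) -> None:
    """One openFDA-style report object per line."""
    with open(path, "w") as fh:
        for report in store:
            fh.write(json.dumps(report_to_openfda(report), sort_keys=True))
            fh.write("\n")


def write_reports_json(store: ReportStore, path: str | Path) -> None:
    """A single openFDA-style response document with a ``results`` array."""
    doc = {"results": [report_to_openfda(r) for r in store]}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
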