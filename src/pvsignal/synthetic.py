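"""Synthetic spontaneous-report generator with plantable ground truth.

Real FAERS extracts carry no ground truth, so algorithm validation needs
report collections whose association structure is known by construction.
The generator draws each report independently:

* each indication term is present with its configured probability;
* each drug is present with its marginal probability, multiplied by the
  drug-multiplier of any present confounder indication (then clamped to
  [0, 1]) — this is the only source of drug co-occurrence structure, so the
  null model stays clean;
* each event occurs with its baseline probability times the risk
  multiplier ``rho`` of every planted association whose drug is present,
  times the event-multiplier of any present confounder indication, times
  the combination-multiplier of any planted interaction whose *both* drugs
  are present — clamped to [0, 1].

Under this multiplicative risk model, for a rare event with a rare exposed
fraction the relative reporting ratio approaches the planted ``rho``:
RRR = P(event|drug)/P(event) = rho / (1 + P(drug)(rho - 1)), which tends to
rho as P(drug) -> 0.  Recovery tests therefore use rare drugs and events;
probability clamping additionally biases recovered RRR downward for
non-rare events.

Identical configuration + seed reproduce the collection byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reports import ReportStore, SafetyReport, normalize_term

__all__ = [
    "PlantedAssociation",
    "PlantedConfounder",
    "PlantedInteraction",
    "SyntheticConfig",
    "generate",
    "fixture_model_case",
    "FIXTURE_DRUG",
    "FIXTURE_EVENT",
    "FIXTURE_OTHER_DRUG",
    "FIXTURE_OTHER_EVENT",
]


@dataclass(frozen=True)
class PlantedAssociation:
    """Drug multiplies the event's probability by ``rho`` when present."""

    drug: str
    event: str
    rho: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("risk multiplier rho must be >= 0")


@dataclass(frozen=True)
class PlantedConfounder:
    """Indication that drives both drug usage and the event.

    When the indication is present, the drug's probability is multiplied by
    ``drug_multiplier`` and the event's by ``event_multiplier`` — classic
    confounding by indication, removable by background correction.
    """

    indication: str
    drug: str
    event: str
    drug_multiplier: float
    event_multiplier: float

    def __post_init__(self) -> None:
        if self.drug_multiplier < 0 or self.event_multiplier < 0:
            raise ValueError("multipliers must be >= 0")


@dataclass(frozen=True)
class PlantedInteraction:
    """Extra event risk applied only when both drugs are present."""

    drug1: str
    drug2: str
    event: str
    combo_multiplier: float

    def __post_init__(self) -> None:
        if self.combo_multiplier < 0:
            raise ValueError("combo multiplier must be >= 0")


def _check_probs(vocab: Sequence[tuple[str, float]], what: str) -> None:
    for term, p in vocab:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{what} probability for {term!r} out of [0, 1]: {p}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic report collection.

    Vocabularies are ``(term, probability)`` pairs: marginal presence
    probability for drugs and indications, baseline per-report probability
    for events.  Planted structures reference vocabulary terms by name.
    """

    n_reports: int
    drug_vocab: tuple[tuple[str, float], ...]
    event_vocab: tuple[tuple[str, float], ...]
    indication_vocab: tuple[tuple[str, float], ...] = ()
    associations: tuple[PlantedAssociation, ...] = ()
    confounders: tuple[PlantedConfounder, ...] = ()
    interactions: tuple[PlantedInteraction, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        object.__setattr__(self, "drug_vocab", tuple(
            (normalize_term(t), float(p)) for t, p in self.drug_vocab))
        object.__setattr__(self, "event_vocab", tuple(
            (normalize_term(t), float(p)) for t, p in self.event_vocab))
        object.__setattr__(self, "indication_vocab", tuple(
            (normalize_term(t), float(p)) for t, p in self.indication_vocab))
        object.__setattr__(self, "associations", tuple(self.associations))
        object.__setattr__(self, "confounders", tuple(self.confounders))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        _check_probs(self.drug_vocab, "drug")
        _check_probs(self.event_vocab, "event baseline")
        _check_probs(self.indication_vocab, "indication")


def generate(config: SyntheticConfig) -> ReportStore:
    """Draw a report collection from the generative model (vectorized)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_terms = [t for t, _ in config.drug_vocab]
    event_terms = [t for t, _ in config.event_vocab]
    ind_terms = [t for t, _ in config.indication_vocab]
    drug_idx = {t: i for i, t in enumerate(drug_terms)}
    event_idx = {t: i for i, t in enumerate(event_terms)}
    ind_idx = {t: i for i, t in enumerate(ind_terms)}

    # indications first: they shift drug probabilities
    ind_p = np.array([p for _, p in config.indication_vocab], float)
    ind_mat = rng.random((n, len(ind_terms))) < ind_p if ind_terms else np.zeros((n, 0), bool)

    drug_p = np.tile(np.array([p for _, p in config.drug_vocab], float), (n, 1))
    for cf in config.confounders:
        i = ind_idx[normalize_term(cf.indication)]
        j = drug_idx[normalize_term(cf.drug)]
        drug_p[ind_mat[:, i], j] *= cf.drug_multiplier
    np.clip(drug_p, 0.0, 1.0, out=drug_p)
    drug_mat = rng.random((n, len(drug_terms))) < drug_p

    event_p = np.tile(np.array([p for _, p in config.event_vocab], float), (n, 1))
    for assoc in config.associations:
        j = drug_idx[normalize_term(assoc.drug)]
        k = event_idx[normalize_term(assoc.event)]
        event_p[drug_mat[:, j], k] *= assoc.rho
    for cf in config.confounders:
        i = ind_idx[normalize_term(cf.indication)]
        k = event_idx[normalize_term(cf.event)]
        event_p[ind_mat[:, i], k] *= cf.event_multiplier
    for inter in config.interactions:
        j1 = drug_idx[normalize_term(inter.drug1)]
        j2 = drug_idx[normalize_term(inter.drug2)]
        k = event_idx[normalize_term(inter.event)]
        both = drug_mat[:, j1] & drug_mat[:, j2]
        event_p[both, k] *= inter.combo_multiplier
    np.clip(event_p, 0.0, 1.0, out=event_p)
    event_mat = rng.random((n, len(event_terms))) < event_p

    def rows_to_sets(mat: np.ndarray, terms: list[str]) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(n)]
        rows, cols = np.nonzero(mat)
        for r, c in zip(rows.tolist(), cols.tolist()):
            out[r].append(terms[c])
        return out

    drug_sets = rows_to_sets(drug_mat, drug_terms)
    event_sets = rows_to_sets(event_mat, event_terms)
    ind_sets = rows_to_sets(ind_mat, ind_terms)

    width = max(7, len(str(n)))
    store = ReportStore()
    for i in range(n):
        store.add(
            SafetyReport(
                report_id=f"SYN-{i + 1:0{width}d}",
                drugs=frozenset(drug_sets[i]),
                reactions=frozenset(event_sets[i]),
                indications=frozenset(ind_sets[i]),
            )
        )
    return store


# ---------------------------------------------------------------------------
# Deterministic textbook fixtures
# ---------------------------------------------------------------------------

FIXTURE_DRUG = "DRUGX"
FIXTURE_EVENT = "EVENTY"
FIXTURE_OTHER_DRUG = "OTHERDRUG"
FIXTURE_OTHER_EVENT = "OTHEREVENT"


def fixture_model_case(which: int) -> ReportStore:
    """Deterministic stores reproducing the two textbook 2x2 model tables.

    Case 1 (100 reports): DE=1, De=9, dE=9, de=81 — the event occurs in 10%
    of DRUGX users and in 10% of other-drug users, so every
    disproportionality ratio equals 1.  Case 2 (90 reports): DE=2, De=8,
    dE=8, de=72 — 20% of DRUGX users versus 10% of the background, giving
    RRR = 1.8, PRR = 2 and ROR = 2.25.  Non-DRUGX reports carry OTHERDRUG
    so the complementary population is genuinely "users of other drugs".
    """
    cells = {1: (1, 9, 9, 81), 2: (2, 8, 8, 72)}
    if which not in cells:
        raise ValueError(f"unknown model case {which}; expected 1 or 2")
    de_, De_, dE_, dd_ = cells[which]
    reports: list[SafetyReport] = []

    def emit(count: int, drugs: frozenset[str], reactions: frozenset[str]) -> None:
        for _ in range(count):
            reports.append(
                SafetyReport(
                    report_id=f"MC{which}-{len(reports) + 1:04d}",
                    drugs=drugs,
                    reactions=reactions,
                )
            )

    emit(de_, frozenset({FIXTURE_DRUG}), frozenset({FIXTURE_EVENT}))
    emit(De_, frozenset({FIXTURE_DRUG}), frozenset({FIXTURE_OTHER_EVENT}))
    emit(dE_, frozenset({FIXTURE_OTHER_DRUG}), frozenset({FIXTURE_EVENT}))
    emit(dd_, frozenset({FIXTURE_OTHER_DRUG}), frozenset({FIXTURE_OTHER_EVENT}))
    return ReportStore(reports)
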