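"""Cohort construction: from raw hospital-visit records to class-labeled transactions.

The pipeline implemented here turns longitudinal visit records (one row per
patient per year with a list of raw ICD-10 codes) into

1. per-patient clinical histories in which every 3-character diagnosis code is
   kept at its first year of occurrence,
2. a study cohort defined by an index diagnosis of type 2 diabetes (ICD-10
   E11), an age filter and a prior-visit requirement, and
3. a class-labeled transaction database in which each patient contributes one
   transaction per timeframe relative to the index year: ``n5-n1`` (five years
   before the diagnosis), ``0-4``, ``5-9`` and ``10-`` (years after it).

All time arithmetic is done on calendar years; visits are aggregated annually
and no finer resolution exists anywhere in the package.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError, FormatError, ValidationError

# Timeframe classes relative to the index year.  Bounds are closed; the last
# class is open-ended.  Offsets below -5 fall outside the studied window and
# map to no class at all.
CLASS_LABELS: tuple[str, ...] = ("n5-n1", "0-4", "5-9", "10-")
CLASS_BOUNDS: dict[str, tuple[int, int | None]] = {
    "n5-n1": (-5, -1),
    "0-4": (0, 4),
    "5-9": (5, 9),
    "10-": (10, None),
}

#: ICD-10 code of the index diagnosis (type 2 diabetes mellitus).
INDEX_CODE = "E11"

#: Keyword stems that scope the free-text onset-year search.
DEFAULT_NOTE_STEMS: tuple[str, ...] = ("diabetes", "t2dm", "e11")

_YEAR_RE = re.compile(r"\b(19\d{2}|20\d{2})\b")
_CLAUSE_SPLIT_RE = re.compile(r"[;.!?]")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisitRecord:
    """One hospital attendance, aggregated to calendar-year resolution."""

    patient_id: str
    year: int
    sex: str  # "M" or "F"
    birth_year: int
    death_year: int | None
    icd_codes: tuple[str, ...]
    note_text: str | None = None


@dataclass
class PatientHistory:
    """Per-patient first-occurrence map plus index-diagnosis metadata.

    ``first_occurrence`` maps each normalized, in-scope 3-character code to the
    earliest year it was recorded.  ``index_year`` is the year of the first E11
    record, possibly moved earlier by a dated free-text note
    (``index_source == "note_corrected"``).
    """

    patient_id: str
    sex: str
    birth_year: int
    death_year: int | None
    first_occurrence: dict[str, int]
    index_year: int | None
    index_source: str = "recorded"
    visit_years: frozenset[int] = frozenset()

    @property
    def recorded_index_year(self) -> int | None:
        """Year of the first E11 record, before any note correction."""
        return self.first_occurrence.get(INDEX_CODE)


@dataclass(frozen=True)
class Transaction:
    """Items (first-occurrence codes) of one patient in one timeframe class."""

    patient_id: str
    timeframe: str
    items: frozenset[str]


@dataclass
class TransactionDB:
    """Class-labeled transaction database with per-class denominators."""

    transactions: list[Transaction]
    class_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_sizes:
            sizes: dict[str, int] = defaultdict(int)
            for t in self.transactions:
                sizes[t.timeframe] += 1
            self.class_sizes = {c: sizes[c] for c in CLASS_LABELS if sizes[c]}

    def __len__(self) -> int:
        return len(self.transactions)

    def by_class(self, label: str) -> list[Transaction]:
        return [t for t in self.transactions if t.timeframe == label]


@dataclass
class CohortFunnel:
    """Ordered (filter name, patients remaining) counts of the cohort build."""

    steps: list[tuple[str, int]]

    def __post_init__(self) -> None:
        counts = [n for _, n in self.steps]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValidationError("funnel counts must be non-increasing")

    def report(self) -> list[dict]:
        """Funnel table with each stage's share of the source count.

        Shares are percentages truncated (not rounded) to one decimal, a
        conservative reporting convention that never overstates how much of
        the source population was retained.
        """
        if not self.steps:
            return []
        source = self.steps[0][1]
        return [
            {
                "filter": name,
                "patients": n,
                "share_of_source_pct": truncated_share_pct(n, source),
            }
            for name, n in self.steps
        ]


def truncated_share_pct(part: int, whole: int, decimals: int = 1) -> float:
    """Percentage of ``part`` in ``whole``, truncated to ``decimals`` places."""
    if whole <= 0:
        return 0.0
    scale = 10 ** decimals
    return math.floor(part / whole * 100 * scale) / scale


# ---------------------------------------------------------------------------
# Code normalization
# ---------------------------------------------------------------------------

def normalize_icd(raw_code: str) -> str:
    """Normalize a raw ICD-10 string to its 3-character category.

    Cleaning steps: strip whitespace, drop dots, uppercase, truncate to the
    first three characters.  ``"e11.2" -> "E11"``.

    Raises
    ------
    FormatError
        If fewer than three characters remain after cleaning.
    """
    cleaned = raw_code.strip().replace(".", "").upper()
    if len(cleaned) < 3:
        raise FormatError(f"ICD code too short after cleaning: {raw_code!r}")
    return cleaned[:3]


def chapter_in_scope(code: str) -> bool:
    """True iff the code belongs to ICD-10 chapters A through N.

    Later chapters (pregnancy, perinatal, congenital, symptom, external-cause
    and administrative codes) are excluded from the analysis.
    """
    return "A" <= code[0] <= "N"


# ---------------------------------------------------------------------------
# Annual aggregation and first occurrences
# ---------------------------------------------------------------------------

def aggregate_yearly(
    records: Iterable[VisitRecord],
) -> dict[tuple[str, int], set[str]]:
    """Union of normalized, in-scope codes per (patient, year).

    Duplicate codes within a year collapse; visits in different years stay
    separate.  The result is independent of input record order.
    """
    out: dict[tuple[str, int], set[str]] = defaultdict(set)
    for rec in records:
        key = (rec.patient_id, rec.year)
        codes = out[key]  # keep the key even if no code survives the filter
        for raw in rec.icd_codes:
            code = normalize_icd(raw)
            if chapter_in_scope(code):
                codes.add(code)
    return dict(out)


def first_occurrences(
    yearly: Mapping[tuple[str, int], set[str]],
) -> dict[str, tuple[dict[str, int], int | None]]:
    """Map each patient to (code -> earliest year, preliminary index year).

    The preliminary index year is the first year containing an E11 record, or
    ``None`` when the patient has no E11 at all.
    """
    per_patient: dict[str, dict[str, int]] = defaultdict(dict)
    for (pid, year), codes in sorted(yearly.items()):
        firsts = per_patient[pid]
        for code in codes:
            if code not in firsts or year < firsts[code]:
                firsts[code] = year
    return {
        pid: (firsts, firsts.get(INDEX_CODE))
        for pid, firsts in per_patient.items()
    }


# ---------------------------------------------------------------------------
# Free-text onset extraction and index correction
# ---------------------------------------------------------------------------

def extract_onset_year(
    note_text: str, stems: Sequence[str] = DEFAULT_NOTE_STEMS
) -> int | None:
    """Earliest 4-digit year (1900-2099) that follows a diabetes keyword stem.

    The note is split into clauses (on ``;``, ``.``, ``!``, ``?``); within a
    clause only years appearing *after* a stem are eligible, so a year tied to
    an unrelated condition in another clause is never picked up.  Returns
    ``None`` when no stem-scoped year exists — absence is a value, not an
    error.
    """
    years: list[int] = []
    lowered_stems = tuple(s.lower() for s in stems)
    for clause in _CLAUSE_SPLIT_RE.split(note_text):
        low = clause.lower()
        positions = [m for s in lowered_stems for m in _iter_find(low, s)]
        if not positions:
            continue
        first_stem_end = min(positions)
        for match in _YEAR_RE.finditer(clause):
            if match.start() >= first_stem_end:
                years.append(int(match.group(1)))
    return min(years) if years else None


def _iter_find(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return
        yield idx + len(needle)
        start = idx + 1


def correct_index_year(
    history: PatientHistory, note_year: int | None
) -> PatientHistory:
    """Move the index year earlier when a dated note precedes the record.

    Only strictly earlier note years update the index; later or absent note
    years leave the history unchanged.
    """
    if history.index_year is None:
        raise ValidationError(
            f"patient {history.patient_id}: cannot correct an absent index year"
        )
    if note_year is not None and note_year < history.index_year:
        return dataclasses.replace(
            history, index_year=note_year, index_source="note_corrected"
        )
    return history


def build_histories(records: Sequence[VisitRecord]) -> list[PatientHistory]:
    """Assemble per-patient histories from raw records.

    Runs annual aggregation, first-occurrence deduplication, and note-based
    index correction (using the earliest stem-scoped year found across all of
    the patient's notes).  Patients without any E11 record keep
    ``index_year=None`` and are candidates for exclusion downstream.
    """
    yearly = aggregate_yearly(records)
    firsts = first_occurrences(yearly)

    meta: dict[str, VisitRecord] = {}
    visit_years: dict[str, set[int]] = defaultdict(set)
    note_years: dict[str, list[int]] = defaultdict(list)
    for rec in sorted(records, key=lambda r: (r.patient_id, r.year)):
        meta.setdefault(rec.patient_id, rec)
        visit_years[rec.patient_id].add(rec.year)
        if rec.note_text:
            year = extract_onset_year(rec.note_text)
            if year is not None:
                note_years[rec.patient_id].append(year)

    histories = []
    for pid in sorted(firsts):
        first_map, prelim_index = firsts[pid]
        rec = meta[pid]
        hist = PatientHistory(
            patient_id=pid,
            sex=rec.sex,
            birth_year=rec.birth_year,
            death_year=rec.death_year,
            first_occurrence=first_map,
            index_year=prelim_index,
            visit_years=frozenset(visit_years[pid]),
        )
        if hist.index_year is not None and note_years[pid]:
            hist = correct_index_year(hist, min(note_years[pid]))
        histories.append(hist)
    return histories


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

def build_cohort(
    histories: Sequence[PatientHistory],
    window: tuple[int, int] | None = None,
) -> tuple[list[PatientHistory], CohortFunnel]:
    """Apply the study's exclusion filters in their stated order.

    1. a confirmed E11 index diagnosis exists;
    2. age at the index year is at most 100;
    3. at least one hospital visit fell within the five years preceding the
       index year (the visit itself predating the first E11 record).

    Returns the retained histories and a funnel of patient counts after each
    filter.  ``window`` is accepted for interface symmetry with the serialized
    pipeline; the filters themselves only use per-patient years.
    """
    del window  # filters are relative to the per-patient index year
    steps = [("input", len(histories))]

    with_index = [h for h in histories if h.index_year is not None]
    steps.append(("confirmed_e11_index", len(with_index)))

    age_ok = [h for h in with_index if h.index_year - h.birth_year <= 100]
    steps.append(("age_at_index_le_100", len(age_ok)))

    prior_visit = [h for h in age_ok if _has_prior_visit(h)]
    steps.append(("visit_within_5y_before_index", len(prior_visit)))

    return prior_visit, CohortFunnel(steps)


def _has_prior_visit(history: PatientHistory) -> bool:
    index = history.index_year
    recorded = history.recorded_index_year
    limit = recorded if recorded is not None else index
    return any(
        year in history.visit_years
        for year in range(index - 5, index)
        if year < limit
    )


# ---------------------------------------------------------------------------
# Timeframe assignment and transaction building
# ---------------------------------------------------------------------------

def assign_timeframe(offset: int) -> str | None:
    """Map an integer year offset (diagnosis year - index year) to its class.

    Offsets below -5 lie outside the studied window and return ``None``; a
    comorbidity recorded in the index calendar year itself (offset 0) counts
    as post-diagnosis and falls in class ``0-4``.
    """
    if offset < -5:
        return None
    for label, (lo, hi) in CLASS_BOUNDS.items():
        if offset >= lo and (hi is None or offset <= hi):
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def build_transactions(
    cohort: Sequence[PatientHistory],
    follow_up: Mapping[str, int] | None = None,
    window: tuple[int, int] | None = None,
) -> TransactionDB:
    """Emit one transaction per patient per observable timeframe class.

    A class is observable when its calendar window overlaps the patient's
    observation interval ``[first visit year, min(death year, last observed
    year)]``.  Patients contribute *empty* transactions for observable classes
    without new diagnoses, so per-class transaction counts equal per-timeframe
    patient denominators.  The index code E11 itself is never an item, and a
    given (patient, code) pair appears in at most one transaction because only
    first occurrences are kept.

    Parameters
    ----------
    cohort
        Filtered patient histories with confirmed index years.
    follow_up
        Optional map patient id -> last observed year; defaults to each
        patient's last visit year.
    window
        Optional (start, end) data window; an index year outside it raises
        :class:`ConsistencyError`.
    """
    transactions: list[Transaction] = []
    for hist in cohort:
        index = hist.index_year
        if index is None:
            raise ConsistencyError(
                f"patient {hist.patient_id} has no index year; run build_cohort first"
            )
        if window is not None and not (window[0] <= index <= window[1]):
            raise ConsistencyError(
                f"patient {hist.patient_id}: index year {index} outside data "
                f"window {window}"
            )
        last = (
            follow_up[hist.patient_id]
            if follow_up is not None
            else max(hist.visit_years)
        )
        first_obs = min(hist.visit_years)
        end_obs = min(last, hist.death_year) if hist.death_year else last

        items_by_class: dict[str, set[str]] = defaultdict(set)
        for code, year in hist.first_occurrence.items():
            if code == INDEX_CODE:
                continue
            label = assign_timeframe(year - index)
            if label is not None:
                items_by_class[label].add(code)

        for label in CLASS_LABELS:
            lo, hi = CLASS_BOUNDS[label]
            start = index + lo
            end = index + hi if hi is not None else None
            observable = max(start, first_obs) <= min(
                end_obs, end if end is not None else end_obs
            )
            if observable:
                transactions.append(
                    Transaction(
                        patient_id=hist.patient_id,
                        timeframe=label,
                        items=frozenset(items_by_class.get(label, ())),
                    )
                )
    return TransactionDB(transactions)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_transactions_jsonl(db: TransactionDB, path) -> None:
    """One transaction per line: patient id, class label, sorted items."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in db.transactions:
            fh.write(
                json.dumps(
                    {
                        "patient_id": t.patient_id,
                        "class": t.timeframe,
                        "items": sorted(t.items),
                    }
                )
                + "\n"
            )


def read_transactions_jsonl(path) -> TransactionDB:
    transactions = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            transactions.append(
                Transaction(
                    patient_id=obj["patient_id"],
                    timeframe=obj["class"],
                    items=frozenset(obj["items"]),
                )
            )
    return TransactionDB(transactions)


def write_funnel_csv(funnel: CohortFunnel, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["filter", "patients", "share_of_source_pct"]
        )
        writer.writeheader()
        writer.writerows(funnel.report())


_COHORT_FIELDS = [
    "patient_id",
    "sex",
    "birth_year",
    "death_year",
    "index_year",
    "index_source",
    "first_visit_year",
    "last_visit_year",
]


def write_cohort_csv(cohort: Sequence[PatientHistory], path) -> None:
    """Patient-level cohort table (metadata only, not the diagnosis map)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_COHORT_FIELDS)
        writer.writeheader()
        for h in cohort:
            writer.writerow(
                {
                    "patient_id": h.patient_id,
                    "sex": h.sex,
                    "birth_year": h.birth_year,
                    "death_year": h.death_year if h.death_year else "",
                    "index_year": h.index_year,
                    "index_source": h.index_source,
                    "first_visit_year": min(h.visit_years),
                    "last_visit_year": max(h.visit_years),
                }
            )
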