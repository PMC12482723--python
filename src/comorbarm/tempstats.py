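"""Statistical companions to the mined rules.

Crude gender odds ratios with Wald 95% confidence intervals (females as the
reference group), adjusted temporal prevalence ratios across the four
timeframe classes, and per-timeframe descriptive statistics.

The adjusted ratio of a condition in timeframe ``t`` is its prevalence there
divided by the mean of its prevalences over the four timeframes; the vector
lies in [0, 4] and sums to 4, with values above 1 marking periods where the
condition concentrates.

Degenerate 2x2 tables are flagged rather than continuity-corrected: a
condition absent in males is reported as OR 0.00 with CI [0.00, 0.00], not a
Haldane-Anscombe-corrected estimate.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cohort import CLASS_BOUNDS, CLASS_LABELS, PatientHistory, TransactionDB
from .errors import EmptyInputError, ValidationError

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Condition-by-sex counts within one timeframe's observable cohort."""

    m1: int  # males with the condition
    m0: int  # males without
    f1: int  # females with
    f0: int  # females without

    def __post_init__(self) -> None:
        if min(self.m1, self.m0, self.f1, self.f0) < 0:
            raise ValidationError("contingency counts must be non-negative")


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    degenerate: str = "none"  # none | zero_numerator | zero_denominator | empty_margin

    def formatted(self) -> str:
        """Presentation string ``x.xx [a.aa-b.bb]``."""
        if not math.isfinite(self.or_value):
            return "inf"
        return f"{self.or_value:.2f} [{self.ci_low:.2f}-{self.ci_high:.2f}]"


def gender_or(table: ContingencyTable2x2) -> OddsRatioResult:
    """Crude male-vs-female odds ratio with a Wald 95% CI.

    ``OR = (m1 * f0) / (m0 * f1)``;
    ``CI = exp(ln OR +/- 1.96 * sqrt(1/m1 + 1/m0 + 1/f1 + 1/f0))``.

    Zero cells are reported as degenerate flags instead of corrected numbers:
    a zero numerator gives OR 0.00 with CI [0.00, 0.00]; a zero denominator
    gives an infinite OR; an empty sex margin gives ``empty_margin``.
    """
    m1, m0, f1, f0 = table.m1, table.m0, table.f1, table.f0
    if m1 + m0 == 0 or f1 + f0 == 0:
        return OddsRatioResult(math.nan, math.nan, math.nan, "empty_margin")
    if m1 * f0 == 0:
        return OddsRatioResult(0.0, 0.0, 0.0, "zero_numerator")
    if m0 * f1 == 0:
        return OddsRatioResult(math.inf, math.inf, math.inf, "zero_denominator")
    or_value = (m1 * f0) / (m0 * f1)
    se = math.sqrt(1 / m1 + 1 / m0 + 1 / f1 + 1 / f0)
    return OddsRatioResult(
        or_value,
        math.exp(math.log(or_value) - _Z95 * se),
        math.exp(math.log(or_value) + _Z95 * se),
    )


def condition_table(
    db: TransactionDB,
    sex_by_patient: Mapping[str, str],
    condition: str,
    timeframe: str,
) -> ContingencyTable2x2:
    """Build the 2x2 condition-by-sex table for one timeframe class.

    The denominators are the class's observable patients (one transaction per
    patient per class); the cases are those whose class transaction contains
    the condition code.
    """
    m1 = m0 = f1 = f0 = 0
    for t in db.transactions:
        if t.timeframe != timeframe:
            continue
        male = sex_by_patient[t.patient_id] == "M"
        has = condition in t.items
        if male:
            m1, m0 = m1 + has, m0 + (not has)
        else:
            f1, f0 = f1 + has, f0 + (not has)
    return ContingencyTable2x2(m1, m0, f1, f0)


def or_for_condition(
    db: TransactionDB,
    sex_by_patient: Mapping[str, str],
    condition: str,
    timeframe: str,
) -> OddsRatioResult:
    """Crude gender OR of a condition within one timeframe class."""
    return gender_or(condition_table(db, sex_by_patient, condition, timeframe))


# ---------------------------------------------------------------------------
# Adjusted temporal prevalence ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjustedRatioVector:
    condition: str
    ratios: tuple[float, float, float, float]


def adjusted_ratio(
    counts: Sequence[int], denominators: Sequence[int], condition: str = ""
) -> AdjustedRatioVector:
    """Prevalence in each timeframe relative to the cross-timeframe mean.

    ``ratio_t = p_t / mean(p)`` with ``p_t = count_t / n_t``.  The vector lies
    in [0, 4] and sums to 4; a condition occurring only pre-diagnosis scores
    (4, 0, 0, 0).

    Raises
    ------
    ValidationError
        On a zero denominator or on all-zero counts (ratio undefined).
    """
    if len(counts) != 4 or len(denominators) != 4:
        raise ValidationError("adjusted ratios require exactly four timeframes")
    if any(n <= 0 for n in denominators):
        raise ValidationError("all timeframe denominators must be positive")
    p = np.asarray(counts, dtype=float) / np.asarray(denominators, dtype=float)
    mean = p.mean()
    if mean == 0.0:
        raise ValidationError(
            f"adjusted ratio undefined for {condition or 'condition'}: no occurrences"
        )
    return AdjustedRatioVector(condition=condition, ratios=tuple(p / mean))


def condition_adjusted_ratios(
    db: TransactionDB, conditions: Sequence[str] | None = None
) -> list[AdjustedRatioVector]:
    """Adjusted ratio vectors for a set of conditions (default: all items).

    Only computable when all four timeframe classes are populated; conditions
    with zero occurrences overall are skipped.
    """
    if any(c not in db.class_sizes for c in CLASS_LABELS):
        raise EmptyInputError("all four timeframe classes must be populated")
    denominators = [db.class_sizes[c] for c in CLASS_LABELS]
    counts: dict[str, list[int]] = {}
    for t in db.transactions:
        ci = CLASS_LABELS.index(t.timeframe)
        for item in t.items:
            counts.setdefault(item, [0, 0, 0, 0])[ci] += 1
    codes = sorted(counts) if conditions is None else list(conditions)
    out = []
    for code in codes:
        row = counts.get(code)
        if row is None or sum(row) == 0:
            continue
        out.append(adjusted_ratio(row, denominators, condition=code))
    return out


def summarize_adjusted_ratios(
    vectors: Sequence[AdjustedRatioVector],
) -> dict[str, dict[str, float]]:
    """Per-timeframe mean and sample SD of the adjusted ratios."""
    if not vectors:
        raise EmptyInputError("no adjusted-ratio vectors to summarize")
    arr = np.array([v.ratios for v in vectors])
    sd = arr.std(axis=0, ddof=1) if len(vectors) > 1 else np.zeros(4)
    return {
        label: {"mean": float(arr[:, i].mean()), "sd": float(sd[i])}
        for i, label in enumerate(CLASS_LABELS)
    }


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def timeframe_descriptives(
    cohort: Sequence[PatientHistory], db: TransactionDB
) -> dict[str, dict[str, float]]:
    """Per-timeframe patient counts, gender/death percentages, age statistics.

    Ages are taken at the index year.  ``pct_dead`` counts deaths occurring
    during or before the class's calendar window among the class's observable
    patients (for the open-ended last class: any recorded death).
    """
    by_id = {h.patient_id: h for h in cohort}
    n_cohort = len(cohort)
    out: dict[str, dict[str, float]] = {}
    for label in CLASS_LABELS:
        pids = [t.patient_id for t in db.transactions if t.timeframe == label]
        if not pids:
            continue
        hists = [by_id[p] for p in pids]
        ages = np.array([h.index_year - h.birth_year for h in hists], float)
        _, hi = CLASS_BOUNDS[label]
        dead = sum(
            1
            for h in hists
            if h.death_year is not None
            and (hi is None or h.death_year <= h.index_year + hi)
        )
        males = sum(1 for h in hists if h.sex == "M")
        q1, med, q3 = np.percentile(ages, [25, 50, 75])
        out[label] = {
            "n": len(pids),
            "pct_of_cohort": 100.0 * len(pids) / n_cohort,
            "pct_male": 100.0 * males / len(pids),
            "pct_dead": 100.0 * dead / len(pids),
            "age_mean": float(ages.mean()),
            "age_sd": float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
            "age_median": float(med),
            "age_q1": float(q1),
            "age_q3": float(q3),
            "age_iqr": float(q3 - q1),
        }
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_or_table_csv(
    rows: Sequence[tuple[str, str, OddsRatioResult]], path
) -> None:
    """OR table rows (class, condition, result) with a presentation column."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["class", "condition", "or", "ci_low", "ci_high", "degenerate", "display"]
        )
        for label, condition, res in rows:
            writer.writerow(
                [
                    label,
                    condition,
                    f"{res.or_value:.6f}" if math.isfinite(res.or_value) else "inf",
                    f"{res.ci_low:.6f}" if math.isfinite(res.ci_low) else "inf",
                    f"{res.ci_high:.6f}" if math.isfinite(res.ci_high) else "inf",
                    res.degenerate,
                    res.formatted(),
                ]
            )


def write_adjusted_ratios_csv(
    vectors: Sequence[AdjustedRatioVector], path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["condition", *CLASS_LABELS])
        for v in vectors:
            writer.writerow([v.condition, *(f"{r:.6f}" for r in v.ratios)])


def write_descriptives_csv(desc: Mapping[str, Mapping[str, float]], path) -> None:
    fields = [
        "class",
        "n",
        "pct_of_cohort",
        "pct_male",
        "pct_dead",
        "age_mean",
        "age_sd",
        "age_median",
        "age_q1",
        "age_q3",
        "age_iqr",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for label, row in desc.items():
            writer.writerow([label, *(row[f] for f in fields[1:])])
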