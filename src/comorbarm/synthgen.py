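"""Seeded synthetic longitudinal visit data with analytically known ground truth.

The generator emulates the structure of an administrative hospital database
around a type 2 diabetes (E11) index diagnosis: annual visits inside a fixed
data window, per-condition first occurrences planted with per-timeframe
enrichment multipliers and gender rate ratios, attrition and death after the
index year, and free-text notes that sometimes carry an onset year earlier
than the first recorded E11 code.

The generative model is deliberately simple so that every downstream estimate
has a closed form:

* For each patient the observable timeframe classes form a *prefix* of
  ``n5-n1, 0-4, 5-9, 10-`` — the two pre/peri-index classes are always
  observable for cohort-eligible patients, and each later class start must be
  reached before attrition, death or the window end.
* Each (patient, condition) pair first occurs in exactly one timeframe class
  (or never): a single categorical draw assigns class ``m`` with probability
  ``p_m = base * 5 * enrichment_m * gender_factor * bundle_factor`` (the
  configuration is validated so these sum to at most 1).  The rate of the
  condition among class-``m`` transactions is therefore exactly ``p_m``, and
  a flat enrichment vector yields lift exactly 1 in every class.  Conditions
  are independent of each other apart from optional pairwise "bundles" that
  plant co-occurrence for the network stage.  An occurrence assigned to a
  class the patient never becomes observable in is simply never recorded.

:func:`class_conditional_rates`, :func:`implied_lift` and
:func:`implied_gender_or` evaluate those marginals exactly, giving the
recovery-test oracle against which the mining and statistics stages are
checked.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import CLASS_LABELS, INDEX_CODE, VisitRecord, normalize_icd
from .errors import ConfigError, ValidationError

#: Nominal length (years) of one timeframe class; scales annual base rates to
#: per-class occurrence probabilities.
CLASS_NOMINAL_YEARS = 5

#: In-window but out-of-scope filler codes (chapters O-Z) used to make visits
#: non-empty without perturbing the mined itemsets.
_FILLER_CODES = ("Z000", "Z038", "R51", "O800", "R104", "S525", "T784", "Q210")

_DATED_NOTE_TEMPLATES = (
    "Known diabetes since {y}, on oral antidiabetic therapy",
    "T2DM first diagnosed in {y} per referral letter",
    "History of type 2 diabetes; E11 first recorded {y}",
    "Patient reports diabetes onset around {y} at family physician",
)
_DATELESS_NOTE_TEMPLATES = (
    "No prior history of diabetes documented",
    "Follow-up visit for chronic conditions; diabetes well controlled",
    "Hypertension since 1999; no diabetes date on record",
)


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSpec:
    """One plantable condition: code, base rate, gender effect, enrichment.

    ``base_rate`` is an annual first-occurrence probability scale; the
    per-class probability is ``base_rate * 5 * enrichment[m]`` (clipped to
    [0, 1]), multiplied by ``male_rate_ratio`` for male patients.
    """

    code: str
    base_rate: float
    male_rate_ratio: float
    enrichment: tuple[float, float, float, float]
    name: str = ""


@dataclass(frozen=True)
class Bundle:
    """Pairwise co-occurrence plant: carriers get both rates multiplied."""

    code_a: str
    code_b: str
    factor: float
    carrier_prob: float


@dataclass
class SimConfig:
    """Full specification of one synthetic population."""

    n_patients: int
    conditions: list[ConditionSpec]
    start_year: int = 2007
    end_year: int = 2021
    index_year_weights: dict[int, float] | None = None
    male_fraction: float = 0.46
    attrition: float = 0.06
    death_hazard: float = 0.02
    note_coverage: float = 0.77
    note_earlier_onset_fraction: float = 0.08
    frac_no_e11: float = 0.02
    frac_over_age: float = 0.01
    frac_no_prior_visit: float = 0.05
    bundles: list[Bundle] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        validate_config(self)

    @property
    def index_years(self) -> list[int]:
        if self.index_year_weights is not None:
            return sorted(self.index_year_weights)
        return list(range(self.start_year + 1, self.end_year + 1))

    @property
    def index_probs(self) -> np.ndarray:
        years = self.index_years
        if self.index_year_weights is not None:
            w = np.array([self.index_year_weights[y] for y in years], float)
        else:
            w = np.ones(len(years))
        return w / w.sum()


def validate_config(config: SimConfig) -> None:
    """Raise :class:`ConfigError` naming the first offending field."""
    if config.n_patients < 0:
        raise ConfigError("n_patients must be non-negative")
    if config.end_year <= config.start_year:
        raise ConfigError("end_year must exceed start_year")
    for name in (
        "male_fraction",
        "attrition",
        "death_hazard",
        "note_coverage",
        "note_earlier_onset_fraction",
        "frac_no_e11",
        "frac_over_age",
        "frac_no_prior_visit",
    ):
        value = getattr(config, name)
        if not 0.0 <= value <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1], got {value}")
    if config.frac_no_e11 + config.frac_over_age + config.frac_no_prior_visit > 1:
        raise ConfigError("planted violation fractions sum above 1")
    codes = set()
    for spec in config.conditions:
        if len(spec.enrichment) != 4:
            raise ConfigError(f"enrichment for {spec.code} must have length 4")
        if spec.base_rate < 0 or spec.base_rate > 1:
            raise ConfigError(f"base_rate for {spec.code} must be in [0, 1]")
        if spec.male_rate_ratio < 0:
            raise ConfigError(f"male_rate_ratio for {spec.code} must be >= 0")
        if any(e < 0 for e in spec.enrichment):
            raise ConfigError(f"enrichment for {spec.code} must be >= 0")
        norm = normalize_icd(spec.code)
        if norm != spec.code:
            raise ConfigError(f"condition code {spec.code!r} is not a normalized icd3")
        if spec.code == INDEX_CODE:
            raise ConfigError("the index code E11 cannot be a planted condition")
        if spec.code in codes:
            raise ConfigError(f"duplicate condition code {spec.code}")
        codes.add(spec.code)
    bundle_factors = {}
    for b in config.bundles:
        bundle_factors[b.code_a] = max(b.factor, 1.0)
        bundle_factors[b.code_b] = max(b.factor, 1.0)
    for spec in config.conditions:
        worst = (
            spec.base_rate
            * CLASS_NOMINAL_YEARS
            * sum(spec.enrichment)
            * max(spec.male_rate_ratio, 1.0)
            * bundle_factors.get(spec.code, 1.0)
        )
        if worst > 1.0 + 1e-12:
            raise ConfigError(
                f"first-occurrence class probabilities for {spec.code} sum to "
                f"{worst:.3f} > 1; lower base_rate, enrichment or bundle factor"
            )
    bundle_members: set[str] = set()
    for b in config.bundles:
        for c in (b.code_a, b.code_b):
            if c not in codes:
                raise ConfigError(f"bundle code {c} not in condition catalog")
            if c in bundle_members:
                raise ConfigError(f"code {c} appears in more than one bundle")
            bundle_members.add(c)
        if b.factor < 0 or not 0.0 <= b.carrier_prob <= 1.0:
            raise ConfigError("bundle factor must be >= 0 and carrier_prob in [0, 1]")
    if config.index_year_weights is not None:
        for y in config.index_year_weights:
            if not config.start_year + 1 <= y <= config.end_year:
                raise ConfigError(
                    f"index_year_weights year {y} outside (start_year, end_year]"
                )


# ---------------------------------------------------------------------------
# Analytic ground truth
# ---------------------------------------------------------------------------

def _bundle_lookup(config: SimConfig) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for b in config.bundles:
        out[b.code_a] = (b.factor, b.carrier_prob)
        out[b.code_b] = (b.factor, b.carrier_prob)
    return out


def _class_probs(spec: ConditionSpec, male: bool, factor: float) -> list[float]:
    g = spec.male_rate_ratio if male else 1.0
    return [
        spec.base_rate * CLASS_NOMINAL_YEARS * e * g * factor
        for e in spec.enrichment
    ]


def class_conditional_rates(
    config: SimConfig,
) -> dict[str, dict[str, list[float]]]:
    """Exact per-class presence probabilities for every condition.

    Returns ``{code: {"overall"|"M"|"F": [rate per class]}}`` where the rate
    for class ``m`` is the probability that a class-``m`` transaction of a
    patient (of the given sex) contains the code, mixing over bundle carrier
    status.  Under the single-categorical-draw model this is the class
    probability ``p_m`` itself.
    """
    bundles = _bundle_lookup(config)
    rates: dict[str, dict[str, list[float]]] = {}
    for spec in config.conditions:
        factor, cp = bundles.get(spec.code, (1.0, 0.0))
        by_sex: dict[str, list[float]] = {}
        for sex, male in (("M", True), ("F", False)):
            plain = _class_probs(spec, male, 1.0)
            if cp > 0:
                carrier = _class_probs(spec, male, factor)
                by_sex[sex] = [
                    cp * c + (1 - cp) * p for c, p in zip(carrier, plain)
                ]
            else:
                by_sex[sex] = plain
        mf = config.male_fraction
        by_sex["overall"] = [
            mf * m + (1 - mf) * f for m, f in zip(by_sex["M"], by_sex["F"])
        ]
        rates[spec.code] = by_sex
    return rates


def expected_class_weights(config: SimConfig) -> dict[str, float]:
    """P(class observable) per class for a cohort-eligible patient.

    The pre-index and peri-index classes are observable by construction; a
    later class starting ``s`` years after the index is observable iff the
    window end is not reached and neither attrition nor death strikes first:
    ``P = sum_y q_y 1[y + s <= end] (1-attrition)^s (1-death)^(s-1)``.
    """
    years = config.index_years
    probs = config.index_probs
    a, d = config.attrition, config.death_hazard
    weights = {"n5-n1": 1.0, "0-4": 1.0}
    for label, s in (("5-9", 5), ("10-", 10)):
        w = 0.0
        for y, q in zip(years, probs):
            if y + s <= config.end_year:
                w += q * (1 - a) ** s * (1 - d) ** (s - 1)
        weights[label] = w
    return weights


def implied_lift(config: SimConfig, code: str, timeframe: str) -> float:
    """Closed-form lift of a planted condition against one timeframe class.

    ``P(code in a class-c transaction) / P(code in any transaction)``, with
    the transaction population weighted by the expected class sizes.

    Raises
    ------
    KeyError
        If the code is not in the condition catalog or the class is unknown.
    """
    rates = class_conditional_rates(config)
    if code not in rates:
        raise KeyError(f"unknown condition code {code!r}")
    if timeframe not in CLASS_LABELS:
        raise KeyError(f"unknown timeframe class {timeframe!r}")
    weights = expected_class_weights(config)
    r = rates[code]["overall"]
    w = [weights[c] for c in CLASS_LABELS]
    overall = sum(wi * ri for wi, ri in zip(w, r)) / sum(w)
    if overall == 0.0:
        raise ValidationError(f"condition {code} never occurs under this config")
    return r[CLASS_LABELS.index(timeframe)] / overall


def implied_gender_or(config: SimConfig, code: str, timeframe: str) -> float:
    """Male-vs-female odds ratio of presence in a class transaction.

    Returns ``inf`` when the condition is female-absent and 0.0 when it is
    male-absent, mirroring the degenerate handling of the estimator.
    """
    rates = class_conditional_rates(config)
    if code not in rates:
        raise KeyError(f"unknown condition code {code!r}")
    idx = CLASS_LABELS.index(timeframe)
    rm = rates[code]["M"][idx]
    rf = rates[code]["F"][idx]
    if rm == 0.0:
        return 0.0
    if rf == 0.0 or rm == 1.0:
        return math.inf
    return (rm / (1 - rm)) / (rf / (1 - rf))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    n_patients: int
    n_eligible: int
    class_weights: dict[str, float]
    rates: dict[str, dict[str, list[float]]]
    implied_lifts: dict[str, dict[str, float]]
    implied_ors: dict[str, dict[str, float]]
    true_index_year: dict[str, int]
    eligible: dict[str, bool]
    planted_violations: dict[str, int]

    def lift_mc_interval(
        self,
        code: str,
        timeframe: str,
        alpha: float = 0.01,
        reps: int = 20_000,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, float]:
        """Monte-Carlo interval for the *estimated* lift under the model.

        Simulates the generative sampling exactly at the count level: patients
        fall into observability strata (classes observable = a prefix of the
        four, with nested probabilities given by ``class_weights``), and
        within a stratum each patient's first-occurrence class is one
        categorical draw, so per-class presence counts are multinomial —
        capturing the negative coupling between classes that a per-class
        binomial would miss.  Returns the ``(alpha/2, 1-alpha/2)`` quantiles
        of the plug-in lift estimate.
        """
        rng = rng or np.random.default_rng(0)
        n = self.n_eligible
        w3 = self.class_weights["5-9"]
        w4 = self.class_weights["10-"]
        r = np.array(self.rates[code]["overall"])
        idx = CLASS_LABELS.index(timeframe)

        # strata: prefix length 2 / 3 / 4 (nested observability)
        strata_p = np.array([1.0 - w3, w3 - w4, w4])
        n_strata = rng.multinomial(n, strata_p, size=reps)  # (reps, 3)

        x = np.zeros((reps, 4))
        for s, prefix in enumerate((2, 3, 4)):
            pv = np.append(r[:prefix], 1.0 - r[:prefix].sum())
            draws = rng.multinomial(n_strata[:, s], pv)  # (reps, prefix+1)
            x[:, :prefix] += draws[:, :prefix]

        n_c = np.empty((reps, 4))
        n_c[:, 0] = n_c[:, 1] = n
        n_c[:, 2] = n_strata[:, 1] + n_strata[:, 2]
        n_c[:, 3] = n_strata[:, 2]
        n_c = np.maximum(n_c, 1)
        total_tx = n_c.sum(axis=1)
        total_x = x.sum(axis=1)
        ok = total_x > 0
        lifts = (x[ok, idx] / n_c[ok, idx]) * total_tx[ok] / total_x[ok]
        lo, hi = np.quantile(lifts, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)


def _empty_truth() -> GroundTruth:
    return GroundTruth(
        n_patients=0,
        n_eligible=0,
        class_weights={},
        rates={},
        implied_lifts={},
        implied_ors={},
        true_index_year={},
        eligible={},
        planted_violations={},
    )


# ---------------------------------------------------------------------------
# Note rendering
# ---------------------------------------------------------------------------

def render_note(
    index_year: int,
    onset_year: int | None,
    rng: np.random.Generator | None = None,
) -> str:
    """Render a free-text note, optionally embedding an earlier onset year.

    The dated templates place a 4-digit year after one of the keyword stems
    the extractor scans for, so ``extract_onset_year(render_note(i, o)) == o``
    holds for every supported template; the dateless templates yield ``None``.
    """
    if onset_year is not None and onset_year > index_year:
        raise ValidationError(
            f"onset year {onset_year} after index year {index_year}"
        )
    if onset_year is None:
        pool = _DATELESS_NOTE_TEMPLATES
        pick = 0 if rng is None else int(rng.integers(len(pool)))
        return pool[pick]
    pool = _DATED_NOTE_TEMPLATES
    pick = 0 if rng is None else int(rng.integers(len(pool)))
    return pool[pick].format(y=onset_year)


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _rawify(code: str, rng: np.random.Generator) -> str:
    """Emit a raw-looking variant of a 3-character code (suffix, dot, case)."""
    u = rng.random()
    if u < 0.30:
        return code + str(rng.integers(0, 10))
    if u < 0.45:
        return f"{code}.{rng.integers(0, 10)}"
    if u < 0.60:
        return (code + str(rng.integers(0, 10))).lower()
    return code


def generate_population(
    config: SimConfig,
) -> tuple[list[VisitRecord], GroundTruth]:
    """Sample a full synthetic population and its ground truth.

    Records are returned sorted by (patient, year); identical configs give
    bit-identical output.  Each patient's randomness comes from a sub-stream
    keyed by (seed, patient index), so per-patient output does not depend on
    generation order.
    """
    if config.n_patients == 0:
        return [], _empty_truth()

    n = config.n_patients
    n_no_e11 = round(config.frac_no_e11 * n)
    n_over_age = round(config.frac_over_age * n)
    n_no_prior = round(config.frac_no_prior_visit * n)
    n_eligible = n - n_no_e11 - n_over_age - n_no_prior
    if n_eligible < 0:
        raise ConfigError("planted violation fractions leave no eligible patients")

    groups = (
        ["eligible"] * n_eligible
        + ["no_e11"] * n_no_e11
        + ["over_age"] * n_over_age
        + ["no_prior_visit"] * n_no_prior
    )

    specs = config.conditions
    base = np.array([s.base_rate for s in specs])
    rr = np.array([s.male_rate_ratio for s in specs])
    enrich = np.array([s.enrichment for s in specs])  # (K, 4)
    bundles = _bundle_lookup(config)
    bundle_factor = np.array([bundles.get(s.code, (1.0, 0.0))[0] for s in specs])
    bundle_cp = np.array([bundles.get(s.code, (1.0, 0.0))[1] for s in specs])
    codes = [s.code for s in specs]

    index_years = np.array(config.index_years)
    index_probs = config.index_probs

    records: list[VisitRecord] = []
    true_index: dict[str, int] = {}
    eligible_map: dict[str, bool] = {}

    pad = max(6, len(str(n)))
    for i in range(n):
        pid = f"P{i:0{pad}d}"
        group = groups[i]
        rng = np.random.default_rng([config.seed, i])

        male = rng.random() < config.male_fraction
        index = int(index_years[rng.choice(len(index_years), p=index_probs)])
        if group == "over_age":
            age = int(rng.integers(101, 106))
        else:
            age = int(np.clip(round(rng.normal(63.2, 13.9)), 18, 99))
        birth_year = index - age

        t_att = (
            int(rng.geometric(config.attrition)) if config.attrition > 0 else 10**6
        )
        t_death = (
            int(rng.geometric(config.death_hazard))
            if config.death_hazard > 0
            else 10**6
        )
        end_obs = min(config.end_year, index + t_att - 1, index + t_death)
        death_year = index + t_death if index + t_death <= end_obs else None

        if group == "no_prior_visit":
            entry = index
        else:
            entry = int(rng.integers(max(config.start_year, index - 5), index))

        # observable class prefix (class starts at index + s)
        observable = np.array(
            [True, True, index + 5 <= end_obs, index + 10 <= end_obs]
        )
        if group == "no_prior_visit":
            observable[0] = False

        # one categorical first-occurrence draw per condition: class m with
        # probability p_m, or never (validated so the p_m sum to <= 1)
        carrier = rng.random(len(specs)) < bundle_cp
        factor = np.where(carrier, bundle_factor, 1.0)
        g = np.where(male, rr, 1.0)
        p = base[:, None] * CLASS_NOMINAL_YEARS * enrich * (g * factor)[:, None]
        cum = np.cumsum(p, axis=1)  # (K, 4)
        u = rng.random(len(specs))
        assigned = np.full(len(specs), -1)
        hit = u < cum[:, 3]
        assigned[hit] = np.argmax(u[hit, None] < cum[hit], axis=1)

        visits: dict[int, list[str]] = {entry: [_FILLER_CODES[i % len(_FILLER_CODES)]]}
        if entry < index - 1 and rng.random() < 0.5:
            extra = int(rng.integers(entry, index))
            visits.setdefault(extra, []).append(
                _FILLER_CODES[int(rng.integers(len(_FILLER_CODES)))]
            )
        # terminal contact: the last visit marks the end of observation, so
        # downstream follow-up (last visit year) matches the generative model
        visits.setdefault(end_obs, []).append(
            _FILLER_CODES[int(rng.integers(len(_FILLER_CODES)))]
        )

        # index diagnosis record (and optional delayed recording with a note)
        noted = rng.random() < config.note_coverage
        corrected = (
            group != "no_e11"
            and noted
            and rng.random() < config.note_earlier_onset_fraction
        )
        recorded = index
        if corrected:
            recorded = min(index + int(rng.integers(1, 4)), end_obs)
            if recorded == index:
                corrected = False
        note: str | None = None
        if noted:
            onset = index if corrected else None
            note = render_note(recorded, onset, rng)
        if group != "no_e11":
            visits.setdefault(recorded, []).append(_rawify(INDEX_CODE, rng))

        # condition first occurrences and duplicate echoes
        class_windows = [
            (entry, index - 1),
            (index, min(end_obs, index + 4)),
            (index + 5, min(end_obs, index + 9)),
            (index + 10, end_obs),
        ]
        for k in np.flatnonzero(assigned >= 0):
            m = int(assigned[k])
            if not observable[m]:
                continue
            lo, hi = class_windows[m]
            year = int(rng.integers(lo, hi + 1))
            visits.setdefault(year, []).append(_rawify(codes[k], rng))
            if year < end_obs and rng.random() < 0.4:
                echo = int(rng.integers(year + 1, end_obs + 1))
                visits.setdefault(echo, []).append(_rawify(codes[k], rng))

        note_year = recorded if group != "no_e11" else entry
        sex = "M" if male else "F"
        for year in sorted(visits):
            records.append(
                VisitRecord(
                    patient_id=pid,
                    year=year,
                    sex=sex,
                    birth_year=birth_year,
                    death_year=death_year,
                    icd_codes=tuple(sorted(visits[year])),
                    note_text=note if year == note_year else None,
                )
            )
        true_index[pid] = index
        eligible_map[pid] = group == "eligible"

    records.sort(key=lambda r: (r.patient_id, r.year))

    rates = class_conditional_rates(config)
    truth = GroundTruth(
        n_patients=n,
        n_eligible=n_eligible,
        class_weights=expected_class_weights(config),
        rates=rates,
        implied_lifts={
            c: {cls: implied_lift(config, c, cls) for cls in CLASS_LABELS}
            for c in codes
        },
        implied_ors={
            c: {cls: implied_gender_or(config, c, cls) for cls in CLASS_LABELS}
            for c in codes
        },
        true_index_year=true_index,
        eligible=eligible_map,
        planted_violations={
            "no_e11": n_no_e11,
            "over_age": n_over_age,
            "no_prior_visit": n_no_prior,
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# Default and benchmark configurations
# ---------------------------------------------------------------------------

def default_catalog() -> list[ConditionSpec]:
    """Hand-curated catalog of common diabetes-era comorbidities.

    Base rates, gender rate ratios and per-timeframe enrichments are chosen to
    echo the qualitative temporal patterns reported for hospital cohorts:
    musculoskeletal, ophthalmic and gynaecological conditions enriched before
    the diagnosis; metabolic, renal and cardiovascular conditions in the first
    post-diagnosis years; infections and kidney failure late in follow-up.
    """
    rows = [
        ("I10", "hypertension", 0.025, 1.13, (1.2, 1.4, 0.9, 0.6)),
        ("E78", "hyperlipidaemia", 0.032, 0.99, (0.9, 1.5, 0.9, 0.6)),
        ("H52", "disorders of refraction and accommodation", 0.032, 0.76, (1.3, 1.1, 0.8, 0.6)),
        ("I20", "angina pectoris", 0.030, 0.99, (1.2, 1.2, 0.9, 0.7)),
        ("I25", "ischaemic heart disease", 0.025, 1.14, (1.0, 1.3, 1.0, 0.7)),
        ("H36", "diabetic retinopathy", 0.027, 0.81, (0.9, 1.4, 1.0, 0.7)),
        ("H25", "senile cataract", 0.022, 0.68, (1.1, 1.1, 0.9, 0.8)),
        ("J18", "pneumonia", 0.022, 1.12, (0.9, 1.1, 1.1, 1.1)),
        ("E66", "obesity", 0.022, 0.74, (0.9, 1.6, 0.7, 0.5)),
        ("M47", "spondylosis", 0.021, 0.81, (1.5, 1.0, 0.8, 0.6)),
        ("H57", "other disorders of eye and adnexa", 0.020, 0.92, (1.0, 1.1, 1.0, 0.8)),
        ("I50", "chronic heart failure", 0.020, 1.18, (0.8, 1.2, 1.1, 1.0)),
        ("M54", "dorsalgia", 0.019, 0.84, (1.45, 1.0, 0.8, 0.6)),
        ("I70", "atherosclerosis", 0.018, 1.16, (0.9, 1.2, 1.0, 0.9)),
        ("N18", "chronic kidney disease", 0.017, 0.87, (0.7, 1.5, 1.25, 1.2)),
        ("G63", "polyneuropathy in diseases classified elsewhere", 0.010, 0.99, (0.6, 1.8, 1.1, 1.1)),
        ("E79", "hyperuricemia", 0.009, 0.91, (0.7, 1.6, 1.0, 0.9)),
        ("J96", "chronic respiratory failure", 0.010, 1.48, (0.6, 1.5, 1.4, 1.7)),
        ("E87", "fluid, electrolyte and acid-base disorders", 0.010, 1.12, (0.7, 1.5, 1.35, 1.3)),
        ("N17", "acute kidney injury", 0.007, 1.26, (0.6, 1.5, 1.5, 1.7)),
        ("E86", "volume depletion", 0.008, 0.82, (0.7, 1.5, 1.45, 1.6)),
        ("D64", "other anaemias", 0.013, 0.93, (0.8, 1.5, 1.1, 1.2)),
        ("M81", "osteoporosis", 0.014, 0.20, (1.6, 0.9, 0.8, 0.7)),
        ("J06", "upper respiratory infection", 0.005, 0.66, (1.6, 0.9, 0.8, 0.7)),
        ("N92", "excessive, frequent and irregular menstruation", 0.005, 0.0, (1.5, 0.9, 0.7, 0.5)),
        ("N95", "menopausal and perimenopausal disorders", 0.010, 0.0, (1.4, 1.0, 0.7, 0.5)),
        ("B34", "acute viral infection", 0.009, 1.00, (0.7, 0.9, 1.6, 2.6)),
        ("N39", "lower urinary infection", 0.010, 1.20, (0.9, 1.0, 1.1, 1.2)),
        ("N30", "cystitis", 0.012, 0.79, (0.9, 1.0, 1.2, 1.0)),
        ("G62", "other polyneuropathies", 0.008, 1.16, (0.8, 1.2, 1.3, 1.1)),
        ("N19", "unspecified kidney failure", 0.004, 1.45, (0.5, 1.0, 1.4, 2.4)),
        ("K57", "diverticulosis of large intestine", 0.005, 0.92, (0.8, 1.0, 1.4, 1.0)),
        ("I44", "atrioventricular and left bundle-branch block", 0.004, 1.48, (0.6, 1.5, 1.0, 0.9)),
        ("I65", "occlusion and stenosis of precerebral arteries", 0.007, 1.44, (0.8, 1.1, 1.2, 1.0)),
        ("I73", "peripheral arterial disease", 0.005, 1.80, (0.7, 1.1, 1.5, 1.2)),
    ]
    return [
        ConditionSpec(code=c, name=nm, base_rate=b, male_rate_ratio=r, enrichment=e)
        for c, nm, b, r, e in rows
    ]


def default_bundles() -> list[Bundle]:
    """Concordant-disease co-occurrence plants exercising the network stage."""
    return [
        Bundle("I10", "I25", factor=1.6, carrier_prob=0.30),
        Bundle("N18", "I50", factor=1.8, carrier_prob=0.20),
        Bundle("E78", "E66", factor=1.5, carrier_prob=0.25),
    ]


def default_config(n_patients: int = 2000, seed: int = 0) -> SimConfig:
    """Demo configuration: the curated catalog plus co-occurrence bundles."""
    return SimConfig(
        n_patients=n_patients,
        conditions=default_catalog(),
        bundles=default_bundles(),
        seed=seed,
    )


def benchmark_config(
    n_patients: int = 25_000, n_conditions: int = 100, seed: int = 0
) -> SimConfig:
    """Recovery-benchmark configuration with randomized planted effects.

    Each condition gets a log-uniform base rate, a log-uniform gender rate
    ratio in [0.5, 2], and a single enriched timeframe with multiplier drawn
    from [1.5, 3].  Used by the parameter-recovery tests and the acceptance
    script.
    """
    rng = np.random.default_rng(seed)
    letters = "ABCDFGHIJKLMN"  # skip chapter E to keep clear of E11
    specs = []
    used = set()
    while len(specs) < n_conditions:
        code = f"{letters[int(rng.integers(len(letters)))]}{int(rng.integers(10, 100))}"
        if code in used:
            continue
        used.add(code)
        base = float(np.exp(rng.uniform(np.log(0.004), np.log(0.015))))
        ratio = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        enrichment = [1.0, 1.0, 1.0, 1.0]
        enrichment[int(rng.integers(4))] = float(rng.uniform(1.5, 3.0))
        specs.append(
            ConditionSpec(
                code=code,
                base_rate=base,
                male_rate_ratio=ratio,
                enrichment=tuple(enrichment),
            )
        )
    return SimConfig(n_patients=n_patients, conditions=specs, seed=seed)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_VISIT_FIELDS = [
    "patient_id",
    "year",
    "sex",
    "birth_year",
    "death_year",
    "icd_codes",
    "note_text",
]


def write_visits_csv(records: Sequence[VisitRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_VISIT_FIELDS)
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "patient_id": r.patient_id,
                    "year": r.year,
                    "sex": r.sex,
                    "birth_year": r.birth_year,
                    "death_year": r.death_year if r.death_year else "",
                    "icd_codes": ";".join(r.icd_codes),
                    "note_text": r.note_text or "",
                }
            )


def read_visits_csv(path) -> list[VisitRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                VisitRecord(
                    patient_id=row["patient_id"],
                    year=int(row["year"]),
                    sex=row["sex"],
                    birth_year=int(row["birth_year"]),
                    death_year=int(row["death_year"]) if row["death_year"] else None,
                    icd_codes=tuple(row["icd_codes"].split(";")) if row["icd_codes"] else (),
                    note_text=row["note_text"] or None,
                )
            )
    return records


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "n_patients": truth.n_patients,
                "n_eligible": truth.n_eligible,
                "class_weights": truth.class_weights,
                "rates": truth.rates,
                "implied_lifts": truth.implied_lifts,
                "implied_ors": {
                    c: {k: (v if math.isfinite(v) else None) for k, v in d.items()}
                    for c, d in truth.implied_ors.items()
                },
                "true_index_year": truth.true_index_year,
                "eligible": truth.eligible,
                "planted_violations": truth.planted_violations,
            },
            fh,
            indent=1,
        )


def read_ground_truth_json(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return GroundTruth(
        n_patients=obj["n_patients"],
        n_eligible=obj["n_eligible"],
        class_weights=obj["class_weights"],
        rates=obj["rates"],
        implied_lifts=obj["implied_lifts"],
        implied_ors={
            c: {k: (math.inf if v is None else v) for k, v in d.items()}
            for c, d in obj["implied_ors"].items()
        },
        true_index_year=obj["true_index_year"],
        eligible=obj["eligible"],
        planted_violations=obj["planted_violations"],
    )
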