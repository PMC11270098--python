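"""Synthetic in-hospital-cardiac-arrest (IHCA) cohort generator.

Emulates a claims-style EHR cohort: every patient carries an ordered,
dated sequence of visits with diagnosis-code sets, a terminal resuscitation
(arrest) record identified by procedure codes 99.60/99.63, and an optional
death day.  Diagnosis draws are Bernoulli per visit with within-visit
co-occurrence boosts applied conditionally on codes already drawn in a fixed
catalogue order, which is the minimal reproducible mechanism for planting
comorbidity confounding.  Thirty-day mortality follows a per-visit logistic
model that is additive in the visit's diagnosis-code effects; a triggered
death truncates the visit sequence, so no visit postdates death and the
final record of a dying patient is the record that killed them.

All randomness flows through per-patient substreams derived from
``(seed, patient_index)`` so cohorts are byte-reproducible and individual
patients can be regenerated in isolation.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger("dshap_ehr")

DEFAULT_IHCA_PROCEDURE_CODES = frozenset({"99.60", "99.63"})
#: inclusive day window for the mortality label
MORTALITY_WINDOW_DAYS = 30


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


class DataError(ValueError):
    """Malformed cohort data encountered while reading or validating."""


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic sub-seed for a named pipeline stage (< 2**31)."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CodeDef:
    """One diagnosis code in the synthetic catalogue.

    ``cooccur`` maps *earlier* catalogue codes to multiplicative prevalence
    boosts: if code ``j`` was already drawn in the visit, this code's
    prevalence is multiplied by ``cooccur[j]`` (boosts < 1 suppress).  The
    boosted prevalence is clamped to [0, 1].
    """

    code: str
    label: str
    base_prevalence: float
    mortality_logodds: float = 0.0
    cooccur: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not (0.0 <= self.base_prevalence <= 1.0):
            raise ConfigError(
                f"field 'base_prevalence' of code {self.code!r}: "
                f"{self.base_prevalence} not in [0, 1]"
            )
        if not math.isfinite(self.mortality_logodds):
            raise ConfigError(
                f"field 'mortality_logodds' of code {self.code!r}: must be finite"
            )
        for other, boost in self.cooccur.items():
            if boost < 0:
                raise ConfigError(
                    f"field 'cooccur' of code {self.code!r}: boost for "
                    f"{other!r} is {boost}, must be >= 0"
                )


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort's generating process."""

    n_patients: int
    catalogue: list[CodeDef]
    visits_mean: float = 9.3
    visits_dispersion: float = 4.0
    inter_visit_days_mean: float = 30.0
    baseline_logodds: float = -3.3
    ihca_procedure_codes: frozenset[str] = DEFAULT_IHCA_PROCEDURE_CODES
    ihca_rate: float = 1.0
    extra_ihca_rate: float = 0.026
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError(f"field 'n_patients': {self.n_patients} must be >= 0")
        if not self.visits_mean > 0:
            raise ConfigError(f"field 'visits_mean': {self.visits_mean} must be > 0")
        if not self.visits_dispersion > 0:
            raise ConfigError(
                f"field 'visits_dispersion': {self.visits_dispersion} must be > 0"
            )
        if not self.inter_visit_days_mean > 0:
            raise ConfigError(
                f"field 'inter_visit_days_mean': {self.inter_visit_days_mean} must be > 0"
            )
        if not (0.0 <= self.ihca_rate <= 1.0):
            raise ConfigError(f"field 'ihca_rate': {self.ihca_rate} not in [0, 1]")
        if not (0.0 <= self.extra_ihca_rate <= 1.0):
            raise ConfigError(
                f"field 'extra_ihca_rate': {self.extra_ihca_rate} not in [0, 1]"
            )
        seen: set[str] = set()
        for cd in self.catalogue:
            cd.validate()
            if cd.code in seen:
                raise ConfigError(f"field 'catalogue': duplicate code {cd.code!r}")
            seen.add(cd.code)
        for cd in self.catalogue:
            for other in cd.cooccur:
                if other not in seen:
                    raise ConfigError(
                        f"field 'cooccur' of code {cd.code!r}: unknown code {other!r}"
                    )


@dataclass
class Visit:
    patient_id: str
    visit_index: int
    day_offset: int
    setting: str  # "inpatient" | "outpatient"; cosmetic metadata
    dx_codes: set[str]
    proc_codes: set[str]


@dataclass
class Patient:
    patient_id: str
    sex: str
    age_at_first_visit: int
    visits: list[Visit]
    death_day_offset: Optional[int] = None


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), patient_index]))


def _visit_risks(spec: CohortSpec, dx_matrix: np.ndarray) -> np.ndarray:
    """Per-visit 30-day death probability from the additive logistic model."""
    logodds = np.array([c.mortality_logodds for c in spec.catalogue])
    z = spec.baseline_logodds + dx_matrix @ logodds
    return 1.0 / (1.0 + np.exp(-z))


def visit_risk(spec: CohortSpec, visit: Visit) -> float:
    """True (generator-side) 30-day death probability of one visit."""
    z = spec.baseline_logodds + sum(
        c.mortality_logodds for c in spec.catalogue if c.code in visit.dx_codes
    )
    return 1.0 / (1.0 + math.exp(-z))


def _draw_dx_matrix(spec: CohortSpec, n_visits: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a (n_visits, n_codes) 0/1 matrix with sequential co-occurrence."""
    n_codes = len(spec.catalogue)
    u = rng.random((n_visits, n_codes))
    drawn = np.zeros((n_visits, n_codes), dtype=bool)
    index = {c.code: i for i, c in enumerate(spec.catalogue)}
    for ci, cd in enumerate(spec.catalogue):
        p = np.full(n_visits, cd.base_prevalence)
        for other, boost in cd.cooccur.items():
            oi = index[other]
            if oi < ci:
                p = np.where(drawn[:, oi], p * boost, p)
        np.clip(p, 0.0, 1.0, out=p)
        drawn[:, ci] = u[:, ci] < p
    return drawn


def plant_mortality(
    spec: CohortSpec, patient: Patient, seed: int
) -> Optional[int]:
    """Sample a death day for an already-generated visit sequence.

    After each visit, death within the next 30 days occurs with probability
    ``logistic(baseline_logodds + sum of the visit's code effects)``; the
    first triggering visit fixes the death day uniformly in
    ``(day_offset, day_offset + 30]``.  Returns ``None`` when no visit
    triggers.  (``sample_cohort`` additionally truncates the sequence at the
    triggering visit; this standalone entry point leaves visits untouched.)
    """
    rng = np.random.default_rng(seed)
    n = len(patient.visits)
    if n == 0:
        return None
    dx = np.zeros((n, len(spec.catalogue)), dtype=bool)
    index = {c.code: i for i, c in enumerate(spec.catalogue)}
    for vi, v in enumerate(patient.visits):
        for code in v.dx_codes:
            if code in index:
                dx[vi, index[code]] = True
    risks = _visit_risks(spec, dx)
    triggers = rng.random(n) < risks
    if not triggers.any():
        return None
    t = int(np.argmax(triggers))
    return patient.visits[t].day_offset + int(rng.integers(1, MORTALITY_WINDOW_DAYS + 1))


def _sample_patient(spec: CohortSpec, patient_index: int, seed: int) -> Patient:
    rng = _patient_rng(seed, patient_index)
    pid = f"P{patient_index:06d}"

    m, k = spec.visits_mean, spec.visits_dispersion
    n_visits = max(1, int(rng.negative_binomial(k, k / (k + m))))
    gaps = np.maximum(1, rng.poisson(spec.inter_visit_days_mean, size=n_visits))
    gaps[0] = 0
    day_offsets = np.cumsum(gaps)

    dx = _draw_dx_matrix(spec, n_visits, rng)
    risks = _visit_risks(spec, dx)
    triggers = rng.random(n_visits) < risks
    death_day: Optional[int] = None
    if triggers.any():
        t = int(np.argmax(triggers))
        death_day = int(day_offsets[t]) + int(rng.integers(1, MORTALITY_WINDOW_DAYS + 1))
        n_visits = t + 1  # no visits after death
        dx = dx[:n_visits]
        day_offsets = day_offsets[:n_visits]

    settings = np.where(rng.random(n_visits) < 0.45, "inpatient", "outpatient")
    codes = [c.code for c in spec.catalogue]
    visits = [
        Visit(
            patient_id=pid,
            visit_index=vi,
            day_offset=int(day_offsets[vi]),
            setting=str(settings[vi]),
            dx_codes={codes[ci] for ci in np.nonzero(dx[vi])[0]},
            proc_codes=set(),
        )
        for vi in range(n_visits)
    ]

    ihca_codes = sorted(spec.ihca_procedure_codes)
    if ihca_codes and rng.random() < spec.ihca_rate:
        # the sequence-terminating visit is the arrest record
        visits[-1].proc_codes.add(ihca_codes[int(rng.integers(len(ihca_codes)))])
        visits[-1].setting = "inpatient"
        if len(visits) > 1 and rng.random() < spec.extra_ihca_rate:
            vi = int(rng.integers(len(visits) - 1))
            visits[vi].proc_codes.add(ihca_codes[int(rng.integers(len(ihca_codes)))])
            visits[vi].setting = "inpatient"

    sex = "F" if rng.random() < 0.62 else "M"
    age = int(np.clip(round(rng.normal(68.66, 18.96)), 0, 118))
    return Patient(pid, sex, age, visits, death_day)


def sample_cohort(spec: CohortSpec, seed: Optional[int] = None) -> list[Patient]:
    """Generate a full cohort; reproducible given ``(spec, seed)``."""
    spec.validate()
    seed = spec.seed if seed is None else seed
    return [_sample_patient(spec, i, seed) for i in range(spec.n_patients)]


# ---------------------------------------------------------------------------
# labels and subsets
# ---------------------------------------------------------------------------

def label_30day_mortality(patient: Patient, visit: Visit) -> bool:
    """True iff death occurs within [0, 30] days of the visit (inclusive)."""
    if patient.death_day_offset is None:
        return False
    delta = patient.death_day_offset - visit.day_offset
    return 0 <= delta <= MORTALITY_WINDOW_DAYS


def is_ihca_visit(visit: Visit, ihca_codes: Iterable[str] = DEFAULT_IHCA_PROCEDURE_CODES) -> bool:
    return bool(visit.proc_codes & set(ihca_codes))


def build_ihca_subset(
    cohort: Iterable[Patient],
    ihca_codes: Iterable[str] = DEFAULT_IHCA_PROCEDURE_CODES,
) -> list[Patient]:
    """Patients with at least one visit carrying an arrest procedure code."""
    codes = set(ihca_codes)
    return [p for p in cohort if any(v.proc_codes & codes for v in p.visits)]


# ---------------------------------------------------------------------------
# cohort arithmetic (count bookkeeping in the shape of a CONSORT summary)
# ---------------------------------------------------------------------------

def records_after_exclusion(total_records: int, excluded_records: int) -> int:
    """Analyzed record count after removing excluded record classes."""
    if excluded_records > total_records:
        raise DataError("excluded_records exceeds total_records")
    return total_records - excluded_records


def percent(numerator: float, denominator: float) -> float:
    """Share as a percentage; 0 for an empty denominator."""
    return 100.0 * numerator / denominator if denominator else 0.0


def mean_records_per_patient(n_records: int, n_patients: int) -> float:
    return n_records / n_patients if n_patients else 0.0


def cohort_summary(
    cohort: Sequence[Patient],
    ihca_codes: Iterable[str] = DEFAULT_IHCA_PROCEDURE_CODES,
) -> dict[str, float]:
    """CONSORT-style descriptive statistics of a generated cohort."""
    codes = set(ihca_codes)
    n_patients = len(cohort)
    n_records = sum(len(p.visits) for p in cohort)
    n_ihca_records = sum(
        1 for p in cohort for v in p.visits if v.proc_codes & codes
    )
    deaths = [p for p in cohort if p.death_day_offset is not None]
    arrest_counts = [
        sum(1 for v in p.visits if v.proc_codes & codes) for p in cohort
    ]
    with_arrest = [c for c in arrest_counts if c > 0]
    single = sum(1 for c in with_arrest if c == 1)
    first_arrest_deaths = 0
    for p in deaths:
        arrests = [v for v in p.visits if v.proc_codes & codes]
        if arrests and 0 <= p.death_day_offset - arrests[0].day_offset <= MORTALITY_WINDOW_DAYS:
            first_arrest_deaths += 1
    return {
        "n_patients": float(n_patients),
        "n_records": float(n_records),
        "mean_records_per_patient": mean_records_per_patient(n_records, n_patients),
        "mortality_pct": percent(len(deaths), n_patients),
        "ihca_record_pct": percent(n_ihca_records, n_records),
        "single_arrest_pct": percent(single, len(with_arrest)),
        "first_arrest_death_pct": percent(first_arrest_deaths, len(deaths)),
    }


def mention_shares(cohort: Iterable[Patient]) -> dict[str, float]:
    """Observed share of all diagnosis mentions per code, as fractions."""
    counts: dict[str, int] = {}
    total = 0
    for p in cohort:
        for v in p.visits:
            for c in v.dx_codes:
                counts[c] = counts.get(c, 0) + 1
                total += 1
    return {c: n / total for c, n in counts.items()} if total else {}


def expected_mention_shares(catalogue: Sequence[CodeDef]) -> dict[str, float]:
    """Expected per-code share of diagnosis mentions implied by a catalogue.

    Exact under the restriction that boost-source codes are not themselves
    boosted (one-level dependency), which covers the shipped fixtures; raises
    otherwise rather than silently approximating.
    """
    sources = {s for cd in catalogue for s in cd.cooccur}
    for cd in catalogue:
        if cd.code in sources and cd.cooccur:
            raise ConfigError(
                f"field 'cooccur': code {cd.code!r} is both boosted and a boost "
                "source; expected shares are only exact for one-level dependencies"
            )
    base = {cd.code: cd.base_prevalence for cd in catalogue}
    marginal: dict[str, float] = {}
    for cd in catalogue:
        if not cd.cooccur:
            marginal[cd.code] = cd.base_prevalence
            continue
        srcs = sorted(cd.cooccur)
        m = 0.0
        for mask in range(1 << len(srcs)):
            p_mask, prev = 1.0, cd.base_prevalence
            for bit, s in enumerate(srcs):
                if mask >> bit & 1:
                    p_mask *= base[s]
                    prev *= cd.cooccur[s]
                else:
                    p_mask *= 1.0 - base[s]
            m += p_mask * min(1.0, prev)
        marginal[cd.code] = m
    total = sum(marginal.values())
    return {c: v / total for c, v in marginal.items()}


# ---------------------------------------------------------------------------
# cohort I/O: patient-per-line JSONL and flat visit-level CSV
# ---------------------------------------------------------------------------

def _patient_to_dict(p: Patient) -> dict:
    d = asdict(p)
    for v in d["visits"]:
        v["dx_codes"] = sorted(v["dx_codes"])
        v["proc_codes"] = sorted(v["proc_codes"])
    return d


def _patient_from_dict(d: Mapping) -> Patient:
    try:
        visits = [
            Visit(
                patient_id=v["patient_id"],
                visit_index=int(v["visit_index"]),
                day_offset=int(v["day_offset"]),
                setting=v["setting"],
                dx_codes=set(v["dx_codes"]),
                proc_codes=set(v["proc_codes"]),
            )
            for v in d["visits"]
        ]
        return Patient(
            patient_id=d["patient_id"],
            sex=d["sex"],
            age_at_first_visit=int(d["age_at_first_visit"]),
            visits=visits,
            death_day_offset=(
                None if d.get("death_day_offset") is None else int(d["death_day_offset"])
            ),
        )
    except (KeyError, TypeError) as exc:
        raise DataError(f"malformed patient record: {exc}") from exc


def write_cohort_jsonl(cohort: Iterable[Patient], path, header: Mapping | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        for p in cohort:
            fh.write(json.dumps(_patient_to_dict(p), separators=(",", ":")) + "\n")


def read_cohort_jsonl(path) -> list[Patient]:
    cohort = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                cohort.append(_patient_from_dict(json.loads(line)))
            except json.JSONDecodeError as exc:
                raise DataError(f"line {ln}: invalid JSON: {exc}") from exc
    return cohort


def write_visits_csv(cohort: Iterable[Patient], path, header: Mapping | None = None) -> None:
    """Flat visit-level CSV; code sets are pipe-delimited within a cell."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "visit_index", "day_offset", "setting",
             "dx_codes", "proc_codes", "death_day_offset"]
        )
        for p in cohort:
            death = "" if p.death_day_offset is None else p.death_day_offset
            for v in p.visits:
                writer.writerow(
                    [p.patient_id, v.visit_index, v.day_offset, v.setting,
                     "|".join(sorted(v.dx_codes)), "|".join(sorted(v.proc_codes)), death]
                )


def read_visits_csv(path) -> list[Patient]:
    with open(path, encoding="utf-8") as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(io.StringIO("".join(rows)))
    patients: dict[str, Patient] = {}
    for row in reader:
        pid = row["patient_id"]
        if pid not in patients:
            death = row["death_day_offset"]
            patients[pid] = Patient(
                patient_id=pid, sex="", age_at_first_visit=0, visits=[],
                death_day_offset=int(death) if death else None,
            )
        patients[pid].visits.append(
            Visit(
                patient_id=pid,
                visit_index=int(row["visit_index"]),
                day_offset=int(row["day_offset"]),
                setting=row["setting"],
                dx_codes=set(filter(None, row["dx_codes"].split("|"))),
                proc_codes=set(filter(None, row["proc_codes"].split("|"))),
            )
        )
    for p in patients.values():
        p.visits.sort(key=lambda v: v.visit_index)
    return list(patients.values())


# ---------------------------------------------------------------------------
# flat key/value spec files with a `codes:` table section
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = {
    "n_patients": int,
    "visits_mean": float,
    "visits_dispersion": float,
    "inter_visit_days_mean": float,
    "baseline_logodds": float,
    "ihca_rate": float,
    "extra_ihca_rate": float,
    "seed": int,
}


def parse_cohort_config(text: str) -> CohortSpec:
    """Parse a flat key/value cohort spec.

    Scalar section: ``key = value`` lines.  A ``codes:`` line opens the
    catalogue table whose rows are ``code | label | prevalence | logodds |
    boosts`` with boosts written ``SRC:factor,SRC:factor``.  Parse errors
    name the line number and field.
    """
    scalars: dict = {}
    catalogue: list[CodeDef] = []
    in_codes = False
    ihca_codes: Optional[frozenset] = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "codes:":
            in_codes = True
            continue
        if not in_codes:
            if "=" not in line:
                raise ConfigError(f"line {ln}: expected 'key = value', got {line!r}")
            key, _, val = (s.strip() for s in line.partition("="))
            if key == "ihca_procedure_codes":
                ihca_codes = frozenset(filter(None, (s.strip() for s in val.split(","))))
                continue
            if key not in _SCALAR_FIELDS:
                raise ConfigError(f"line {ln}: unknown field {key!r}")
            try:
                scalars[key] = _SCALAR_FIELDS[key](val)
            except ValueError as exc:
                raise ConfigError(f"line {ln}: field {key!r}: {exc}") from exc
        else:
            parts = [s.strip() for s in line.split("|")]
            if len(parts) != 5:
                raise ConfigError(
                    f"line {ln}: codes row needs 5 '|'-separated fields "
                    f"(code | label | prevalence | logodds | boosts), got {len(parts)}"
                )
            code, label, prev_s, lo_s, boosts_s = parts
            try:
                prev = float(prev_s)
            except ValueError as exc:
                raise ConfigError(f"line {ln}: field 'prevalence': {exc}") from exc
            try:
                lo = float(lo_s)
            except ValueError as exc:
                raise ConfigError(f"line {ln}: field 'logodds': {exc}") from exc
            cooccur: dict[str, float] = {}
            if boosts_s:
                for item in boosts_s.split(","):
                    if ":" not in item:
                        raise ConfigError(
                            f"line {ln}: field 'boosts': expected SRC:factor, got {item!r}"
                        )
                    src, _, fac = item.partition(":")
                    try:
                        cooccur[src.strip()] = float(fac)
                    except ValueError as exc:
                        raise ConfigError(f"line {ln}: field 'boosts': {exc}") from exc
            catalogue.append(CodeDef(code, label, prev, lo, cooccur))
    if "n_patients" not in scalars:
        raise ConfigError("field 'n_patients': missing")
    if not catalogue:
        raise ConfigError("field 'codes': catalogue section missing or empty")
    spec = CohortSpec(catalogue=catalogue, **scalars)
    if ihca_codes is not None:
        spec.ihca_procedure_codes = ihca_codes
    spec.validate()
    return spec


def format_cohort_config(spec: CohortSpec) -> str:
    lines = [f"{k} = {getattr(spec, k)}" for k in _SCALAR_FIELDS]
    lines.append("ihca_procedure_codes = " + ",".join(sorted(spec.ihca_procedure_codes)))
    lines.append("codes:")
    for cd in spec.catalogue:
        boosts = ",".join(f"{s}:{f}" for s, f in sorted(cd.cooccur.items()))
        lines.append(
            f"{cd.code} | {cd.label} | {cd.base_prevalence} | {cd.mortality_logodds} | {boosts}"
        )
    return "\n".join(lines) + "\n"
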