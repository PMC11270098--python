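"""Expert-annotation protocol simulation and code-importance statistics.

Validation subset: patients whose arrest record carries a positive 30-day
mortality label and has at least four prior records.  Each such patient
contributes five *current* decision points (the arrest record and its four
predecessors, each judged on its own diagnoses) and four *historical*
decision points (the last four of those records, each judged on its
preceding window).  Two simulated annotators assign an ordinal 1-4 scale
(1 = high likelihood of 30-day mortality, 4 = very low) by thresholding a
noise-perturbed version of the record's true generative risk; disagreements
greater than one point go to a senior adjudicator.

Per-code statistics over a labelled record set:

    count_high  records in the high stratum containing the code (once per record)
    count_low   likewise for the low stratum
    high_ratio  count_high / total high-stratum records
    low_ratio   count_low / total low-stratum records
    importance  high_ratio - low_ratio

The benchmark stratifies by adjudicated scale (1 -> high, 4 -> low, 2-3
contribute nowhere); the model-side tables stratify by the record's impact
basis against inclusive thresholds (>= theta_high high, <= theta_low low).
Tables are ranked by importance descending with ties broken by code string;
ranked tables are compared by top-k overlap and a tie-corrected rank
correlation (Kendall tau-b) over the code union with absent codes ranked
last.
"""

from __future__ import annotations

import csv
import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .code_impact import CodeImpactRow, aggregate_code_impacts, record_basis
from .dshap_core import Attribution, attribution_batch
from .ehr_synth import (
    DEFAULT_IHCA_PROCEDURE_CODES,
    CohortSpec,
    ConfigError,
    Patient,
    is_ihca_visit,
    label_30day_mortality,
    visit_risk,
)
from .risk_model import MLPModel, RecordWindow, windows_from_patient

logger = logging.getLogger("dshap_ehr")

DEFAULT_CUTPOINTS = (0.5, 0.2, 0.05)  # risk thresholds for scales 1/2/3
THETA_HIGH = 0.25
THETA_LOW = 0.10
SCALES = (1, 2, 3, 4)


class EmptyStratumError(ValueError):
    """Both the high and the low stratum are empty; no table can be formed."""


class ScaleError(ValueError):
    pass


@dataclass
class DecisionPoint:
    patient_id: str
    visit_index: int
    mode: str  # "current" | "historical"
    scale_a: Optional[int] = None
    scale_b: Optional[int] = None
    scale_final: Optional[int] = None


@dataclass
class RankComparison:
    top_k_overlap: int
    k: int
    rank_correlation: float
    ranks: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# decision points
# ---------------------------------------------------------------------------

def qualifying_arrest_index(
    patient: Patient,
    ihca_codes: Iterable[str] = DEFAULT_IHCA_PROCEDURE_CODES,
    n_prior: int = 4,
) -> Optional[int]:
    """Index of the first arrest record with a positive 30-day-mortality
    label and >= n_prior preceding records; None if the patient does not
    qualify."""
    for i, v in enumerate(patient.visits):
        if is_ihca_visit(v, ihca_codes) and label_30day_mortality(patient, v):
            return i if i >= n_prior else None
    return None


def build_decision_points(
    patient: Patient,
    ihca_codes: Iterable[str] = DEFAULT_IHCA_PROCEDURE_CODES,
    n_prior: int = 4,
) -> list[DecisionPoint]:
    """Five current and four historical decision points, or none.

    Patients whose qualifying arrest record has fewer than ``n_prior``
    predecessors are excluded (logged), keeping the per-patient point
    counts uniform.
    """
    t = qualifying_arrest_index(patient, ihca_codes, n_prior)
    if t is None:
        has_arrest = any(
            is_ihca_visit(v, ihca_codes) and label_30day_mortality(patient, v)
            for v in patient.visits
        )
        if has_arrest:
            logger.info(
                "patient %s excluded from validation: fewer than %d records "
                "before the qualifying arrest", patient.patient_id, n_prior,
            )
        return []
    pid = patient.patient_id
    points = [
        DecisionPoint(pid, patient.visits[i].visit_index, "current")
        for i in range(t - n_prior, t + 1)
    ]
    points += [
        DecisionPoint(pid, patient.visits[i].visit_index, "historical")
        for i in range(t - n_prior + 1, t + 1)
    ]
    return points


# ---------------------------------------------------------------------------
# simulated annotators and adjudication
# ---------------------------------------------------------------------------

def _bin_risk(risk: float, cutpoints: Sequence[float]) -> int:
    for scale, cut in enumerate(cutpoints, start=1):
        if risk >= cut:
            return scale
    return len(cutpoints) + 1


def _check_cutpoints(cutpoints: Sequence[float]) -> None:
    if any(b >= a for a, b in zip(cutpoints, cutpoints[1:])):
        raise ConfigError(
            f"field 'cutpoints': {tuple(cutpoints)} must be strictly decreasing"
        )


def simulate_annotators(
    point_truth_risk: float,
    noise_scale: float,
    seed: int,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
) -> tuple[int, int]:
    """Two independent ordinal judgments of one decision point.

    Each annotator perturbs the true risk on the log-odds scale with
    logistic noise of the given scale, then bins the perturbed risk at the
    cut-points (an ordered four-category model).  ``noise_scale = 0``
    reproduces deterministic thresholding of the truth.
    """
    if not (0.0 <= point_truth_risk <= 1.0):
        raise ValueError(f"risk {point_truth_risk} not in [0, 1]")
    _check_cutpoints(cutpoints)
    rng = np.random.default_rng(seed)
    r = min(max(point_truth_risk, 1e-12), 1.0 - 1e-12)
    logit = math.log(r / (1.0 - r))
    out = []
    for _ in range(2):
        z = logit + noise_scale * rng.logistic()
        out.append(_bin_risk(1.0 / (1.0 + math.exp(-z)), cutpoints))
    return out[0], out[1]


def adjudicate(
    scale_a: int,
    scale_b: int,
    tiebreak_fn: Callable[[int, int], int],
) -> int:
    """Final scale: the more severe of two near-agreeing judgments (lower
    number = more severe); a gap greater than one point goes to the
    adjudicator."""
    for s in (scale_a, scale_b):
        if s not in SCALES:
            raise ScaleError(f"scale {s!r} outside {SCALES}")
    if abs(scale_a - scale_b) <= 1:
        return min(scale_a, scale_b)
    final = tiebreak_fn(scale_a, scale_b)
    if final not in SCALES:
        raise ScaleError(f"tiebreak returned {final!r}, outside {SCALES}")
    return final


def adjudicate_mean_round(scale_a: int, scale_b: int, tiebreak_fn) -> int:
    """Alternative near-agreement rule: rounded mean instead of severity."""
    for s in (scale_a, scale_b):
        if s not in SCALES:
            raise ScaleError(f"scale {s!r} outside {SCALES}")
    if abs(scale_a - scale_b) <= 1:
        return round((scale_a + scale_b) / 2)
    return tiebreak_fn(scale_a, scale_b)


# ---------------------------------------------------------------------------
# segmentation and importance tables
# ---------------------------------------------------------------------------

def segment_records(
    basis_values: Sequence[float],
    theta_high: float = THETA_HIGH,
    theta_low: float = THETA_LOW,
) -> list[str]:
    """Inclusive thresholding: >= theta_high -> high, <= theta_low -> low."""
    if not theta_low < theta_high:
        raise ConfigError(
            f"field 'theta_low': {theta_low} must be < theta_high ({theta_high})"
        )
    out = []
    for v in basis_values:
        out.append("high" if v >= theta_high else "low" if v <= theta_low else "neither")
    return out


def importance_table(
    records_with_labels: Iterable[tuple[str, Iterable[str]]],
    all_codes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Ranked per-code importance over labelled records.

    ``records_with_labels`` yields ``(label, codes)`` pairs with label in
    {"high", "low", "neither"}; a code counts at most once per record.
    Codes listed in ``all_codes`` but absent from every labelled record get
    zero rows so every catalogue code receives a rank.
    """
    n_high = n_low = 0
    count_high: dict[str, int] = {}
    count_low: dict[str, int] = {}
    universe: set[str] = set(all_codes) if all_codes is not None else set()
    for label, codes in records_with_labels:
        codes = set(codes)
        universe |= codes
        if label == "high":
            n_high += 1
            for c in codes:
                count_high[c] = count_high.get(c, 0) + 1
        elif label == "low":
            n_low += 1
            for c in codes:
                count_low[c] = count_low.get(c, 0) + 1
        elif label != "neither":
            raise ValueError(f"unknown record label {label!r}")
    if n_high == 0 and n_low == 0:
        raise EmptyStratumError(
            "no records fall in either the high or the low stratum"
        )
    rows = []
    for code in sorted(universe):
        ch, cl = count_high.get(code, 0), count_low.get(code, 0)
        hr = ch / n_high if n_high else 0.0
        lr = cl / n_low if n_low else 0.0
        rows.append((code, ch, cl, hr, lr, hr - lr))
    frame = pd.DataFrame(
        rows,
        columns=["diagnosis", "count_high", "count_low",
                 "high_ratio", "low_ratio", "importance"],
    )
    frame = frame.sort_values(
        ["importance", "diagnosis"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame.attrs["n_high"] = n_high
    frame.attrs["n_low"] = n_low
    return frame


def recover_stratum_total(
    ratios_pct: Sequence[float],
    counts: Optional[Sequence[int]] = None,
    n_max: int = 2000,
) -> int:
    """Smallest record total consistent with printed percentage ratios.

    With ``counts`` given, the total must reproduce every printed ratio as
    ``round(100 * count / total, 2)``; without counts, an integer numerator
    must exist for every ratio.  Published two-decimal tables pin the
    stratum denominator this way.
    """
    ratios = [float(r) for r in ratios_pct]
    if counts is not None:
        counts = [int(c) for c in counts]
        if len(counts) != len(ratios):
            raise ValueError("counts and ratios_pct must have equal length")
        start = max(counts + [1])
        for n in range(start, n_max + 1):
            if all(round(100.0 * c / n, 2) == r for c, r in zip(counts, ratios)):
                return n
    else:
        for n in range(1, n_max + 1):
            if all(round(100.0 * round(r * n / 100.0) / n, 2) == r for r in ratios):
                return n
    raise ValueError(f"no stratum total <= {n_max} reproduces the printed ratios")


def compare_rankings(
    benchmark: pd.DataFrame, dshap: pd.DataFrame, k: int = 5
) -> RankComparison:
    """Top-k overlap and tie-corrected rank correlation of two tables."""
    b_rank = dict(zip(benchmark["diagnosis"], benchmark["rank"]))
    d_rank = dict(zip(dshap["diagnosis"], dshap["rank"]))
    union = sorted(set(b_rank) | set(d_rank))
    b_last, d_last = len(b_rank) + 1, len(d_rank) + 1
    rows = [(c, b_rank.get(c, b_last), d_rank.get(c, d_last)) for c in union]
    ranks = pd.DataFrame(rows, columns=["diagnosis", "benchmark_rank", "dshap_rank"])
    top_b = set(benchmark["diagnosis"].iloc[:k])
    top_d = set(dshap["diagnosis"].iloc[:k])
    tau = kendalltau(ranks["benchmark_rank"], ranks["dshap_rank"]).statistic
    return RankComparison(
        top_k_overlap=len(top_b & top_d),
        k=k,
        rank_correlation=float(tau),
        ranks=ranks,
    )


# ---------------------------------------------------------------------------
# end-to-end validation run
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    points: pd.DataFrame
    benchmark_current: pd.DataFrame
    benchmark_historical: pd.DataFrame
    dshap_current: pd.DataFrame
    dshap_historical: pd.DataFrame
    comparison_current: RankComparison
    comparison_historical: RankComparison
    metadata: dict


def _point_seed(master: int, pid: str, visit_index: int, mode: str) -> int:
    return (int(master) + zlib.crc32(f"{pid}|{visit_index}|{mode}".encode())) % (2**31 - 1)


def _window_truth_risk(spec: CohortSpec, window: RecordWindow, mode: str) -> float:
    if mode == "current":
        return visit_risk(spec, window.current)
    risks = [visit_risk(spec, v) for v in window.history]
    surv = 1.0
    for r in risks:
        surv *= 1.0 - r
    return 1.0 - surv


def run_validation(
    cohort: Sequence[Patient],
    cohort_spec: CohortSpec,
    model: MLPModel,
    *,
    theta_high: float = THETA_HIGH,
    theta_low: float = THETA_LOW,
    noise_scale: float = 0.1,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
    basis_mode: str = "max_code_impact",
    adjudication: str = "severity",
    k: int = 5,
    seed: int = 0,
) -> ValidationResult:
    """Annotate, attribute, segment and rank one cohort end to end.

    The benchmark tables stratify decision points by the adjudicated
    annotator scale; the model tables stratify the same points by their
    impact basis.  Current-mode points count the judged visit's diagnosis
    codes, historical-mode points the codes of the up-to-four preceding
    visits (the scope of the historical impact).
    """
    spec = model.spec
    ihca = cohort_spec.ihca_procedure_codes
    all_codes = [c.code for c in cohort_spec.catalogue]
    adjudicate_fn = adjudicate if adjudication == "severity" else adjudicate_mean_round

    by_pid = {p.patient_id: p for p in cohort}
    points: list[DecisionPoint] = []
    windows: list[RecordWindow] = []
    for p in cohort:
        pts = build_decision_points(p, ihca, n_prior=spec.history_window)
        if not pts:
            continue
        wmap = {w.current.visit_index: w for w in windows_from_patient(p, spec)}
        for pt in pts:
            points.append(pt)
            windows.append(wmap[pt.visit_index])
    if not points:
        raise EmptyStratumError("no patient qualifies for the validation subset")

    # annotate
    truths = []
    for pt, w in zip(points, windows):
        risk = _window_truth_risk(cohort_spec, w, pt.mode)
        truths.append(risk)
        a, b = simulate_annotators(
            risk, noise_scale, _point_seed(seed, pt.patient_id, pt.visit_index, pt.mode),
            cutpoints,
        )
        tiebreak = lambda _a, _b, r=risk: _bin_risk(r, cutpoints)
        pt.scale_a, pt.scale_b = a, b
        pt.scale_final = adjudicate_fn(a, b, tiebreak)

    # attribute once per window and derive impacts + basis
    att = attribution_batch(model, windows)
    from .code_impact import code_impacts_frame  # local import to avoid cycle

    impacts = code_impacts_frame(model, windows, att)
    impacts_by_rec: dict[tuple[str, int], list[CodeImpactRow]] = {}
    for row in impacts.itertuples(index=False):
        impacts_by_rec.setdefault((row.patient_id, row.visit_index), []).append(
            CodeImpactRow(row.patient_id, row.visit_index, row.code,
                          row.current_impact, row.historical_impact)
        )

    bench_records = {"current": [], "historical": []}
    dshap_records = {"current": [], "historical": []}
    point_rows = []
    for i, (pt, w) in enumerate(zip(points, windows)):
        codes = (
            set(w.current.dx_codes)
            if pt.mode == "current"
            else set().union(*(v.dx_codes for v in w.history)) if w.history else set()
        )
        bench_label = {1: "high", 4: "low"}.get(pt.scale_final, "neither")
        bench_records[pt.mode].append((bench_label, codes))
        rows = impacts_by_rec.get((pt.patient_id, pt.visit_index), [])
        basis = record_basis(
            rows, float(att["f_x"].iloc[i]), basis_mode,
            which="current" if pt.mode == "current" else "historical",
        )
        dshap_label = segment_records([basis], theta_high, theta_low)[0]
        dshap_records[pt.mode].append((dshap_label, codes))
        point_rows.append(
            (pt.patient_id, pt.visit_index, pt.mode, pt.scale_a, pt.scale_b,
             pt.scale_final, truths[i], basis, bench_label, dshap_label)
        )

    bench_cur = importance_table(bench_records["current"], all_codes)
    bench_his = importance_table(bench_records["historical"], all_codes)
    dshap_cur = importance_table(dshap_records["current"], all_codes)
    dshap_his = importance_table(dshap_records["historical"], all_codes)

    points_frame = pd.DataFrame(
        point_rows,
        columns=["patient_id", "visit_index", "mode", "scale_a", "scale_b",
                 "scale_final", "truth_risk", "basis", "benchmark_label",
                 "dshap_label"],
    )
    n_eligible = len({pt.patient_id for pt in points})
    return ValidationResult(
        points=points_frame,
        benchmark_current=bench_cur,
        benchmark_historical=bench_his,
        dshap_current=dshap_cur,
        dshap_historical=dshap_his,
        comparison_current=compare_rankings(bench_cur, dshap_cur, k),
        comparison_historical=compare_rankings(bench_his, dshap_his, k),
        metadata={
            "n_eligible_patients": n_eligible,
            "n_points": len(points),
            "theta_high": theta_high,
            "theta_low": theta_low,
            "basis_mode": basis_mode,
            "noise_scale": noise_scale,
            "adjudication": adjudication,
            "seed": seed,
            "segmentation_scope": "decision-point record set",
            "rank_correlation": "kendall tau-b over code union, absent ranked last",
        },
    )


# ---------------------------------------------------------------------------
# annotation file I/O
# ---------------------------------------------------------------------------

def write_annotations_csv(points: Iterable[DecisionPoint], path, header=None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "visit_index", "mode", "scale_a", "scale_b", "scale_final"]
        )
        for pt in points:
            writer.writerow(
                [pt.patient_id, pt.visit_index, pt.mode, pt.scale_a, pt.scale_b,
                 pt.scale_final]
            )


def read_annotations_csv(path) -> list[DecisionPoint]:
    out = []
    with open(path, encoding="utf-8") as fh:
        rows = [line for line in fh if not line.startswith("#")]
    import io as _io

    for row in csv.DictReader(_io.StringIO("".join(rows))):
        out.append(
            DecisionPoint(
                patient_id=row["patient_id"],
                visit_index=int(row["visit_index"]),
                mode=row["mode"],
                scale_a=int(row["scale_a"]),
                scale_b=int(row["scale_b"]),
                scale_final=int(row["scale_final"]),
            )
        )
    return out


def write_importance_tsv(frame: pd.DataFrame, path, header=None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"# n_high: {frame.attrs.get('n_high')}\n")
        fh.write(f"# n_low: {frame.attrs.get('n_low')}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_importance_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
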