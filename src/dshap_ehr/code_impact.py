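"""Diagnosis-level aggregation of unit attributions into record impacts.

A record window's attribution vector lives on (H+1) multi-hot blocks; the
*current impact* of a code is its contribution at the current-visit block,
its *historical impact* the (unweighted linear-combination) sum of its
contributions over the H history blocks.  With the zero reference, a code
absent from a slot has x = ref there and hence contributes exactly 0, so
the aggregation partitions the block-wise attribution mass over exactly the
codes present in the window (conservation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dshap_core import Attribution
from .risk_model import MLPModel, ModelSpec, RecordWindow

logger = logging.getLogger("dshap_ehr")

BASIS_MODES = ("max_code_impact", "predicted_probability")


@dataclass
class CodeImpactRow:
    patient_id: str
    visit_index: int
    code: str
    current_impact: float
    historical_impact: float
    record_basis: Optional[float] = None


def aggregate_code_impacts(
    attribution: Attribution, window: RecordWindow, spec: ModelSpec
) -> list[CodeImpactRow]:
    """One row per code present anywhere in the window."""
    phi = np.asarray(attribution.phi)
    V = len(spec.vocabulary)
    if phi.shape != (spec.input_dim,):
        raise ValueError(
            f"attribution length {phi.shape} does not match layout "
            f"({spec.n_blocks} blocks x {V} codes)"
        )
    index = {c: i for i, c in enumerate(spec.vocabulary)}
    slots = [window.current] + list(window.history[: spec.history_window])
    present = sorted({c for v in slots for c in v.dx_codes})
    rows = []
    for code in present:
        ci = index[code]
        cur = float(phi[ci])
        hist = float(sum(phi[b * V + ci] for b in range(1, spec.n_blocks)))
        rows.append(
            CodeImpactRow(
                patient_id=window.patient_id,
                visit_index=window.current.visit_index,
                code=code,
                current_impact=cur,
                historical_impact=hist,
            )
        )
    return rows


def record_basis(
    rows: Sequence[CodeImpactRow],
    prediction: float,
    mode: str = "max_code_impact",
    *,
    which: str = "current",
) -> float:
    """Scalar used to segment the record into high/low impact strata.

    ``max_code_impact`` takes the maximum per-code impact of the requested
    kind (current or historical); ``predicted_probability`` takes the
    model's prediction for the record.
    """
    if mode not in BASIS_MODES:
        raise ValueError(f"mode must be one of {BASIS_MODES}, got {mode!r}")
    if which not in ("current", "historical"):
        raise ValueError(f"which must be 'current' or 'historical', got {which!r}")
    if mode == "predicted_probability":
        return float(prediction)
    if not rows:
        logger.warning("record_basis: empty impact rows; basis falls back to 0")
        return 0.0
    key = (lambda r: r.current_impact) if which == "current" else (
        lambda r: r.historical_impact)
    return float(max(key(r) for r in rows))


def code_impacts_frame(
    model: MLPModel,
    windows: Sequence[RecordWindow],
    attributions: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format impact table for a batch of attributed windows.

    ``attributions`` is the frame produced by
    :func:`dshap_ehr.dshap_core.attribution_batch` for the same windows in
    the same order.
    """
    spec = model.spec
    unit_cols = spec.unit_names()
    phi = attributions[unit_cols].to_numpy()
    records = []
    for i, w in enumerate(windows):
        att = Attribution(
            phi=phi[i],
            f_x=float(attributions["f_x"].iloc[i]),
            f_ref=float(attributions["f_ref"].iloc[i]),
        )
        for r in aggregate_code_impacts(att, w, spec):
            records.append(
                (r.patient_id, r.visit_index, r.code, r.current_impact, r.historical_impact)
            )
    return pd.DataFrame(
        records,
        columns=["patient_id", "visit_index", "code", "current_impact", "historical_impact"],
    )


def write_impacts_csv(frame: pd.DataFrame, path, header: Optional[dict] = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False)


def read_impacts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
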