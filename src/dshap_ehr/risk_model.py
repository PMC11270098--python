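"""Visit-sequence 30-day-mortality predictor with visit-addressable inputs.

The network is a plain feed-forward stack over a fixed input layout of
(H+1) contiguous multi-hot blocks of length |vocabulary|: block 0 encodes
the current visit, blocks 1..H the up-to-H prior visits (most recent
first), with absent history slots left at the all-zeros reference.  Hidden
units are rectifiers only and the output unit is a logistic probability, so
the whole model is piecewise-linear up to the final squash and the
rescale-rule attribution of :mod:`dshap_ehr.dshap_core` applies cleanly.

The first ``len(visit_encoder_dims)`` layers are initialized block-diagonal
with the per-visit encoder weights shared across slots (a hierarchical
visit-then-patient encoding); training is unconstrained dense SGD, so the
tying is an initialization prior rather than a hard constraint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .ehr_synth import Patient, Visit, label_30day_mortality

logger = logging.getLogger("dshap_ehr")

MODEL_FORMAT_VERSION = 1
SUPPORTED_ACTIVATIONS = ("relu", "identity")


class ModelConfigError(ValueError):
    pass


class VocabularyError(KeyError):
    """A window contains a code absent from the model vocabulary."""


class DegenerateDataError(ValueError):
    """Training labels are single-class."""


@dataclass
class ModelSpec:
    vocabulary: list[str]
    history_window: int = 4
    visit_encoder_dims: tuple[int, ...] = (16,)
    head_dims: tuple[int, ...] = (16,)
    activation: str = "relu"
    init_seed: int = 0

    def validate(self) -> None:
        if not self.vocabulary:
            raise ModelConfigError("vocabulary must be non-empty")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ModelConfigError("vocabulary contains duplicate codes")
        if self.history_window < 0:
            raise ModelConfigError("history_window must be >= 0")
        for dims, name in ((self.visit_encoder_dims, "visit_encoder_dims"),
                           (self.head_dims, "head_dims")):
            if any(d < 1 for d in dims):
                raise ModelConfigError(f"{name}: all layer widths must be >= 1")
        if self.activation not in SUPPORTED_ACTIVATIONS:
            raise ModelConfigError(
                f"activation {self.activation!r} unsupported; "
                f"use one of {SUPPORTED_ACTIVATIONS}"
            )

    @property
    def n_blocks(self) -> int:
        return self.history_window + 1

    @property
    def input_dim(self) -> int:
        return self.n_blocks * len(self.vocabulary)

    def unit_names(self) -> list[str]:
        """Column names per input unit: ``h{block}_{code}`` (h0 = current)."""
        return [f"h{b}_{c}" for b in range(self.n_blocks) for c in self.vocabulary]


@dataclass
class RecordWindow:
    """One prediction/attribution unit: a visit plus its recent history."""

    current: Visit
    history: list[Visit]  # most recent first, length <= H
    patient_id: str


@dataclass
class MLPModel:
    """Dense rectifier MLP with a logistic output unit.

    ``weights[i]`` has shape (fan_out, fan_in); hidden layers use
    ``spec.activation``, the final layer is linear and ``predict`` applies
    the logistic squash.
    """

    spec: ModelSpec
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward_trace(np.atleast_2d(x))[-1][:, 0]

    def forward_trace(self, X: np.ndarray) -> list[np.ndarray]:
        """Pre-activations of every linear layer, input included as entry 0."""
        trace = [X]
        a = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W.T + b
            trace.append(z)
            if i < self.n_layers - 1:
                a = np.maximum(z, 0.0) if self.spec.activation == "relu" else z
        return trace


def featurize(window: RecordWindow, spec: ModelSpec) -> np.ndarray:
    """Multi-hot (H+1)-block vector; unknown codes raise VocabularyError."""
    index = {c: i for i, c in enumerate(spec.vocabulary)}
    V = len(spec.vocabulary)
    x = np.zeros(spec.input_dim)
    slots = [window.current] + list(window.history[: spec.history_window])
    for b, visit in enumerate(slots):
        for code in visit.dx_codes:
            if code not in index:
                raise VocabularyError(
                    f"code {code!r} (patient {window.patient_id}, "
                    f"visit {visit.visit_index}) not in model vocabulary"
                )
            x[b * V + index[code]] = 1.0
    return x


def featurize_batch(windows: Sequence[RecordWindow], spec: ModelSpec) -> np.ndarray:
    if not windows:
        return np.zeros((0, spec.input_dim))
    return np.stack([featurize(w, spec) for w in windows])


def windows_from_patient(patient: Patient, spec: ModelSpec) -> list[RecordWindow]:
    """One window per visit, history = up to H prior visits, recent first."""
    out = []
    for i, visit in enumerate(patient.visits):
        hist = list(reversed(patient.visits[max(0, i - spec.history_window): i]))
        out.append(RecordWindow(current=visit, history=hist, patient_id=patient.patient_id))
    return out


def build_model(spec: ModelSpec) -> MLPModel:
    """Seeded He-style initialization; encoder layers start block-diagonal."""
    spec.validate()
    rng = np.random.default_rng(spec.init_seed)
    V, B = len(spec.vocabulary), spec.n_blocks
    weights, biases = [], []

    fan_in_block = V
    for width in spec.visit_encoder_dims:
        Wb = rng.normal(0.0, np.sqrt(2.0 / fan_in_block), size=(width, fan_in_block))
        W = np.zeros((B * width, B * fan_in_block))
        for b in range(B):
            W[b * width:(b + 1) * width, b * fan_in_block:(b + 1) * fan_in_block] = Wb
        weights.append(W)
        biases.append(np.zeros(B * width))
        fan_in_block = width

    fan_in = B * fan_in_block
    for width in list(spec.head_dims) + [1]:
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(width, fan_in)))
        biases.append(np.zeros(width))
        fan_in = width
    return MLPModel(spec=spec, weights=weights, biases=biases)


def predict(model: MLPModel, window: RecordWindow) -> float:
    x = featurize(window, model.spec)
    return float(predict_batch(model, x[None, :])[0])


def predict_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    z = model.forward_trace(X)[-1][:, 0]
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: MLPModel
    auroc: float
    n_train: int
    n_heldout: int


def _records(cohort: Iterable[Patient], spec: ModelSpec):
    windows, labels = [], []
    for p in cohort:
        for w in windows_from_patient(p, spec):
            windows.append(w)
            labels.append(float(label_30day_mortality(p, w.current)))
    return windows, np.array(labels)


def train(
    model: MLPModel,
    cohort: Sequence[Patient],
    *,
    lr: float = 0.1,
    epochs: int = 12,
    batch_size: int = 256,
    momentum: float = 0.9,
    l2: float = 1e-5,
    heldout_fraction: float = 0.2,
    seed: int = 0,
) -> TrainResult:
    """Minibatch SGD on the cross-entropy; patient-level held-out AUROC.

    Deterministic given seeds; no early stopping.  The held-out
    discrimination summary is the rank-statistic area under the ROC curve.
    """
    spec = model.spec
    rng = np.random.default_rng(seed)
    pids = sorted({p.patient_id for p in cohort})
    heldout_ids = set(
        rng.choice(pids, size=int(round(heldout_fraction * len(pids))), replace=False)
    )
    train_pats = [p for p in cohort if p.patient_id not in heldout_ids]
    test_pats = [p for p in cohort if p.patient_id in heldout_ids]

    w_tr, y_tr = _records(train_pats, spec)
    w_te, y_te = _records(test_pats, spec)
    if len(np.unique(y_tr)) < 2:
        raise DegenerateDataError(
            "training labels are single-class; cohort must yield at least one "
            "positive and one negative 30-day-mortality record"
        )
    X_tr = featurize_batch(w_tr, spec)
    X_te = featurize_batch(w_te, spec)

    vel_w = [np.zeros_like(W) for W in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    n = len(y_tr)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Xb, yb = X_tr[idx], y_tr[idx]
            trace = model.forward_trace(Xb)
            p = 1.0 / (1.0 + np.exp(-trace[-1][:, 0]))
            delta = ((p - yb) / len(yb))[:, None]  # dL/dz at the output
            for li in range(model.n_layers - 1, -1, -1):
                a_in = trace[li]
                if li > 0 and spec.activation == "relu":
                    a_in = np.maximum(a_in, 0.0)
                gW = delta.T @ a_in + l2 * model.weights[li]
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ model.weights[li]
                    if spec.activation == "relu":
                        delta = delta * (trace[li] > 0)
                vel_w[li] = momentum * vel_w[li] - lr * gW
                vel_b[li] = momentum * vel_b[li] - lr * gb
                model.weights[li] += vel_w[li]
                model.biases[li] += vel_b[li]

    if len(y_te) and len(np.unique(y_te)) == 2:
        auroc = float(roc_auc_score(y_te, predict_batch(model, X_te)))
    else:
        auroc = float("nan")
        logger.warning("held-out split is single-class; AUROC undefined")
    return TrainResult(model=model, auroc=auroc, n_train=len(y_tr), n_heldout=len(y_te))


# ---------------------------------------------------------------------------
# save / load: versioned single-file JSON parameter archive
# ---------------------------------------------------------------------------

def save_model(model: MLPModel, path) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": {
            "vocabulary": model.spec.vocabulary,
            "history_window": model.spec.history_window,
            "visit_encoder_dims": list(model.spec.visit_encoder_dims),
            "head_dims": list(model.spec.head_dims),
            "activation": model.spec.activation,
            "init_seed": model.spec.init_seed,
        },
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> MLPModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelConfigError(
            f"unsupported model archive version {doc.get('format_version')!r}"
        )
    s = doc["spec"]
    spec = ModelSpec(
        vocabulary=list(s["vocabulary"]),
        history_window=int(s["history_window"]),
        visit_encoder_dims=tuple(s["visit_encoder_dims"]),
        head_dims=tuple(s["head_dims"]),
        activation=s["activation"],
        init_seed=int(s["init_seed"]),
    )
    return MLPModel(
        spec=spec,
        weights=[np.asarray(W, dtype=float) for W in doc["weights"]],
        biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
    )
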