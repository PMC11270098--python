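"""Deep additive attribution by multiplier back-propagation (rescale rule).

Given a model built from linear maps and piecewise-linear (or logistic)
units, each unit's contribution is obtained by back-propagating
*multipliers*: a linear layer contributes its transposed weights, a
nonlinear unit contributes the secant slope

    m = (sigma(z_x) - sigma(z_ref)) / (z_x - z_ref)

between its pre-activation under the input and under the reference (its
derivative on the reference side when the two nearly coincide).  The
per-input contribution is phi_i = m_i (x_i - ref_i).  Because every layer's
output change equals its multipliers applied to its input change exactly,
the completeness identity sum(phi) = f(x) - f(ref) holds to floating-point
precision by construction.

An exact Shapley-value oracle by subset enumeration (n <= 12) is provided
as the independent test surface: the two routes agree exactly on affine
models, and the oracle additionally certifies the dummy and symmetry
axioms.  For general rectifier networks the rescale chain is an
approximation to the exact Shapley value; the test suite measures and
reports the deviation rather than asserting equality.

The default reference is the all-zeros multi-hot vector ("no diagnoses
recorded"), which makes absent codes and empty history slots carry exactly
zero attribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .risk_model import MLPModel, ModelSpec, RecordWindow, featurize_batch

logger = logging.getLogger("dshap_ehr")

COMPLETENESS_TOL = 1e-6
#: below this pre-activation gap the secant is replaced by the derivative
NEAR_EQUAL_EPS = 1e-9
MAX_EXACT_N = 12

_SIGMOID = lambda z: 1.0 / (1.0 + np.exp(-z))

_SUPPORTED = {"relu", "identity", "sigmoid"}


class CapabilityError(ValueError):
    """Requested nonlinearity/layer is outside the supported family."""


class ResourceError(ValueError):
    """Exact enumeration requested for too many players."""


@dataclass
class Attribution:
    """Per-input-unit contributions with the completeness bookkeeping."""

    phi: np.ndarray
    f_x: float
    f_ref: float

    @property
    def residual(self) -> float:
        return self.f_x - self.f_ref - float(self.phi.sum())

    def check_completeness(self, tol: float = COMPLETENESS_TOL) -> None:
        if abs(self.residual) > tol:
            raise AssertionError(
                f"completeness violated: residual {self.residual:.3e} > {tol:.0e}"
            )


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "identity":
        return z
    if name == "sigmoid":
        return _SIGMOID(z)
    raise CapabilityError(f"unsupported nonlinearity {name!r}")


def _deriv_ref_side(name: str, z_ref: np.ndarray) -> np.ndarray:
    # kink convention: derivative on the reference's side, 0 at exactly 0
    if name == "relu":
        return (z_ref > 0).astype(float)
    if name == "identity":
        return np.ones_like(z_ref)
    if name == "sigmoid":
        s = _SIGMOID(z_ref)
        return s * (1.0 - s)
    raise CapabilityError(f"unsupported nonlinearity {name!r}")


def rescale_multiplier(
    unit_nonlinearity: str, pre_x: float, pre_ref: float, eps: float = NEAR_EQUAL_EPS
) -> float:
    """Secant slope of one nonlinear unit between reference and input."""
    if unit_nonlinearity not in _SUPPORTED:
        raise CapabilityError(f"unsupported nonlinearity {unit_nonlinearity!r}")
    return float(
        _rescale(unit_nonlinearity, np.asarray([pre_x], dtype=float),
                 np.asarray([pre_ref], dtype=float), eps)[0]
    )


def _rescale(name: str, z_x: np.ndarray, z_ref: np.ndarray, eps: float = NEAR_EQUAL_EPS) -> np.ndarray:
    dz = z_x - z_ref
    near = np.abs(dz) < eps
    safe = np.where(near, 1.0, dz)
    secant = (_act(name, z_x) - _act(name, z_ref)) / safe
    return np.where(near, _deriv_ref_side(name, z_ref), secant)


def zero_reference(spec: ModelSpec) -> np.ndarray:
    """The all-zeros 'no diagnoses recorded' baseline input."""
    return np.zeros(spec.input_dim)


def deep_shap_batch(
    model: MLPModel, X: np.ndarray, ref: np.ndarray, *, on: str = "probability"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized rescale attribution for a batch of inputs.

    Returns ``(phi, f_x, f_ref)`` where ``phi`` has the shape of ``X``.
    ``on="probability"`` explains the logistic output, ``on="logit"`` the
    pre-squash score.
    """
    if on not in ("probability", "logit"):
        raise CapabilityError(f"unsupported output scale {on!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError(
            f"reference shape {ref.shape} does not match input width {X.shape[1]}"
        )
    act = model.spec.activation
    tr_x = model.forward_trace(X)
    tr_r = model.forward_trace(ref[None, :])

    z_out_x, z_out_r = tr_x[-1][:, 0], tr_r[-1][0, 0]
    if on == "probability":
        f_x, f_ref = _SIGMOID(z_out_x), float(_SIGMOID(z_out_r))
        m = _rescale("sigmoid", z_out_x, np.full_like(z_out_x, z_out_r))[:, None]
    else:
        f_x, f_ref = z_out_x, float(z_out_r)
        m = np.ones((X.shape[0], 1))

    for li in range(model.n_layers - 1, -1, -1):
        m = m @ model.weights[li]
        if li > 0:
            m = m * _rescale(act, tr_x[li], tr_r[li])
    phi = m * (X - ref[None, :])
    return phi, f_x, np.full(X.shape[0], f_ref)


def deep_shap(
    model: MLPModel,
    x: np.ndarray,
    ref: Optional[np.ndarray] = None,
    *,
    on: str = "probability",
) -> Attribution:
    """Rescale-rule attribution of one input against a single reference."""
    if ref is None:
        ref = zero_reference(model.spec)
    phi, f_x, f_ref = deep_shap_batch(model, np.asarray(x)[None, :], ref, on=on)
    return Attribution(phi=phi[0], f_x=float(f_x[0]), f_ref=float(f_ref[0]))


def deep_shap_mean(
    model: MLPModel, x: np.ndarray, refs: np.ndarray, *, on: str = "probability"
) -> Attribution:
    """Average of single-reference attributions over a background set.

    Off by default throughout the pipeline; provided for sensitivity
    analysis against the zero baseline.
    """
    refs = np.atleast_2d(refs)
    parts = [deep_shap(model, x, r, on=on) for r in refs]
    return Attribution(
        phi=np.mean([a.phi for a in parts], axis=0),
        f_x=parts[0].f_x,
        f_ref=float(np.mean([a.f_ref for a in parts])),
    )


# ---------------------------------------------------------------------------
# exact Shapley enumeration oracle
# ---------------------------------------------------------------------------

def exact_shapley(
    black_box_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    ref: np.ndarray,
    n_max: int = MAX_EXACT_N,
) -> Attribution:
    """Exact Shapley values by full subset enumeration.

    ``black_box_fn`` maps a (m, n) batch of inputs to (m,) outputs.  Each
    coalition S evaluates the function at the hybrid input taking ``x`` on S
    and ``ref`` elsewhere.  Completeness holds exactly by construction.
    Cost is 2**n evaluations; refuses n above ``n_max`` (default 12).
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n = x.shape[0]
    if n > n_max:
        raise ResourceError(
            f"exact enumeration over {n} inputs needs 2**{n} evaluations; "
            f"limit is n <= {n_max}"
        )
    subsets = np.arange(2**n)
    masks = (subsets[:, None] >> np.arange(n)) & 1  # (2^n, n)
    hybrids = ref[None, :] + masks * (x - ref)[None, :]
    f = np.asarray(black_box_fn(hybrids), dtype=float)
    if f.shape != (2**n,):
        raise ValueError("black_box_fn must return one output per row")

    sizes = masks.sum(axis=1)
    fact_w = np.array([_shapley_weight(s, n) for s in range(n)])
    phi = np.zeros(n)
    for i in range(n):
        without = (subsets >> i) & 1 == 0
        s_idx = subsets[without]
        gain = f[s_idx | (1 << i)] - f[s_idx]
        phi[i] = float(np.sum(fact_w[sizes[s_idx]] * gain))
    return Attribution(phi=phi, f_x=float(f[-1]), f_ref=float(f[0]))


def _shapley_weight(s: int, n: int) -> float:
    # |S|! (n-|S|-1)! / n!  ==  1 / (n * C(n-1, s))
    return 1.0 / (n * comb(n - 1, s))


def model_as_black_box(model: MLPModel, *, on: str = "probability") -> Callable:
    """Adapter so the enumeration oracle can audit an MLP end to end."""
    if on == "probability":
        return lambda X: _SIGMOID(model.forward_trace(np.atleast_2d(X))[-1][:, 0])
    if on == "logit":
        return lambda X: model.forward_trace(np.atleast_2d(X))[-1][:, 0]
    raise CapabilityError(f"unsupported output scale {on!r}")


# ---------------------------------------------------------------------------
# batch attribution over record windows
# ---------------------------------------------------------------------------

def attribution_batch(
    model: MLPModel,
    windows: Sequence[RecordWindow],
    ref: Optional[np.ndarray] = None,
    *,
    on: str = "probability",
    check: bool = True,
) -> pd.DataFrame:
    """Attribution table keyed by (patient_id, visit_index), input order kept.

    Columns: patient_id, visit_index, f_x, f_ref, then one column per input
    unit named ``h{block}_{code}`` (h0 = current visit).  Raises with the
    record identity attached if a window cannot be featurized.
    """
    spec = model.spec
    if ref is None:
        ref = zero_reference(spec)
    cols = ["patient_id", "visit_index", "f_x", "f_ref"] + spec.unit_names()
    if not windows:
        return pd.DataFrame(columns=cols)
    try:
        X = featurize_batch(windows, spec)
    except Exception as exc:
        raise type(exc)(f"attribution_batch: {exc}") from exc
    phi, f_x, f_ref = deep_shap_batch(model, X, ref, on=on)
    if check:
        resid = np.abs(f_x - f_ref - phi.sum(axis=1))
        worst = int(np.argmax(resid)) if len(resid) else 0
        if len(resid) and resid[worst] > COMPLETENESS_TOL:
            w = windows[worst]
            raise AssertionError(
                f"completeness violated for record ({w.patient_id}, "
                f"{w.current.visit_index}): residual {resid[worst]:.3e}"
            )
    frame = pd.DataFrame(phi, columns=spec.unit_names())
    frame.insert(0, "f_ref", f_ref)
    frame.insert(0, "f_x", f_x)
    frame.insert(0, "visit_index", [w.current.visit_index for w in windows])
    frame.insert(0, "patient_id", [w.patient_id for w in windows])
    return frame


def write_attributions_csv(frame: pd.DataFrame, path, header: Optional[dict] = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False)


def read_attributions_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
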