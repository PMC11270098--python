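import logging

import numpy as np
import pytest

from dshap_ehr import ehr_synth as es
from dshap_ehr import risk_model as rm
from dshap_ehr.cli_io import fixture_spec

# the empty-impact-rows warning is expected on code-free records
logging.getLogger("dshap_ehr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_spec():
    return fixture_spec("tiny_linear", seed=1)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return es.sample_cohort(tiny_spec, 1)


@pytest.fixture
def small_model_spec():
    return rm.ModelSpec(
        vocabulary=["DXA", "DXB", "DXC"],
        history_window=2,
        visit_encoder_dims=(4,),
        head_dims=(4,),
        init_seed=0,
    )


def make_visit(pid="P0", idx=0, day=0, dx=(), proc=()):
    return es.Visit(
        patient_id=pid, visit_index=idx, day_offset=day,
        setting="inpatient", dx_codes=set(dx), proc_codes=set(proc),
    )


def make_patient(pid="P0", visit_dx=((),), death=None, proc_at=None, gap=10):
    """Patient with one visit per entry of visit_dx, `gap` days apart."""
    visits = [
        make_visit(pid, i, i * gap, dx,
                   proc=("99.63",) if proc_at is not None and i == proc_at else ())
        for i, dx in enumerate(visit_dx)
    ]
    return es.Patient(pid, "F", 70, visits, death)


@pytest.fixture
def affine_model():
    """Single-layer model: logit(x) = w . x + b with w = (2, -1, 0), b = 0.5."""
    spec = rm.ModelSpec(
        vocabulary=["A", "B", "C"], history_window=0,
        visit_encoder_dims=(), head_dims=(), activation="identity",
    )
    model = rm.MLPModel(
        spec=spec,
        weights=[np.array([[2.0, -1.0, 0.0]])],
        biases=[np.array([0.5])],
    )
    return model
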