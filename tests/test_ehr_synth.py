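"""Generator semantics: reproducibility, planted prevalences and mortality."""

import math
from dataclasses import replace
from itertools import product

import numpy as np
import pytest

import dshap_ehr.ehr_synth as es
from dshap_ehr.cli_io import fixture_spec, paper_like_spec
from conftest import make_patient, make_visit


def _sigma(z):
    return 1.0 / (1.0 + math.exp(-z))


def one_code_spec(prevalence=1.0, logodds=0.0, **kw):
    return es.CohortSpec(
        n_patients=kw.pop("n_patients", 10),
        catalogue=[es.CodeDef("DX1", "Only code", prevalence, logodds)],
        **kw,
    )


class TestSampling:
    def test_empty_cohort(self):
        assert es.sample_cohort(one_code_spec(n_patients=0), 0) == []

    def test_prevalence_one_forces_code_on_every_visit(self):
        spec = one_code_spec(prevalence=1.0, n_patients=10, baseline_logodds=-30.0)
        cohort = es.sample_cohort(spec, 3)
        assert len(cohort) == 10
        assert all("DX1" in v.dx_codes for p in cohort for v in p.visits)

    def test_byte_identical_reruns(self, tmp_path):
        spec = fixture_spec("tiny_linear", seed=9)
        spec = replace(spec, n_patients=200)
        for name in ("a", "b"):
            es.write_cohort_jsonl(es.sample_cohort(spec, 9), tmp_path / name)
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()

    def test_different_seeds_differ(self):
        spec = one_code_spec(prevalence=0.5, n_patients=50)
        a = es.sample_cohort(spec, 1)
        b = es.sample_cohort(spec, 2)
        assert any(
            pa.visits[0].dx_codes != pb.visits[0].dx_codes for pa, pb in zip(a, b)
        )

    def test_visit_invariants_and_death_truncation(self):
        spec = fixture_spec("uti_confounder", seed=5)
        spec = replace(spec, n_patients=300)
        for p in es.sample_cohort(spec, 5):
            assert p.visits, "included patients must have at least one visit"
            idx = [v.visit_index for v in p.visits]
            assert idx == list(range(len(p.visits)))
            days = [v.day_offset for v in p.visits]
            assert days == sorted(days)
            if p.death_day_offset is not None:
                assert all(v.day_offset <= p.death_day_offset for v in p.visits)

    def test_invalid_parameters_name_the_field(self):
        with pytest.raises(es.ConfigError, match="visits_mean"):
            es.sample_cohort(one_code_spec(visits_mean=-1.0), 0)
        with pytest.raises(es.ConfigError, match="base_prevalence"):
            es.sample_cohort(one_code_spec(prevalence=1.5), 0)
        with pytest.raises(es.ConfigError, match="n_patients"):
            es.CohortSpec(n_patients=-1, catalogue=[]).validate()


class TestMortalityModel:
    def test_null_effect_death_rate_matches_baseline(self):
        # all code effects zero: per-visit death probability is the baseline
        p0 = 0.2
        spec = one_code_spec(
            prevalence=0.5, logodds=0.0, baseline_logodds=math.log(p0 / (1 - p0))
        )
        n = 10_000
        deaths = 0
        for i in range(n):
            pat = make_patient(f"P{i}", visit_dx=[("DX1",)])
            deaths += es.plant_mortality(spec, pat, seed=i) is not None
        se = math.sqrt(p0 * (1 - p0) / n)
        assert abs(deaths / n - p0) < 3 * se

    def test_saturating_effect(self):
        spec = one_code_spec(prevalence=1.0, logodds=10.0, baseline_logodds=-2.0)
        visit = make_visit(dx=("DX1",))
        assert es.visit_risk(spec, visit) > 0.99
        hits = sum(
            es.plant_mortality(spec, make_patient(f"P{i}", visit_dx=[("DX1",)]), i)
            is not None
            for i in range(200)
        )
        assert hits >= 195

    def test_mixed_catalogue_matches_enumeration_oracle(self):
        # closed-form expectation by enumerating the four code configurations
        spec = es.CohortSpec(
            n_patients=0,
            catalogue=[
                es.CodeDef("A", "a", 0.4, 1.5),
                es.CodeDef("B", "b", 0.25, -1.0),
            ],
            baseline_logodds=-1.2,
        )
        expected = 0.0
        for a, b in product((0, 1), repeat=2):
            p_cfg = (0.4 if a else 0.6) * (0.25 if b else 0.75)
            expected += p_cfg * _sigma(-1.2 + 1.5 * a - 1.0 * b)
        n = 10_000
        rng = np.random.default_rng(0)
        deaths = 0
        for i in range(n):
            dx = tuple(
                c for c, keep in zip(("A", "B"), rng.random(2) < (0.4, 0.25)) if keep
            )
            deaths += es.plant_mortality(spec, make_patient(f"P{i}", [dx]), i) is not None
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(deaths / n - expected) < 3 * se

    @pytest.mark.parametrize(
        "death,expected", [(30, True), (31, False), (None, False), (0, True)]
    )
    def test_mortality_label_inclusive_30_day_boundary(self, death, expected):
        pat = make_patient(visit_dx=[()], death=death)
        assert es.label_30day_mortality(pat, pat.visits[0]) is expected

    def test_death_before_visit_does_not_label(self):
        pat = make_patient(visit_dx=[(), ()], death=5, gap=10)
        assert es.label_30day_mortality(pat, pat.visits[1]) is False


class TestIhcaSubset:
    def test_no_arrest_codes_gives_empty_subset(self):
        cohort = [make_patient(f"P{i}", [("DXA",)]) for i in range(5)]
        assert es.build_ihca_subset(cohort) == []

    def test_single_carrier_found(self):
        cohort = [
            make_patient("P0", [(), (), ()]),
            make_patient("P1", [(), (), ()], proc_at=2),
        ]
        subset = es.build_ihca_subset(cohort)
        assert [p.patient_id for p in subset] == ["P1"]

    def test_generator_side_arrest_rate(self):
        spec = replace(
            one_code_spec(prevalence=0.2, n_patients=2000), ihca_rate=0.4
        )
        cohort = es.sample_cohort(spec, 4)
        share = len(es.build_ihca_subset(cohort)) / len(cohort)
        assert abs(share - 0.4) < 3 * math.sqrt(0.4 * 0.6 / 2000)


@pytest.fixture(scope="module")
def paper_cohort():
    return es.sample_cohort(paper_like_spec(n_patients=3000, seed=2), 2)


class TestCalibration:
    def test_diabetes_mention_share(self, paper_cohort):
        total = sum(len(v.dx_codes) for p in paper_cohort for v in p.visits)
        assert total >= 50_000
        share = es.mention_shares(paper_cohort)["DM"]
        assert abs(100 * share - 4.93) < 0.5

    def test_top4_rank_order(self, paper_cohort):
        exp = es.expected_mention_shares(paper_like_spec().catalogue)
        assert exp["DM"] > exp["ARF"] > exp["PNEU"] > exp["UTI"]
        obs = es.mention_shares(paper_cohort)
        assert obs["DM"] > obs["ARF"] > obs["PNEU"] > obs["UTI"]

    def test_pneumonia_share_among_uti_visits(self):
        # conditional co-occurrence planted at 23.36%
        spec = replace(fixture_spec("uti_confounder", seed=7), n_patients=9000)
        cohort = es.sample_cohort(spec, 7)
        n_uti = n_both = 0
        for p in cohort:
            for v in p.visits:
                if "UTI" in v.dx_codes:
                    n_uti += 1
                    n_both += "PNEU" in v.dx_codes
        assert n_uti >= 10_000
        target = 0.2336
        se = math.sqrt(target * (1 - target) / n_uti)
        assert abs(n_both / n_uti - target) < 3 * se

    def test_frequency_consistency_simple_marginal(self):
        spec = one_code_spec(prevalence=0.3, n_patients=2000, baseline_logodds=-30.0)
        cohort = es.sample_cohort(spec, 11)
        visits = [v for p in cohort for v in p.visits]
        freq = sum("DX1" in v.dx_codes for v in visits) / len(visits)
        assert abs(freq - 0.3) < 3 * math.sqrt(0.3 * 0.7 / len(visits))


class TestCohortArithmetic:
    def test_exclusion_difference(self):
        assert es.records_after_exclusion(100, 30) == 70
        with pytest.raises(es.DataError):
            es.records_after_exclusion(10, 30)

    def test_percent_and_mean(self):
        assert es.percent(1, 4) == 25.0
        assert es.percent(1, 0) == 0.0
        assert es.mean_records_per_patient(93, 10) == 9.3

    def test_cohort_summary_on_handmade_cohort(self):
        cohort = [
            make_patient("P0", [(), (), ()], death=25, proc_at=2),
            make_patient("P1", [(), ()]),
        ]
        cohort[1].visits[1].proc_codes.add("99.60")
        s = es.cohort_summary(cohort)
        assert s["n_records"] == 5
        assert s["mortality_pct"] == 50.0
        assert s["ihca_record_pct"] == 40.0
        assert s["single_arrest_pct"] == 100.0
        assert s["first_arrest_death_pct"] == 100.0


class TestIO:
    def test_jsonl_roundtrip(self, tiny_cohort, tmp_path):
        path = tmp_path / "cohort.jsonl"
        es.write_cohort_jsonl(tiny_cohort, path, header={"seed": 1})
        back = es.read_cohort_jsonl(path)
        assert back == tiny_cohort

    def test_visits_csv_roundtrip_preserves_visits(self, tiny_cohort, tmp_path):
        path = tmp_path / "visits.csv"
        es.write_visits_csv(tiny_cohort, path)
        back = {p.patient_id: p for p in es.read_visits_csv(path)}
        for p in tiny_cohort:
            q = back[p.patient_id]
            assert q.death_day_offset == p.death_day_offset
            assert [v.dx_codes for v in q.visits] == [v.dx_codes for v in p.visits]
            assert [v.proc_codes for v in q.visits] == [v.proc_codes for v in p.visits]

    def test_malformed_jsonl_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"patient_id": "P0"\n', encoding="utf-8")
        with pytest.raises(es.DataError, match="line 1"):
            es.read_cohort_jsonl(path)


class TestConfigFormat:
    GOOD = """
n_patients = 5
visits_mean = 2.0
baseline_logodds = -2.0
seed = 3
codes:
DX1 | Pneumonia | 0.3 | 2.0 |
DX2 | Urinary tract infection | 0.2 | 0.0 | DX1:1.5
"""

    def test_roundtrip(self):
        spec = es.parse_cohort_config(self.GOOD)
        assert spec.n_patients == 5
        assert spec.catalogue[1].cooccur == {"DX1": 1.5}
        again = es.parse_cohort_config(es.format_cohort_config(spec))
        assert again == spec

    @pytest.mark.parametrize(
        "text,match",
        [
            ("n_patients = five\ncodes:\nA | a | 0.1 | 0 |", r"line 1.*n_patients"),
            ("n_patients = 5\ncodes:\nA | a | bad | 0 |", r"line 3.*prevalence"),
            ("n_patients = 5\ncodes:\nA | a | 0.1 | x |", r"line 3.*logodds"),
            ("n_patients = 5\ncodes:\nA | a | 0.1 |", r"line 3.*5 '\|'-separated"),
            ("n_patients = 5\nmystery = 2\ncodes:\nA | a | 0.1 | 0 |", r"line 2"),
            ("visits_mean = 2\ncodes:\nA | a | 0.1 | 0 |", r"n_patients"),
            ("n_patients = 5", r"codes"),
        ],
    )
    def test_parse_errors_name_line_and_field(self, text, match):
        with pytest.raises(es.ConfigError, match=match):
            es.parse_cohort_config(text.strip())
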