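"""Domain scoring rules: rule-table anchors, properties, oracle parity."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carecomplexity import (
    AnalysisWindow,
    EDVisit,
    Encounter,
    FlagKind,
    FlagRecord,
    HonosAssessment,
    Phq9Result,
    ProblemEntry,
    VirtualPatientRecord,
    VitalsObservation,
    collapse_encounters,
    hospitalization_complexity_score,
    score_all,
)
from carecomplexity.scoring import (
    score_acute_utilization,
    score_adl,
    score_attachment,
    score_medical_complexity,
    score_psychosocial,
    score_relationships,
    score_risk_of_harm,
    score_service_density,
    score_social_environmental,
)
from conftest import AS_OF, random_vpr
from oracle import naive_scores

D = lambda days: AS_OF - dt.timedelta(days=days)


def vpr(**tables) -> VirtualPatientRecord:
    return VirtualPatientRecord(client_id="X", **tables)


def enc(days, program="p1", booked=False, attended=True):
    return Encounter(client_id="X", date=D(days), program=program,
                     booked=booked, attended=attended)


def honos(days=30, **item_values):
    items = [0] * 12
    for key, val in item_values.items():
        items[int(key.removeprefix("item")) - 1] = val
    return HonosAssessment(client_id="X", date=D(days), items=items)


def flag(kind):
    return FlagRecord(client_id="X", flag_kind=FlagKind(kind))


class TestCollapse:
    def test_six_consecutive_days_collapse_to_one(self):
        dates = [dt.date(2018, 6, 1) + dt.timedelta(days=i) for i in range(6)]
        assert collapse_encounters(dates, 7) == [dt.date(2018, 6, 1)]

    def test_monthly_dates_all_retained(self):
        dates = [dt.date(2018, 6, 1) + dt.timedelta(days=30 * i) for i in range(3)]
        assert collapse_encounters(dates, 7) == dates

    def test_empty(self):
        assert collapse_encounters([], 7) == []

    def test_exactly_seven_days_apart_kept(self):
        dates = [dt.date(2018, 6, 1), dt.date(2018, 6, 8)]
        assert collapse_encounters(dates, 7) == dates


class TestAttachment:
    @pytest.mark.parametrize("n_visits,expected", [(0, 4), (1, 3), (2, 2), (3, 1), (4, 0), (7, 0)])
    def test_dispersed_visit_mapping(self, window, config, n_visits, expected):
        record = vpr(encounters=[enc(30 * (i + 1)) for i in range(n_visits)])
        assert score_attachment(record, window, config) == expected

    def test_burst_collapses_before_mapping(self, window, config):
        record = vpr(encounters=[enc(100 - i) for i in range(6)])
        assert score_attachment(record, window, config) == 3  # one collapsed visit

    def test_no_shows_are_not_visits(self, window, config):
        record = vpr(encounters=[enc(30 * (i + 1), booked=True, attended=False)
                                 for i in range(5)])
        assert score_attachment(record, window, config) == 4


class TestServiceDensity:
    @pytest.mark.parametrize("n_programs,expected", [(1, 0), (2, 1), (3, 2), (4, 3), (5, 4), (6, 4)])
    def test_program_count_mapping(self, window, config, n_programs, expected):
        record = vpr(encounters=[enc(30 * (i + 1), program=f"p{i}") for i in range(n_programs)])
        assert score_service_density(record, window, config) == expected

    def test_nsba_elevation(self, window, config):
        base = [enc(30 * (i + 1), program=f"p{i}") for i in range(3)]
        nsba = [enc(10 + 5 * i, booked=True, attended=False) for i in range(11)]
        assert score_service_density(vpr(encounters=base + nsba), window, config) == 3

    def test_ten_nsba_is_not_enough(self, window, config):
        base = [enc(30 * (i + 1), program=f"p{i}") for i in range(3)]
        nsba = [enc(10 + 5 * i, booked=True, attended=False) for i in range(10)]
        assert score_service_density(vpr(encounters=base + nsba), window, config) == 2


class TestHonosDomains:
    def test_social_environmental_item_max(self, window, config):
        record = vpr(honos=[honos(item11=2, item12=1)])
        assert score_social_environmental(record, window, config) == 2

    def test_social_environmental_pwd_dominates(self, window, config):
        record = vpr(honos=[honos()], flags=[flag("PWD_FORM")])
        assert score_social_environmental(record, window, config) == 4

    @pytest.mark.parametrize(
        "items,expected",
        [
            (dict(item1=0, item4=3, item5=1, item8=2), 3),
            (dict(), 0),
            (dict(item5=4), 4),
        ],
    )
    def test_psychosocial(self, window, config, items, expected):
        assert score_psychosocial(vpr(honos=[honos(**items)]), window, config) == expected

    def test_relationships_shx_dominates(self, window, config):
        assert score_relationships(vpr(flags=[flag("SHX_CODE")]), window, config) == 4
        assert score_relationships(vpr(honos=[honos(item9=1)]), window, config) == 1

    def test_adl_interrai_dominates(self, window, config):
        assert score_adl(vpr(flags=[flag("INTERRAI_MDS")]), window, config) == 4
        assert score_adl(vpr(honos=[honos(item10=2)]), window, config) == 2

    def test_no_data_scores_zero(self, window, config):
        empty = vpr()
        for scorer in (score_social_environmental, score_psychosocial,
                       score_relationships, score_adl, score_risk_of_harm):
            assert scorer(empty, window, config) == 0


class TestMedicalComplexity:
    def test_empty_problem_list(self, window, config):
        assert score_medical_complexity(vpr(), window, config) == 0

    def test_single_sumh_not_on_leave(self, window, config):
        record = vpr(problems=[ProblemEntry(client_id="X", code="F32")])
        assert score_medical_complexity(record, window, config) == 2

    def test_sumh_on_extended_leave_maximal(self, window, config):
        record = vpr(
            problems=[ProblemEntry(client_id="X", code="F32")],
            flags=[flag("EXTENDED_LEAVE")],
        )
        assert score_medical_complexity(record, window, config) == 4

    def test_two_dx_with_sumh_tier_three(self, window, config):
        record = vpr(problems=[ProblemEntry(client_id="X", code="F32"),
                               ProblemEntry(client_id="X", code="I10")])
        assert score_medical_complexity(record, window, config) == 3

    def test_four_plain_dx_tier_one(self, window, config):
        codes = ["I10", "M54", "K21", "H52"]
        record = vpr(problems=[ProblemEntry(client_id="X", code=c) for c in codes])
        assert score_medical_complexity(record, window, config) == 1

    def test_six_dx_with_modifiers_clamps_at_four(self, window, config):
        codes = ["I10", "M54", "K21", "H52", "R51", "M17"]
        record = vpr(
            problems=[ProblemEntry(client_id="X", code=c) for c in codes],
            vitals=[VitalsObservation(client_id="X", date=D(10),
                                      systolic_bp=150.0, diastolic_bp=80.0, bmi=32.0)],
        )
        assert score_medical_complexity(record, window, config) == 4

    def test_bmi_increment_highest_only(self, window, config):
        record = vpr(
            problems=[ProblemEntry(client_id="X", code="I10"),
                      ProblemEntry(client_id="X", code="M54")],
            vitals=[VitalsObservation(client_id="X", date=D(5), bmi=36.0)],
        )
        # base 0 (two plain dx), +0.75 for BMI > 35 only
        assert score_medical_complexity(record, window, config) == 0.75

    def test_honos_item_four_forces_tier_four(self, window, config):
        record = vpr(honos=[honos(item7=4)])
        assert score_medical_complexity(record, window, config) == 4

    def test_complex_care_code_tier_four(self, window, config):
        record = vpr(problems=[ProblemEntry(client_id="X", code="E11")])
        assert score_medical_complexity(record, window, config) == 4


class TestAcuteUtilization:
    def test_hcs_examples(self, window, config):
        assert hospitalization_complexity_score(vpr(), window, config) == 0
        one_ed = vpr(ed_visits=[EDVisit(client_id="X", date=D(10), ctas_level=2)])
        assert hospitalization_complexity_score(one_ed, window, config) == 4
        from carecomplexity import AcuteAdmission

        mixed = vpr(
            ed_visits=[EDVisit(client_id="X", date=D(10), ctas_level=5),
                       EDVisit(client_id="X", date=D(20), ctas_level=5)],
            admissions=[AcuteAdmission(client_id="X", admit_date=D(40),
                                       discharge_date=D(30))],
        )
        assert hospitalization_complexity_score(mixed, window, config) == 12

    @pytest.mark.parametrize(
        "n_ctas1,expected_q8",
        # hcs = 5 per CTAS-1 visit: 0->0, 5->1, 15->2, 25->3, 55->4
        [(0, 0), (1, 1), (3, 2), (5, 3), (11, 4)],
    )
    def test_bins_with_higher_score_precedence(self, window, config, n_ctas1, expected_q8):
        visits = [EDVisit(client_id="X", date=D(5 + i), ctas_level=1) for i in range(n_ctas1)]
        assert score_acute_utilization(vpr(ed_visits=visits), window, config) == expected_q8

    def test_bin_edges(self, window, config):
        """hcs 50 sits in the 3-band; anything above falls in the 4-band."""
        visits_50 = [EDVisit(client_id="X", date=D(5 + i), ctas_level=1) for i in range(10)]
        assert score_acute_utilization(vpr(ed_visits=visits_50), window, config) == 3
        visits_51 = visits_50 + [EDVisit(client_id="X", date=D(50), ctas_level=5)]
        assert score_acute_utilization(vpr(ed_visits=visits_51), window, config) == 4


class TestRiskOfHarm:
    def test_honos_mapping(self, window, config):
        assert score_risk_of_harm(vpr(honos=[honos(item1=2, item2=1)]), window, config) == 2

    def test_violence_alert_dominates(self, window, config):
        assert score_risk_of_harm(vpr(flags=[flag("VIOLENCE_ALERT")]), window, config) == 4

    def test_phq9_above_threshold(self, window, config):
        record = vpr(honos=[honos()], phq9=[Phq9Result(client_id="X", date=D(5), total=10)])
        assert score_risk_of_harm(record, window, config) == 4

    def test_phq9_at_threshold_does_not_trigger(self, window, config):
        record = vpr(honos=[honos(item1=1)],
                     phq9=[Phq9Result(client_id="X", date=D(5), total=9)])
        assert score_risk_of_harm(record, window, config) == 1


class TestScoreAll:
    def test_empty_vpr(self, window):
        vec = score_all(vpr(), window)
        assert vec.as_tuple() == (4.0, 0, 0, 0, 0, 0, 0, 0, 0)
        assert vec.completeness[0] is True  # no visits is itself evidence
        assert not any(vec.completeness[1:])

    def test_matches_individual_scorers(self, window, config):
        from carecomplexity import window_filter

        rng = np.random.default_rng(42)
        scorers = (
            score_attachment, score_service_density, score_social_environmental,
            score_psychosocial, score_relationships, score_adl,
            score_medical_complexity, score_acute_utilization, score_risk_of_harm,
        )
        for _ in range(25):
            record = random_vpr(rng)
            vec = score_all(record, window, config)
            windowed = window_filter(record, window)
            individual = tuple(s(windowed, window, config) for s in scorers)
            assert vec.as_tuple() == individual

    def test_fixture_anchors(self, window, fixtures_by_id):
        expected = {
            "no_visits": dict(q1=4),
            "five_dispersed": dict(q1=0),
            "one_burst_week": dict(q1=3),
            "five_programs": dict(q2=4),
            "three_prog_nsba": dict(q2=3),
            "empty_problem_list": dict(q7=0),
            "sumh_only": dict(q7=2),
            "phq9_ten": dict(q9=4),
        }
        for cid, checks in expected.items():
            vec = score_all(fixtures_by_id[cid], window)
            for field, value in checks.items():
                assert getattr(vec, field) == value, (cid, field)

    def test_max_triggers_fixture_hits_every_attainable_maximum(self, window, fixtures_by_id):
        vec = score_all(fixtures_by_id["max_triggers"], window)
        assert vec.as_tuple()[1:] == (4.0,) * 8
        assert vec.q1 == 0  # the visits that max Q2 are themselves attachment


class TestProperties:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=150, deadline=None)
    def test_bounds_and_completeness_invariant(self, seed):
        """Every q lies in [0,4]; an incomplete domain scores 0."""
        window = AnalysisWindow(as_of_date=AS_OF)
        vec = score_all(random_vpr(np.random.default_rng(seed)), window)
        for q, complete in zip(vec.as_tuple(), vec.completeness):
            assert 0.0 <= q <= 4.0
            if not complete:
                assert q == 0.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence_random(self, seed):
        window = AnalysisWindow(as_of_date=AS_OF)
        record = random_vpr(np.random.default_rng(seed))
        vec = score_all(record, window)
        assert list(vec.as_tuple()) == naive_scores(record, AS_OF)

    def test_flag_dominance(self, window, config):
        """Each score=4 presence trigger forces exactly 4 regardless of
        the rest of the record."""
        rng = np.random.default_rng(7)
        cases = {
            "PWD_FORM": (score_social_environmental,),
            "SHX_CODE": (score_social_environmental, score_relationships),
            "INTERRAI_MDS": (score_adl,),
            "MOBILITY_ASSESSMENT": (score_adl,),
            "VIOLENCE_ALERT": (score_risk_of_harm,),
            "EXTENDED_LEAVE": (score_risk_of_harm,),
        }
        from carecomplexity import window_filter

        for kind, scorers in cases.items():
            for _ in range(10):
                record = random_vpr(rng)
                record = record.model_copy(
                    update={"flags": record.flags + [flag(kind)]}
                )
                windowed = window_filter(record, window)
                for scorer in scorers:
                    assert scorer(windowed, window, config) == 4

    def test_q1_monotone_in_visits(self, window, config):
        prev = 5.0
        for n in range(8):
            record = vpr(encounters=[enc(30 * (i + 1)) for i in range(n)])
            q1 = score_attachment(record, window, config)
            assert q1 <= prev
            prev = q1

    def test_hcs_monotone_in_utilization(self, window, config):
        base = vpr(ed_visits=[EDVisit(client_id="X", date=D(10), ctas_level=3)])
        more = vpr(ed_visits=base.ed_visits + [EDVisit(client_id="X", date=D(20), ctas_level=3)])
        assert hospitalization_complexity_score(more, window, config) > \
            hospitalization_complexity_score(base, window, config)
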