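import datetime as dt

import numpy as np
import pytest

from carecomplexity import (
    AnalysisWindow,
    Bundle,
    ScoringConfig,
    VirtualPatientRecord,
    link_records,
    make_worked_fixtures,
)

AS_OF = dt.date(2019, 1, 1)


@pytest.fixture(scope="session")
def window() -> AnalysisWindow:
    return AnalysisWindow(as_of_date=AS_OF)


@pytest.fixture(scope="session")
def config() -> ScoringConfig:
    return ScoringConfig()


@pytest.fixture(scope="session")
def fixtures_bundle() -> Bundle:
    return make_worked_fixtures(AS_OF)


@pytest.fixture(scope="session")
def fixtures_by_id(fixtures_bundle) -> dict[str, VirtualPatientRecord]:
    return {vpr.client_id: vpr for vpr in link_records(fixtures_bundle)}


def random_vpr(rng: np.random.Generator, as_of: dt.date = AS_OF) -> VirtualPatientRecord:
    """A randomized VPR stressing every rule branch, including records
    outside the analysis window, date ties and open admissions."""
    def day(lo=-700, hi=0):
        return as_of + dt.timedelta(days=int(rng.integers(lo, hi + 1)))

    programs = ["p1", "p2", "p3", "p4", "p5", "p6"]
    encounters = [
        dict(
            client_id="X",
            date=day(),
            program=str(rng.choice(programs)),
            booked=bool(rng.random() < 0.6),
            attended=bool(rng.random() < 0.7),
        )
        for _ in range(int(rng.integers(0, 25)))
    ]
    honos = [
        dict(client_id="X", date=day(), items=[int(x) for x in rng.integers(0, 5, size=12)])
        for _ in range(int(rng.integers(0, 4)))
    ]
    codes = ["F32", "F20", "E11", "G30", "I10", "M54", "K21", "E78", "J30", "N39", "ZZZ"]
    problems = [
        dict(
            client_id="X",
            code=str(rng.choice(codes)),
            is_sumh=bool(rng.random() < 0.1),
            is_complex_care=bool(rng.random() < 0.05),
            is_neurodegenerative=bool(rng.random() < 0.05),
        )
        for _ in range(int(rng.integers(0, 9)))
    ]
    vitals = [
        dict(
            client_id="X",
            date=day(),
            systolic_bp=float(rng.uniform(90, 190)) if rng.random() < 0.9 else None,
            diastolic_bp=float(rng.uniform(55, 115)) if rng.random() < 0.9 else None,
            bmi=float(rng.uniform(16, 45)) if rng.random() < 0.9 else None,
        )
        for _ in range(int(rng.integers(0, 4)))
    ]
    ed_visits = [
        dict(client_id="X", date=day(), ctas_level=int(rng.integers(1, 6)))
        for _ in range(int(rng.integers(0, 8)))
    ]
    admissions = []
    for _ in range(int(rng.integers(0, 4))):
        admit = day(-800, -1)
        if rng.random() < 0.2:
            discharge = None  # still admitted
        else:
            discharge = admit + dt.timedelta(days=int(rng.integers(0, 60)))
        admissions.append(dict(client_id="X", admit_date=admit, discharge_date=discharge))
    kinds = ["PWD_FORM", "SHX_CODE", "INTERRAI_MDS", "MOBILITY_ASSESSMENT",
             "VIOLENCE_ALERT", "EXTENDED_LEAVE"]
    flags = [
        dict(client_id="X", flag_kind=k, date=day() if rng.random() < 0.5 else None)
        for k in kinds
        if rng.random() < 0.15
    ]
    phq9 = [
        dict(client_id="X", date=day(), total=int(rng.integers(0, 28)))
        for _ in range(int(rng.integers(0, 3)))
    ]
    return VirtualPatientRecord.model_validate(
        dict(
            client_id="X",
            encounters=encounters,
            honos=honos,
            problems=problems,
            vitals=vitals,
            ed_visits=ed_visits,
            admissions=admissions,
            flags=flags,
            phq9=phq9,
        )
    )
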