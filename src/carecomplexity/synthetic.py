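"""Synthetic multi-source cohort generation.

No client-level clinical data are published for this kind of community
health-center population, so the package ships a generator that
emulates the *structure* the scorer consumes: encounters with bookings
and no-shows across several programs, HoNOS assessments, problem
lists, vitals, ED visits with triage levels, acute admissions, status
flags and PHQ-9 totals.  Cohorts are mixtures of archetypes —
parameter sets sketching recognizable sub-populations:

* ``low`` — youth-clinic / specialty-program users: regularly attached,
  single program, minimal psychosocial burden.
* ``high`` — the highly complex mandate population: multi-program
  involvement, frequent no-shows, elevated HoNOS, substance-use/mental
  -health diagnoses, housing instability, acute utilization.
* ``frail_senior`` — ADL-heavy profile: standardized ADL assessments,
  long admissions, large problem lists, modest mental-health burden.

Every client draws from an independent random stream seeded by
``(cohort seed, client index)``, so bundles are bit-reproducible and
stable under changes to ``n``.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .records import Bundle, FlagKind, TABLES

__all__ = [
    "Archetype",
    "CohortSpec",
    "BUILTIN_ARCHETYPES",
    "assign_archetypes",
    "generate_cohort",
    "make_worked_fixtures",
]

_WINDOW_DAYS = 540  # generation span: comfortably inside an 18-month lookback


def _dist(probs: list[float]) -> list[float]:
    s = sum(probs)
    return [p / s for p in probs]


class Archetype(BaseModel):
    """Generation parameters for one synthetic sub-population.

    Rates are per month over the 18-month generation span unless named
    otherwise; categorical distributions are probability vectors.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    encounters_per_month: float = Field(ge=0)
    nsba_per_month: float = Field(ge=0)
    program_pool: list[str]
    program_count_probs: list[float]  # P(client uses k programs), k = 1..len
    p_honos: float = Field(ge=0, le=1)
    honos_item_probs: list[list[float]]  # 12 rows of P(item = 0..4)
    problem_count_probs: list[float]  # P(n diagnoses = 0, 1, 2, ...)
    p_sumh: float = Field(ge=0, le=1)  # P(problem list includes a SU/MH code)
    p_complex_care: float = Field(ge=0, le=1)
    p_neurodegenerative: float = Field(ge=0, le=1)
    p_vitals: float = Field(ge=0, le=1)
    bmi_mean: float = 24.0
    bmi_sd: float = 3.0
    sbp_mean: float = 120.0
    sbp_sd: float = 12.0
    dbp_mean: float = 76.0
    dbp_sd: float = 8.0
    ed_visits_mean: float = Field(ge=0)  # Poisson mean over the span
    ctas_probs: list[float] = Field(default_factory=lambda: [0.02, 0.08, 0.3, 0.4, 0.2])
    admissions_mean: float = Field(ge=0)
    los_mean_days: float = Field(ge=0)
    flag_probs: dict[str, float] = Field(default_factory=dict)
    p_phq9: float = Field(ge=0, le=1)
    phq9_mean: float = 6.0
    phq9_sd: float = 4.0

    @model_validator(mode="after")
    def _valid(self) -> "Archetype":
        if len(self.honos_item_probs) != 12:
            raise ValueError("honos_item_probs must have 12 rows")
        for row in self.honos_item_probs:
            if len(row) != 5 or any(p < 0 for p in row):
                raise ValueError("each HoNOS item distribution needs 5 non-negative weights")
        if len(self.program_count_probs) > len(self.program_pool):
            raise ValueError("program_count_probs longer than program pool")
        for key in self.flag_probs:
            FlagKind(key)  # raises on unknown flag kinds
        return self


def _honos_rows(base: list[float], overrides: Optional[dict[int, list[float]]] = None):
    rows = [list(base) for _ in range(12)]
    for item, row in (overrides or {}).items():
        rows[item - 1] = list(row)
    return [_dist(r) for r in rows]


BUILTIN_ARCHETYPES: dict[str, Archetype] = {
    "low": Archetype(
        name="low",
        encounters_per_month=0.35,
        nsba_per_month=0.05,
        program_pool=["youth_clinic", "sexual_health", "hep_c"],
        program_count_probs=_dist([0.8, 0.2]),
        p_honos=0.25,
        honos_item_probs=_honos_rows([0.7, 0.2, 0.08, 0.02, 0.0]),
        problem_count_probs=_dist([0.45, 0.3, 0.15, 0.1]),
        p_sumh=0.08,
        p_complex_care=0.01,
        p_neurodegenerative=0.0,
        p_vitals=0.6,
        bmi_mean=23.0,
        ed_visits_mean=0.2,
        ctas_probs=_dist([0.0, 0.03, 0.17, 0.45, 0.35]),
        admissions_mean=0.03,
        los_mean_days=2.0,
        flag_probs={"PWD_FORM": 0.01, "SHX_CODE": 0.03, "VIOLENCE_ALERT": 0.005},
        p_phq9=0.3,
        phq9_mean=4.0,
        phq9_sd=3.0,
    ),
    "high": Archetype(
        name="high",
        encounters_per_month=1.2,
        nsba_per_month=0.8,
        program_pool=["primary_care", "mhsu", "oat", "outreach", "social_work", "housing"],
        program_count_probs=_dist([0.05, 0.1, 0.2, 0.3, 0.25, 0.1]),
        p_honos=0.9,
        honos_item_probs=_honos_rows(
            [0.1, 0.2, 0.3, 0.25, 0.15],
            overrides={11: [0.15, 0.2, 0.25, 0.25, 0.15], 3: [0.05, 0.1, 0.25, 0.35, 0.25]},
        ),
        problem_count_probs=_dist([0.02, 0.05, 0.1, 0.15, 0.2, 0.2, 0.15, 0.08, 0.05]),
        p_sumh=0.85,
        p_complex_care=0.3,
        p_neurodegenerative=0.02,
        p_vitals=0.8,
        bmi_mean=27.0,
        bmi_sd=5.0,
        sbp_mean=132.0,
        sbp_sd=16.0,
        dbp_mean=84.0,
        dbp_sd=10.0,
        ed_visits_mean=4.0,
        ctas_probs=_dist([0.05, 0.15, 0.35, 0.3, 0.15]),
        admissions_mean=0.8,
        los_mean_days=8.0,
        flag_probs={
            "PWD_FORM": 0.35,
            "SHX_CODE": 0.45,
            "VIOLENCE_ALERT": 0.15,
            "EXTENDED_LEAVE": 0.1,
            "INTERRAI_MDS": 0.05,
        },
        p_phq9=0.6,
        phq9_mean=13.0,
        phq9_sd=6.0,
    ),
    "frail_senior": Archetype(
        name="frail_senior",
        encounters_per_month=0.7,
        nsba_per_month=0.15,
        program_pool=["primary_care", "home_health", "geriatrics"],
        program_count_probs=_dist([0.3, 0.5, 0.2]),
        p_honos=0.7,
        honos_item_probs=_honos_rows(
            [0.35, 0.3, 0.2, 0.1, 0.05],
            overrides={5: [0.1, 0.2, 0.3, 0.25, 0.15], 10: [0.1, 0.2, 0.3, 0.25, 0.15]},
        ),
        problem_count_probs=_dist([0.02, 0.05, 0.1, 0.18, 0.25, 0.2, 0.12, 0.08]),
        p_sumh=0.15,
        p_complex_care=0.45,
        p_neurodegenerative=0.25,
        p_vitals=0.95,
        bmi_mean=26.0,
        bmi_sd=4.5,
        sbp_mean=138.0,
        sbp_sd=15.0,
        dbp_mean=82.0,
        dbp_sd=9.0,
        ed_visits_mean=1.5,
        ctas_probs=_dist([0.05, 0.2, 0.4, 0.25, 0.1]),
        admissions_mean=1.2,
        los_mean_days=12.0,
        flag_probs={"INTERRAI_MDS": 0.55, "MOBILITY_ASSESSMENT": 0.4, "PWD_FORM": 0.1},
        p_phq9=0.4,
        phq9_mean=7.0,
        phq9_sd=4.0,
    ),
}


class CohortSpec(BaseModel):
    """Synthetic population specification: size, archetype mixture, seed."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(gt=0)
    mixture: dict[str, float]
    seed: int = 0
    as_of_date: dt.date = dt.date(2019, 1, 1)
    archetypes: Optional[dict[str, Archetype]] = None  # defaults to the built-ins

    @model_validator(mode="after")
    def _valid_mixture(self) -> "CohortSpec":
        pool = self.archetypes if self.archetypes is not None else BUILTIN_ARCHETYPES
        unknown = set(self.mixture) - set(pool)
        if unknown:
            raise ValueError(f"unknown archetypes in mixture: {sorted(unknown)}")
        if any(p < 0 for p in self.mixture.values()):
            raise ValueError("mixture proportions must be non-negative")
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        return self

    def archetype_pool(self) -> dict[str, Archetype]:
        return self.archetypes if self.archetypes is not None else BUILTIN_ARCHETYPES


def _rand_day(rng: np.random.Generator, as_of: dt.date) -> dt.date:
    return as_of - dt.timedelta(days=int(rng.integers(0, _WINDOW_DAYS)))


# codes chosen from the shipped placeholder lists so that code-list based
# category resolution fires on generated data
_SUMH_CODE = "F32"
_CC_CODE = "E11"
_NEURO_CODE = "G30"
_PLAIN_CODES = ["I10", "M54", "K21", "L20", "H52", "R51", "M17", "E78", "J30", "N39"]

_Tables = dict[str, list[dict]]


def _generate_client(
    cid: str, arch: Archetype, rng: np.random.Generator, as_of: dt.date, tables: _Tables
) -> int:
    """Append one client's records; returns the number of records added."""
    span_months = _WINDOW_DAYS / 30.0
    added = 0

    k = int(rng.choice(len(arch.program_count_probs), p=arch.program_count_probs)) + 1
    programs = [str(p) for p in rng.choice(arch.program_pool, size=k, replace=False)]

    for _ in range(int(rng.poisson(arch.encounters_per_month * span_months))):
        tables["encounters"].append(
            dict(
                client_id=cid,
                date=_rand_day(rng, as_of),
                source_system="primary_care_emr",
                program=str(rng.choice(programs)),
                booked=bool(rng.random() < 0.7),
                attended=True,
            )
        )
        added += 1
    for _ in range(int(rng.poisson(arch.nsba_per_month * span_months))):
        tables["encounters"].append(
            dict(
                client_id=cid,
                date=_rand_day(rng, as_of),
                source_system="primary_care_emr",
                program=str(rng.choice(programs)),
                booked=True,
                attended=False,
            )
        )
        added += 1

    if rng.random() < arch.p_honos:
        for _ in range(int(rng.integers(1, 3))):
            items = [int(rng.choice(5, p=row)) for row in arch.honos_item_probs]
            tables["honos"].append(dict(client_id=cid, date=_rand_day(rng, as_of), items=items))
            added += 1

    n_dx = int(rng.choice(len(arch.problem_count_probs), p=arch.problem_count_probs))
    codes: list[str] = []
    if n_dx:
        if rng.random() < arch.p_sumh:
            codes.append(_SUMH_CODE)
        if rng.random() < arch.p_complex_care:
            codes.append(_CC_CODE)
        if rng.random() < arch.p_neurodegenerative:
            codes.append(_NEURO_CODE)
        codes = codes[:n_dx]
        filler = [c for c in _PLAIN_CODES if c not in codes]
        codes.extend(filler[: n_dx - len(codes)])
    for code in codes:
        tables["problems"].append(dict(client_id=cid, code=code, label=f"dx {code}"))
        added += 1

    if rng.random() < arch.p_vitals:
        tables["vitals"].append(
            dict(
                client_id=cid,
                date=_rand_day(rng, as_of),
                systolic_bp=round(max(80.0, rng.normal(arch.sbp_mean, arch.sbp_sd)), 1),
                diastolic_bp=round(max(50.0, rng.normal(arch.dbp_mean, arch.dbp_sd)), 1),
                bmi=round(max(14.0, rng.normal(arch.bmi_mean, arch.bmi_sd)), 1),
            )
        )
        added += 1

    for _ in range(int(rng.poisson(arch.ed_visits_mean))):
        ctas = int(rng.choice(5, p=_dist(arch.ctas_probs))) + 1
        tables["ed_visits"].append(dict(client_id=cid, date=_rand_day(rng, as_of), ctas_level=ctas))
        added += 1

    for _ in range(int(rng.poisson(arch.admissions_mean))):
        admit = _rand_day(rng, as_of)
        los = int(rng.exponential(arch.los_mean_days)) + 1
        tables["admissions"].append(
            dict(
                client_id=cid,
                admit_date=admit,
                discharge_date=min(admit + dt.timedelta(days=los), as_of),
            )
        )
        added += 1

    for kind, prob in arch.flag_probs.items():
        if rng.random() < prob:
            tables["flags"].append(dict(client_id=cid, flag_kind=kind, date=_rand_day(rng, as_of)))
            added += 1

    if rng.random() < arch.p_phq9:
        total = int(np.clip(round(rng.normal(arch.phq9_mean, arch.phq9_sd)), 0, 27))
        tables["phq9"].append(dict(client_id=cid, date=_rand_day(rng, as_of), total=total))
        added += 1

    return added


def assign_archetypes(spec: CohortSpec) -> list[str]:
    """Archetype assignment per client (deterministic given the spec).

    Uses the first draw of each client's private stream, so assignments
    are stable when ``n`` changes.
    """
    names = sorted(spec.mixture)
    cum = np.cumsum([spec.mixture[name] for name in names])
    out = []
    for i in range(spec.n):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        idx = int(np.searchsorted(cum, rng.random(), side="right"))
        out.append(names[min(idx, len(names) - 1)])
    return out


def generate_cohort(spec: CohortSpec) -> Bundle:
    """Generate a schema-valid multi-source bundle of ``spec.n`` clients."""
    pool = spec.archetype_pool()
    assignments = assign_archetypes(spec)
    tables: _Tables = {name: [] for name in TABLES}
    for i, arch_name in enumerate(assignments):
        cid = f"C{i:05d}"
        # fresh stream whose first draw is the assignment draw, consumed here
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        rng.random()
        added = _generate_client(cid, pool[arch_name], rng, spec.as_of_date, tables)
        if added == 0:
            # keep the client linkable without touching any in-window rule:
            # one encounter just outside the 18-month lookback
            tables["encounters"].append(
                dict(
                    client_id=cid,
                    date=spec.as_of_date - dt.timedelta(days=600),
                    source_system="primary_care_emr",
                    program="primary_care",
                    attended=True,
                )
            )
    return Bundle.model_validate(tables)


def make_worked_fixtures(as_of: dt.date = dt.date(2019, 1, 1)) -> Bundle:
    """Deterministic hand-built clients exercising the boundary rules.

    Client ids name the scenario; several reproduce the anchor rows of
    the scoring rule table exactly (no visits, five dispersed visits,
    five programs, empty problem list, PHQ-9 just over threshold, ...).
    """
    def d(days: int) -> dt.date:
        return as_of - dt.timedelta(days=days)

    tables: _Tables = {name: [] for name in TABLES}

    # q1 = 4: no visits inside the window (one stale encounter keeps the
    # client present in the bundle and exercises window filtering)
    tables["encounters"].append(
        dict(client_id="no_visits", date=d(585), program="primary_care")
    )

    # q1 = 0: five attended visits, 30 days apart
    for i in range(5):
        tables["encounters"].append(
            dict(client_id="five_dispersed", date=d(30 * (i + 1)), program="primary_care",
                 booked=True, attended=True)
        )

    # q1 = 3: six visits within a single week collapse to one
    for i in range(6):
        tables["encounters"].append(
            dict(client_id="one_burst_week", date=d(100 - i), program="primary_care")
        )

    # q2 = 4: attended encounters in five distinct programs
    for i, prog in enumerate(["p1", "p2", "p3", "p4", "p5"]):
        tables["encounters"].append(
            dict(client_id="five_programs", date=d(40 * (i + 1)), program=prog,
                 booked=True, attended=True)
        )

    # q2 = 3: three programs (base 2) plus eleven no-shows (+1)
    for i, prog in enumerate(["p1", "p2", "p3"]):
        tables["encounters"].append(
            dict(client_id="three_prog_nsba", date=d(30 * (i + 1)), program=prog)
        )
    for i in range(11):
        tables["encounters"].append(
            dict(client_id="three_prog_nsba", date=d(10 + 9 * i), program="p1",
                 booked=True, attended=False)
        )

    # q7 = 0: an encounter but an empty problem list and no other evidence
    tables["encounters"].append(
        dict(client_id="empty_problem_list", date=d(20), program="primary_care")
    )

    # q7 = 2: one SU/MH diagnosis, not on Extended Leave
    tables["problems"].append(
        dict(client_id="sumh_only", code="F32", label="depressive episode")
    )

    # q9 = 4: latest PHQ-9 of 10 with an otherwise clean record
    tables["phq9"].append(dict(client_id="phq9_ten", date=d(15), total=10))
    tables["honos"].append(dict(client_id="phq9_ten", date=d(15), items=[0] * 12))

    # q3/q5/q6/q9 mid-range HoNOS profile
    tables["honos"].append(
        dict(client_id="honos_mid", date=d(60),
             items=[2, 1, 0, 3, 1, 0, 0, 2, 1, 2, 2, 1])
    )

    # all presence triggers at once; q2..q9 hit the maximum (q1 stays 0
    # because the same attended encounters that max Q2 are visits)
    for i, prog in enumerate(["p1", "p2", "p3", "p4", "p5"]):
        tables["encounters"].append(
            dict(client_id="max_triggers", date=d(45 * (i + 1)), program=prog,
                 booked=True, attended=True)
        )
    tables["honos"].append(dict(client_id="max_triggers", date=d(10), items=[4] * 12))
    for code in ["E11", "F20", "G30", "I50", "N18", "J44"]:
        tables["problems"].append(dict(client_id="max_triggers", code=code, label=f"dx {code}"))
    tables["vitals"].append(
        dict(client_id="max_triggers", date=d(12), systolic_bp=160.0, diastolic_bp=100.0,
             bmi=38.0)
    )
    for i in range(6):
        tables["ed_visits"].append(
            dict(client_id="max_triggers", date=d(20 + 15 * i), ctas_level=1)
        )
    tables["admissions"].append(
        dict(client_id="max_triggers", admit_date=d(120), discharge_date=d(90))
    )
    for kind in ["PWD_FORM", "SHX_CODE", "INTERRAI_MDS", "VIOLENCE_ALERT", "EXTENDED_LEAVE"]:
        tables["flags"].append(dict(client_id="max_triggers", flag_kind=kind, date=d(30)))
    tables["phq9"].append(dict(client_id="max_triggers", date=d(25), total=24))

    return Bundle.model_validate(tables)
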