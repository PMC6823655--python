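"""Nine-domain biopsychosocial complexity scoring.

Each domain receives a partial complexity score (Q-score) on a 0-4
Likert-type scale, computed from a windowed
:class:`~carecomplexity.records.VirtualPatientRecord`:

* Q1 attachment — collapsed visit count in the lookback window
* Q2 service density — distinct services/programs, no-show elevation
* Q3 social/environmental — HoNOS housing & occupation items, PWD/SHX
* Q4 psychosocial — HoNOS cognitive/behavioural/functional items
* Q5 relationships — HoNOS relationship items, SHX codes
* Q6 activities of daily living — HoNOS ADL items, InterRAI/mobility
* Q7 medical complexity — problem-list tiers plus BP/BMI modifiers
* Q8 acute utilization — hospitalization complexity score bins
* Q9 risk of harm — HoNOS behaviour/self-harm items, alerts, PHQ-9

Missing assessment data never raises: a domain with no contributing
evidence scores 0 and its completeness flag is cleared, so marginalized
clients with thin records are still scored.  Attachment is the one
exception — the *absence* of visits is itself the signal, so Q1 is
always considered complete.
"""

from __future__ import annotations

import datetime as dt
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .records import (
    AnalysisWindow,
    FlagKind,
    HonosAssessment,
    VirtualPatientRecord,
    latest_honos,
    latest_phq9,
    latest_vitals,
    window_filter,
)

__all__ = [
    "ScoringConfig",
    "DomainScoreVector",
    "DOMAIN_NAMES",
    "collapse_encounters",
    "score_attachment",
    "score_service_density",
    "score_social_environmental",
    "score_psychosocial",
    "score_relationships",
    "score_adl",
    "score_medical_complexity",
    "hospitalization_complexity_score",
    "score_acute_utilization",
    "score_risk_of_harm",
    "score_all",
]

DOMAIN_NAMES = {
    1: "attachment",
    2: "service_density",
    3: "social_environmental",
    4: "psychosocial",
    5: "relationships",
    6: "adl",
    7: "medical_complexity",
    8: "acute_utilization",
    9: "risk_of_harm",
}


def _default_codelist(name: str) -> set[str]:
    text = resources.files("carecomplexity.config.codelists").joinpath(f"{name}.txt").read_text()
    return {
        line.strip() for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    }


class ScoringConfig(BaseModel):
    """Tunable rule parameters with the operational defaults.

    The shipped code lists (substance-use/mental-health, complex-care,
    neurodegenerative) are small documented placeholders; deployments
    substitute their jurisdiction's lists via config.
    """

    model_config = ConfigDict(validate_assignment=True)

    encounter_collapse_days: int = Field(default=7, gt=0)
    nsba_threshold: int = Field(default=10, ge=0)
    bp_systolic_threshold: float = 140.0
    bp_diastolic_threshold: float = 90.0
    bp_increment: float = 0.5
    # (cutoff, increment) pairs; the highest applicable cutoff wins
    bmi_cutoffs: list[tuple[float, float]] = Field(
        default_factory=lambda: [(25.0, 0.25), (30.0, 0.5), (35.0, 0.75)]
    )
    dx_elevation_threshold: int = 5
    dx_elevation_increment: float = 1.0
    phq9_threshold: int = 9
    hcs_bins: list[float] = Field(default_factory=lambda: [0.0, 15.0, 25.0, 50.0])
    sumh_codes: set[str] = Field(default_factory=lambda: _default_codelist("sumh"))
    complex_care_codes: set[str] = Field(default_factory=lambda: _default_codelist("complex_care"))
    neurodegenerative_codes: set[str] = Field(
        default_factory=lambda: _default_codelist("neurodegenerative")
    )

    @field_validator("hcs_bins")
    @classmethod
    def _bins_increasing(cls, v: list[float]) -> list[float]:
        if sorted(v) != v or len(set(v)) != len(v):
            raise ValueError("hcs_bins must be strictly increasing")
        return v

    @field_validator("bmi_cutoffs")
    @classmethod
    def _cutoffs_valid(cls, v: list[tuple[float, float]]) -> list[tuple[float, float]]:
        v = sorted(v)
        if any(inc < 0 for _, inc in v):
            raise ValueError("BMI increments must be non-negative")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("sumh_codes", "complex_care_codes", "neurodegenerative_codes"):
            val = data.get(key)
            if isinstance(val, str):  # path to a one-code-per-line file
                codes_path = Path(val)
                if not codes_path.is_absolute():
                    codes_path = Path(path).parent / codes_path
                data[key] = {
                    line.strip() for line in codes_path.read_text().splitlines()
                    if line.strip() and not line.lstrip().startswith("#")
                }
        return cls.model_validate(data)


class DomainScoreVector(BaseModel):
    """The nine Q-scores plus per-domain data-completeness flags.

    Every score lies in [0, 4].  Q7 may be fractional after the BP/BMI
    modifiers; the others are integers.  A completeness flag is true
    when at least one contributing data element was present for that
    domain (Q1 is always complete: no visits is itself evidence).
    """

    model_config = ConfigDict(frozen=True)

    q1: float = Field(ge=0, le=4)
    q2: float = Field(ge=0, le=4)
    q3: float = Field(ge=0, le=4)
    q4: float = Field(ge=0, le=4)
    q5: float = Field(ge=0, le=4)
    q6: float = Field(ge=0, le=4)
    q7: float = Field(ge=0, le=4)
    q8: float = Field(ge=0, le=4)
    q9: float = Field(ge=0, le=4)
    completeness: tuple[bool, bool, bool, bool, bool, bool, bool, bool, bool] = (
        (True,) * 9
    )

    def as_tuple(self) -> tuple[float, ...]:
        return (self.q1, self.q2, self.q3, self.q4, self.q5,
                self.q6, self.q7, self.q8, self.q9)


# ---------------------------------------------------------------------------
# helpers

def _honos_max(assessment: Optional[HonosAssessment], item_numbers: Sequence[int]) -> int:
    """AND/OR over listed HoNOS items reads as the max over the items."""
    if assessment is None:
        return 0
    return max(assessment.item(n) for n in item_numbers)


def _problem_categories(vpr: VirtualPatientRecord, config: ScoringConfig):
    """Resolve problem-list category membership from entry booleans or code lists."""
    any_sumh = any(p.is_sumh or p.code in config.sumh_codes for p in vpr.problems)
    any_cc = any(p.is_complex_care or p.code in config.complex_care_codes for p in vpr.problems)
    any_neuro = any(
        p.is_neurodegenerative or p.code in config.neurodegenerative_codes for p in vpr.problems
    )
    return any_sumh, any_cc, any_neuro


def _clamp(x: float) -> float:
    return min(4.0, max(0.0, x))


# ---------------------------------------------------------------------------
# Q1 attachment

def collapse_encounters(dates: Sequence[dt.date], collapse_days: int = 7) -> list[dt.date]:
    """Collapse visit dates less than ``collapse_days`` apart into one visit.

    Greedy forward scan over the sorted dates: a date is dropped when it
    falls fewer than ``collapse_days`` days after the last retained
    date.  This operationalizes "equally dispersed" visits: a flurry of
    same-week contacts counts as a single act of engagement.
    """
    retained: list[dt.date] = []
    for date in sorted(dates):
        if not retained or (date - retained[-1]).days >= collapse_days:
            retained.append(date)
    return retained


def score_attachment(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Q1: fewer (collapsed) visits in the window means poorer attachment.

    4+ visits -> 0, 3 -> 1, 2 -> 2, 1 -> 3, none -> 4.  Only attended
    encounters count as visits; a no-show is not a visit.
    """
    dates = [e.date for e in vpr.encounters if e.attended]
    n = len(collapse_encounters(dates, config.encounter_collapse_days))
    return float(max(0, 4 - n))


# ---------------------------------------------------------------------------
# Q2 service density

def score_service_density(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Q2: breadth of concurrent service involvement.

    Distinct programs with an attended encounter map 1 -> 0, 2 -> 1,
    3 -> 2, 4 -> 3, >4 -> 4; more than ``nsba_threshold`` no-shows in
    the window elevates the score by 1 (clamped to 4).
    """
    programs = {e.program for e in vpr.encounters if e.attended}
    p = len(programs)
    base = 0 if p <= 1 else min(p - 1, 4)
    nsba = sum(1 for e in vpr.encounters if e.is_nsba)
    if nsba > config.nsba_threshold:
        base += 1
    return _clamp(float(base))


# ---------------------------------------------------------------------------
# Q3-Q6, Q9: HoNOS-anchored domains with presence triggers

def score_social_environmental(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Q3: housing instability (HoNOS 11) and occupation/activities
    (HoNOS 12); PWD forms or SHX codes set the maximum."""
    if vpr.has_flag(FlagKind.PWD_FORM) or vpr.has_flag(FlagKind.SHX_CODE):
        return 4.0
    return float(_honos_max(latest_honos(vpr, window), (11, 12)))


def score_psychosocial(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Q4: cognitive (HoNOS 4), behavioural (1, 8) and functional (5)
    impairment."""
    return float(_honos_max(latest_honos(vpr, window), (1, 4, 5, 8)))


def score_relationships(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Q5: relationship problems (HoNOS 9, 11, 12); recorded SHX
    problems set the maximum."""
    if vpr.has_flag(FlagKind.SHX_CODE):
        return 4.0
    return float(_honos_max(latest_honos(vpr, window), (9, 11, 12)))


def score_adl(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Q6: activities of daily living (HoNOS 5, 10, 11, 12); an
    InterRAI-MDS or mobility assessment sets the maximum."""
    if vpr.has_flag(FlagKind.INTERRAI_MDS) or vpr.has_flag(FlagKind.MOBILITY_ASSESSMENT):
        return 4.0
    return float(_honos_max(latest_honos(vpr, window), (5, 10, 11, 12)))


def score_risk_of_harm(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Q9: risk of harm to self or others (HoNOS 1, 2); violence
    alerts, Extended Leave, or a latest PHQ-9 above threshold set the
    maximum."""
    if vpr.has_flag(FlagKind.VIOLENCE_ALERT) or vpr.has_flag(FlagKind.EXTENDED_LEAVE):
        return 4.0
    phq = latest_phq9(vpr, window)
    if phq is not None and phq.total > config.phq9_threshold:
        return 4.0
    return float(_honos_max(latest_honos(vpr, window), (1, 2)))


# ---------------------------------------------------------------------------
# Q7 medical complexity

def score_medical_complexity(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Q7: problem-list tier plus additive BP/BMI/diagnosis-count
    modifiers, clamped to [0, 4].

    Base tier (highest matching wins):

    * 4 — any complex-care code, or 6+ diagnoses, or SU/MH diagnosis
      while on Extended Leave, or a neurodegenerative disorder, or any
      item at 4 on the latest HoNOS
    * 3 — 2+ diagnoses together with a SU/MH diagnosis
    * 2 — any SU/MH diagnosis, not on Extended Leave
    * 1 — 4+ diagnoses
    * 0 — empty problem list

    Modifiers: +1 for more than 5 diagnoses; +0.5 for latest BP above
    140/90 (systolic or diastolic); the single highest applicable BMI
    increment (+0.25 above 25, +0.5 above 30, +0.75 above 35).
    """
    n_dx = len(vpr.problems)
    any_sumh, any_cc, any_neuro = _problem_categories(vpr, config)
    on_leave = vpr.has_flag(FlagKind.EXTENDED_LEAVE)
    honos = latest_honos(vpr, window)
    honos_has_4 = honos is not None and max(honos.items) == 4

    if any_cc or n_dx >= 6 or (any_sumh and on_leave) or any_neuro or honos_has_4:
        base = 4.0
    elif n_dx >= 2 and any_sumh:
        base = 3.0
    elif any_sumh and not on_leave:
        base = 2.0
    elif n_dx >= 4:
        base = 1.0
    else:
        base = 0.0

    score = base
    if n_dx > config.dx_elevation_threshold:
        score += config.dx_elevation_increment

    obs = latest_vitals(vpr, window)
    if obs is not None:
        high_bp = (
            (obs.systolic_bp is not None and obs.systolic_bp > config.bp_systolic_threshold)
            or (obs.diastolic_bp is not None and obs.diastolic_bp > config.bp_diastolic_threshold)
        )
        if high_bp:
            score += config.bp_increment
        if obs.bmi is not None:
            increment = 0.0
            for cutoff, inc in sorted(config.bmi_cutoffs):
                if obs.bmi > cutoff:
                    increment = inc
            score += increment

    return _clamp(score)


# ---------------------------------------------------------------------------
# Q8 acute utilization

def hospitalization_complexity_score(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Combined acute-utilization burden: inverse CTAS plus length of stay.

    Each ED visit contributes ``6 - ctas_level`` (a resuscitation-level
    visit counts 5, a non-urgent visit 1); each acute admission
    contributes its length of stay in days, open admissions accruing to
    the as-of date.
    """
    ed = sum(6 - v.ctas_level for v in vpr.ed_visits)
    los = sum(a.los_days(window.as_of_date) for a in vpr.admissions)
    return float(ed + los)


def score_acute_utilization(
    vpr: VirtualPatientRecord, window: AnalysisWindow, config: ScoringConfig
) -> float:
    """Q8: bin the hospitalization complexity score.

    0 -> 0; (0, 15) -> 1; [15, 25) -> 2; [25, 50] -> 3; > 50 -> 4.
    Where the printed anchor points overlap, the higher score wins.
    """
    hcs = hospitalization_complexity_score(vpr, window, config)
    b1, b2, b3 = config.hcs_bins[1], config.hcs_bins[2], config.hcs_bins[3]
    if hcs > b3:
        return 4.0
    if hcs >= b2:
        return 3.0
    if hcs >= b1:
        return 2.0
    if hcs > 0:
        return 1.0
    return 0.0


# ---------------------------------------------------------------------------
# composition

def _completeness(vpr: VirtualPatientRecord, window: AnalysisWindow) -> tuple[bool, ...]:
    """Per-domain evidence-presence flags on the windowed VPR."""
    has_honos = latest_honos(vpr, window) is not None
    has_enc = bool(vpr.encounters)
    flags = {f.flag_kind for f in vpr.flags}
    return (
        True,  # Q1: absence of visits is itself the attachment signal
        has_enc,
        has_honos or bool(flags & {FlagKind.PWD_FORM, FlagKind.SHX_CODE}),
        has_honos,
        has_honos or FlagKind.SHX_CODE in flags,
        has_honos or bool(flags & {FlagKind.INTERRAI_MDS, FlagKind.MOBILITY_ASSESSMENT}),
        bool(vpr.problems) or bool(vpr.vitals) or has_honos or FlagKind.EXTENDED_LEAVE in flags,
        bool(vpr.ed_visits) or bool(vpr.admissions),
        has_honos
        or bool(vpr.phq9)
        or bool(flags & {FlagKind.VIOLENCE_ALERT, FlagKind.EXTENDED_LEAVE}),
    )


_SCORERS = (
    score_attachment,
    score_service_density,
    score_social_environmental,
    score_psychosocial,
    score_relationships,
    score_adl,
    score_medical_complexity,
    score_acute_utilization,
    score_risk_of_harm,
)


def score_all(
    vpr: VirtualPatientRecord,
    window: AnalysisWindow,
    config: Optional[ScoringConfig] = None,
) -> DomainScoreVector:
    """Apply the analysis window once, then all nine domain scorers."""
    if config is None:
        config = ScoringConfig()
    windowed = window_filter(vpr, window)
    scores = [scorer(windowed, window, config) for scorer in _SCORERS]
    return DomainScoreVector(
        **{f"q{i}": s for i, s in enumerate(scores, start=1)},
        completeness=_completeness(windowed, window),
    )
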