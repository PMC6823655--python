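"""Independent brute-force re-implementation of the scoring rules.

Used only as a test oracle: every rule is written as straight-line
condition enumeration over the raw record lists, with its own window
arithmetic (no dateutil) and its own composite formula.  It shares no
code with the package paths it checks.
"""

from __future__ import annotations

import calendar
import datetime as dt
import math


def month_window_start(as_of: dt.date, months: int) -> dt.date:
    """Subtract calendar months, clamping the day to the month length."""
    total = as_of.year * 12 + (as_of.month - 1) - months
    year, month = divmod(total, 12)
    month += 1
    day = min(as_of.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def in_window(date: dt.date, as_of: dt.date, months: int = 18) -> bool:
    return month_window_start(as_of, months) < date <= as_of


def naive_scores(vpr, as_of: dt.date, months: int = 18) -> list[float]:
    """All nine domain scores by direct enumeration of the rule table."""
    enc = [e for e in vpr.encounters if in_window(e.date, as_of, months)]
    honos_all = [h for h in vpr.honos if in_window(h.date, as_of, months)]
    phq_all = [r for r in vpr.phq9 if in_window(r.date, as_of, months)]
    vit_all = [v for v in vpr.vitals if in_window(v.date, as_of, months)]
    eds = [v for v in vpr.ed_visits if in_window(v.date, as_of, months)]
    start = month_window_start(as_of, months)
    adms = [
        a for a in vpr.admissions
        if a.admit_date <= as_of
        and (a.discharge_date if a.discharge_date is not None else as_of) > start
    ]
    flags = {f.flag_kind.value for f in vpr.flags}

    # latest HoNOS: max date, ties by larger item sum
    latest_h = None
    for h in honos_all:
        if latest_h is None or (h.date, sum(h.items)) > (latest_h.date, sum(latest_h.items)):
            latest_h = h
    latest_p = None
    for r in phq_all:
        if latest_p is None or (r.date, r.total) > (latest_p.date, latest_p.total):
            latest_p = r
    latest_v = None
    for v in vit_all:
        if latest_v is None or v.date >= latest_v.date:
            latest_v = v

    def hmax(*numbers: int) -> int:
        if latest_h is None:
            return 0
        return max(latest_h.items[n - 1] for n in numbers)

    # Q1: collapse attended visit dates with a 7-day greedy scan
    visit_dates = sorted(e.date for e in enc if e.attended)
    kept: list[dt.date] = []
    for date in visit_dates:
        if not kept or (date - kept[-1]).days >= 7:
            kept.append(date)
    n = len(kept)
    if n >= 4:
        q1 = 0
    elif n == 3:
        q1 = 1
    elif n == 2:
        q1 = 2
    elif n == 1:
        q1 = 3
    else:
        q1 = 4

    # Q2
    progs = set()
    for e in enc:
        if e.attended:
            progs.add(e.program)
    p = len(progs)
    if p <= 1:
        q2 = 0
    elif p == 2:
        q2 = 1
    elif p == 3:
        q2 = 2
    elif p == 4:
        q2 = 3
    else:
        q2 = 4
    nsba = sum(1 for e in enc if e.booked and not e.attended)
    if nsba > 10:
        q2 += 1
    q2 = min(q2, 4)

    # Q3
    if "PWD_FORM" in flags or "SHX_CODE" in flags:
        q3 = 4
    else:
        q3 = hmax(11, 12)

    # Q4
    q4 = hmax(1, 4, 5, 8)

    # Q5
    q5 = 4 if "SHX_CODE" in flags else hmax(9, 11, 12)

    # Q6
    if "INTERRAI_MDS" in flags or "MOBILITY_ASSESSMENT" in flags:
        q6 = 4
    else:
        q6 = hmax(5, 10, 11, 12)

    # Q7
    n_dx = len(vpr.problems)
    sumh_list = {"F10", "F11", "F12", "F19", "F20", "F25", "F29", "F31", "F32", "F33",
                 "F41", "F43"}
    cc_list = {"E10", "E11", "I50", "J44", "N18", "C34", "B20"}
    neuro_list = {"G20", "G30", "G35", "G10"}
    any_sumh = any(pr.is_sumh or pr.code in sumh_list for pr in vpr.problems)
    any_cc = any(pr.is_complex_care or pr.code in cc_list for pr in vpr.problems)
    any_neuro = any(pr.is_neurodegenerative or pr.code in neuro_list for pr in vpr.problems)
    on_leave = "EXTENDED_LEAVE" in flags
    honos_has4 = latest_h is not None and 4 in latest_h.items

    if any_cc or n_dx >= 6 or (any_sumh and on_leave) or any_neuro or honos_has4:
        q7 = 4.0
    elif n_dx >= 2 and any_sumh:
        q7 = 3.0
    elif any_sumh and not on_leave:
        q7 = 2.0
    elif n_dx >= 4:
        q7 = 1.0
    else:
        q7 = 0.0
    if n_dx > 5:
        q7 += 1.0
    if latest_v is not None:
        if (latest_v.systolic_bp is not None and latest_v.systolic_bp > 140) or (
            latest_v.diastolic_bp is not None and latest_v.diastolic_bp > 90
        ):
            q7 += 0.5
        if latest_v.bmi is not None:
            if latest_v.bmi > 35:
                q7 += 0.75
            elif latest_v.bmi > 30:
                q7 += 0.5
            elif latest_v.bmi > 25:
                q7 += 0.25
    q7 = min(4.0, max(0.0, q7))

    # Q8
    hcs = 0.0
    for v in eds:
        hcs += 6 - v.ctas_level
    for a in adms:
        end = a.discharge_date if a.discharge_date is not None else as_of
        hcs += max(0, (end - a.admit_date).days)
    if hcs > 50:
        q8 = 4
    elif hcs >= 25:
        q8 = 3
    elif hcs >= 15:
        q8 = 2
    elif hcs > 0:
        q8 = 1
    else:
        q8 = 0

    # Q9
    if "VIOLENCE_ALERT" in flags or "EXTENDED_LEAVE" in flags:
        q9 = 4
    elif latest_p is not None and latest_p.total > 9:
        q9 = 4
    else:
        q9 = hmax(1, 2)

    return [float(q1), float(q2), float(q3), float(q4), float(q5),
            float(q6), q7, float(q8), float(q9)]


def naive_ccs(q: list[float], weights: list[float] | None = None) -> float:
    """Direct formula evaluation of the (weighted) composite."""
    if weights is None:
        weights = [1.0] * 9
    total = 0.0
    for qi, wi in zip(q, weights):
        total += (wi * qi / 4.0) ** 2
    return math.sqrt(total)
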