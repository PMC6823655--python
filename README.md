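# carecomplexity

Person-oriented **biopsychosocial complexity scoring** for community
health-center (CHC) populations, computed from linked multi-source
clinical and administrative records.

CHCs serve marginalized clients whose needs — housing instability,
substance use, mental illness, chronic disease, fractured service
involvement — are poorly captured by disease-oriented case-mix indices.
This package scores each client on **nine complexity domains** using
whatever evidence the record systems already hold, then combines the
domain scores into a composite that supports empanelment, panel
balancing, workload assessment and population reporting.

## The model

Records from several source systems (a primary-care EMR, a community
mental-health EMR, ED and acute-care data marts) are linked by exact
client id into a *virtual patient record* and restricted to an
18-calendar-month lookback window. Nine rule-based scorers each emit a
**Q-score** on a 0–4 Likert-type scale:

| domain | signal |
|---|---|
| Q1 attachment | collapsed visit count (visits < 7 days apart merge); fewer visits → higher score |
| Q2 service density | distinct services/programs attended; > 10 no-shows adds 1 |
| Q3 social/environmental | HoNOS items 11–12; PWD forms or SHX codes → 4 |
| Q4 psychosocial | max of HoNOS items 1, 4, 5, 8 |
| Q5 relationships | max of HoNOS items 9, 11, 12; SHX codes → 4 |
| Q6 activities of daily living | max of HoNOS items 5, 10, 11, 12; InterRAI-MDS / mobility assessment → 4 |
| Q7 medical complexity | problem-list tiers (complex-care codes, diagnosis counts, SU/MH, Extended Leave) plus BP/BMI modifiers |
| Q8 acute utilization | hospitalization complexity score Σ(6 − CTAS) + Σ LOS, binned |
| Q9 risk of harm | max of HoNOS items 1–2; violence alerts, Extended Leave, or PHQ-9 > 9 → 4 |

Each Q is divided by 4 to give an adjusted value *p*ᵢ ∈ [0, 1], and the
**Composite Complexity Score** is the root sum squared

&nbsp;&nbsp;&nbsp;&nbsp;CCS = √(p₁² + p₂² + … + p₉²) &nbsp;∈ [0, 3].

Domains are additionally weighted by staff-perceived importance,
derived from a five-point survey: over-weighted domains ×1.20, neutral
×1.00, under-weighted ×0.75 (defaults: Q3/Q4/Q7 up, Q1/Q6/Q9 neutral,
Q2/Q5/Q8 down). Weighted scores multiply *p*ᵢ inside the root sum
square, keeping the maximum at √(3(1.2² + 1² + 0.75²)) ≈ 3.00125.
Weighted and unweighted scores are always reported side by side.

Missing assessments never fail: a domain with no contributing evidence
scores 0 and its completeness flag is cleared.

## Worked example

The package ships deterministic anchor clients plus a synthetic cohort
generator (no patient data anywhere):

```python
import datetime as dt
import carecomplexity as cc

window = cc.AnalysisWindow(as_of_date=dt.date(2019, 1, 1))   # 18-month lookback
bundle = cc.make_worked_fixtures(window.as_of_date)
for vpr in cc.link_records(bundle):
    vec = cc.score_all(vpr, window)
    res = cc.composite_weighted(vec)
    print(f"{vpr.client_id:20s} q={vec.as_tuple()}  CCS={res.ccs_unweighted:.3f} "
          f"weighted={res.ccs_weighted:.3f}  delta={res.delta:+.3f}")
```

prints (abridged):

```
five_dispersed       q=(0, 0, 0, 0, 0, 0, 0, 0, 0)  CCS=0.000  weighted=0.000  delta=+0.000
no_visits            q=(4, 0, 0, 0, 0, 0, 0, 0, 0)  CCS=1.000  weighted=1.000  delta=+0.000
five_programs        q=(0, 4, 0, 0, 0, 0, 0, 0, 0)  CCS=1.000  weighted=0.750  delta=-0.250
phq9_ten             q=(4, 0, 0, 0, 0, 0, 0, 0, 4)  CCS=1.414  weighted=1.414  delta=+0.000
max_triggers         q=(0, 4, 4, 4, 4, 4, 4, 4, 4)  CCS=2.828  weighted=2.830  delta=+0.001
```

`five_dispersed` (five well-spaced attended visits) is fully attached
and scores zero everywhere; `no_visits` earns the maximal attachment
score Q1 = 4; `five_programs` is spread over five services (Q2 = 4) and
its weighted score drops because service density is under-weighted
(×0.75); a latest PHQ-9 of 10 forces Q9 = 4.

The same pipeline is available from the shell:

```bash
carecomplexity simulate --n 500 --mixture low=0.5,high=0.5 --seed 7 --out cohort.json
carecomplexity score  --bundle cohort.json --as-of 2019-01-01 --out scores/
carecomplexity report --bundle cohort.json --as-of 2019-01-01 --out report/
carecomplexity weights --survey survey.csv --out weights.yaml
```

`report/` then holds the population tables: composite-score band counts
(0–1, 1–2, 2+, weighted and unweighted), per-domain score
distributions, and the per-client weighted-vs-unweighted delta.

## Layout

- `carecomplexity.records` — record types, bundle I/O (JSON / CSV dir),
  exact-ID linkage, analysis-window filtering
- `carecomplexity.scoring` — the nine domain scorers and their config
- `carecomplexity.composite` — CCS, weighting, survey-derived weights
- `carecomplexity.reporting` — population band counts, breakdowns, deltas
- `carecomplexity.synthetic` — archetype-mixture cohort generator
- `carecomplexity.cli` — `simulate` / `score` / `report` / `weights`
- `docs/methods.md` — modelling choices, parameters, limitations
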