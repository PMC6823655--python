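"""Composite Complexity Score (CCS) and domain weighting.

Each domain Q-score (0-4) is divided by 4, giving an adjusted value
p_i in [0, 1].  The composite is the root sum squared of the adjusted
vector,

    CCS = sqrt(p1^2 + ... + p9^2),

which ranges from 0 (no complexity evidence in any domain) to 3 (all
nine domains at the scale maximum).  Weighting multiplies each p_i by
a per-domain factor inside the root sum square; with the default
three-tier factors (1.20 / 1.00 / 0.75, three domains each) the
attainable maximum is sqrt(3*(1.2^2 + 1.0^2 + 0.75^2)) ~= 3.00125, so
the intended 0-3 range is preserved up to rounding.  Weighted and
unweighted scores are always reported together: the weights encode
local stakeholder values and are expected to vary by site and time.

Weights derive from a five-point staff importance survey: domains are
tiered by the fraction of respondents rating them Important or Very
Important, and each tier maps to a multiplicative factor.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .scoring import DomainScoreVector

__all__ = [
    "WeightConfig",
    "CompositeResult",
    "SurveySummary",
    "TieringConfig",
    "DEFAULT_WEIGHTS",
    "composite_unweighted",
    "composite_weighted",
    "derive_weights_from_survey",
    "max_weighted_ccs",
]

#: Default per-domain factors: three over-weighted (1.20), three neutral
#: (1.00), three under-weighted (0.75), per the staff-survey tiering.
DEFAULT_WEIGHTS: dict[str, float] = {
    "w1": 1.00, "w2": 0.75, "w3": 1.20,
    "w4": 1.20, "w5": 0.75, "w6": 1.00,
    "w7": 1.20, "w8": 0.75, "w9": 1.00,
}

RATING_CATEGORIES = (
    "not_important",
    "slightly_important",
    "moderately_important",
    "important",
    "very_important",
)


class WeightConfig(BaseModel):
    """Per-domain multiplicative weighting factors."""

    model_config = ConfigDict(frozen=True)

    w1: float = Field(default=DEFAULT_WEIGHTS["w1"], gt=0)
    w2: float = Field(default=DEFAULT_WEIGHTS["w2"], gt=0)
    w3: float = Field(default=DEFAULT_WEIGHTS["w3"], gt=0)
    w4: float = Field(default=DEFAULT_WEIGHTS["w4"], gt=0)
    w5: float = Field(default=DEFAULT_WEIGHTS["w5"], gt=0)
    w6: float = Field(default=DEFAULT_WEIGHTS["w6"], gt=0)
    w7: float = Field(default=DEFAULT_WEIGHTS["w7"], gt=0)
    w8: float = Field(default=DEFAULT_WEIGHTS["w8"], gt=0)
    w9: float = Field(default=DEFAULT_WEIGHTS["w9"], gt=0)
    note: str = ""

    def as_tuple(self) -> tuple[float, ...]:
        return (self.w1, self.w2, self.w3, self.w4, self.w5,
                self.w6, self.w7, self.w8, self.w9)

    @classmethod
    def identity(cls, note: str = "identity weights") -> "WeightConfig":
        return cls(**{f"w{i}": 1.0 for i in range(1, 10)}, note=note)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WeightConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


class CompositeResult(BaseModel):
    """Adjusted p-vector plus composite scores for one client.

    ``ccs_weighted`` and ``delta`` are None when only the unweighted
    composite was requested.
    """

    model_config = ConfigDict(frozen=True)

    p: tuple[float, float, float, float, float, float, float, float, float]
    ccs_unweighted: float
    ccs_weighted: Optional[float] = None
    delta: Optional[float] = None

    @model_validator(mode="after")
    def _consistent(self) -> "CompositeResult":
        if (self.ccs_weighted is None) != (self.delta is None):
            raise ValueError("ccs_weighted and delta must be set together")
        return self


def _adjusted(q: DomainScoreVector) -> tuple[float, ...]:
    values = q.as_tuple()
    for i, x in enumerate(values, start=1):
        if not 0.0 <= x <= 4.0:
            raise ValueError(f"q{i}={x} outside [0, 4]")
    return tuple(x / 4.0 for x in values)


def composite_unweighted(q: DomainScoreVector) -> CompositeResult:
    """Unweighted CCS: root sum squared of the q/4 vector; range [0, 3]."""
    p = _adjusted(q)
    return CompositeResult(p=p, ccs_unweighted=math.sqrt(sum(x * x for x in p)))


def composite_weighted(q: DomainScoreVector, w: Optional[WeightConfig] = None) -> CompositeResult:
    """Weighted and unweighted CCS together, plus their delta.

    The factors multiply the adjusted p_i inside the root sum square;
    weighted scores are not re-normalized afterwards.
    """
    if w is None:
        w = WeightConfig()
    p = _adjusted(q)
    unweighted = math.sqrt(sum(x * x for x in p))
    weighted = math.sqrt(sum((wi * x) ** 2 for wi, x in zip(w.as_tuple(), p)))
    return CompositeResult(
        p=p, ccs_unweighted=unweighted, ccs_weighted=weighted, delta=weighted - unweighted
    )


def max_weighted_ccs(w: Optional[WeightConfig] = None) -> float:
    """Largest attainable weighted CCS (all domains at 4, p_i = 1)."""
    if w is None:
        w = WeightConfig()
    return math.sqrt(sum(wi * wi for wi in w.as_tuple()))


# ---------------------------------------------------------------------------
# survey-derived weights

class SurveySummary(BaseModel):
    """Rating counts from the five-point staff importance survey.

    ``counts[d][category]`` is the number of respondents giving domain
    ``d`` (1-9) that rating; ``n_respondents`` is the survey total (a
    respondent may skip a domain, so per-domain counts sum to at most
    n).
    """

    model_config = ConfigDict(frozen=True)

    counts: dict[int, dict[str, int]]
    n_respondents: int = Field(gt=0)

    @model_validator(mode="after")
    def _valid_counts(self) -> "SurveySummary":
        if set(self.counts) != set(range(1, 10)):
            raise ValueError("counts must cover domains 1..9 exactly")
        for d, row in self.counts.items():
            unknown = set(row) - set(RATING_CATEGORIES)
            if unknown:
                raise ValueError(f"domain {d}: unknown rating categories {sorted(unknown)}")
            if any(c < 0 for c in row.values()):
                raise ValueError(f"domain {d}: negative rating count")
            if sum(row.values()) > self.n_respondents:
                raise ValueError(f"domain {d}: counts exceed respondent total")
        return self

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurveySummary":
        """Read a domain x rating count table.

        Expected columns: ``domain`` (1-9) plus one column per rating
        category (``not_important`` ... ``very_important``).
        """
        frame = pd.read_csv(path)
        counts = {
            int(row["domain"]): {cat: int(row[cat]) for cat in RATING_CATEGORIES if cat in row}
            for _, row in frame.iterrows()
        }
        n = max(sum(row.values()) for row in counts.values())
        return cls(counts=counts, n_respondents=n)

    def high_fraction(self, domain: int) -> float:
        """Fraction of this domain's ratings that are Important or Very
        Important."""
        row = self.counts[domain]
        total = sum(row.values())
        if total == 0:
            raise ValueError(f"domain {domain}: no respondents")
        high = row.get("important", 0) + row.get("very_important", 0)
        return high / total


class TieringConfig(BaseModel):
    """Thresholds mapping the Important/Very-Important fraction to factors.

    Three tiers by default: fraction >= ``high_threshold`` -> 1.20,
    fraction < ``low_threshold`` -> 0.75, otherwise 1.00.  Setting
    ``low_threshold`` to None collapses to the two-tier scheme
    (>= high -> 1.20, else 0.75).
    """

    model_config = ConfigDict(frozen=True)

    high_threshold: float = Field(default=2 / 3, ge=0, le=1)
    low_threshold: Optional[float] = Field(default=1 / 3, ge=0, le=1)
    high_factor: float = 1.20
    mid_factor: float = 1.00
    low_factor: float = 0.75

    @model_validator(mode="after")
    def _ordered(self) -> "TieringConfig":
        if self.low_threshold is not None and self.low_threshold > self.high_threshold:
            raise ValueError("low_threshold must not exceed high_threshold")
        return self


def derive_weights_from_survey(
    survey: SurveySummary, tiering: Optional[TieringConfig] = None
) -> WeightConfig:
    """Map per-domain survey importance fractions onto weighting factors."""
    if tiering is None:
        tiering = TieringConfig()
    weights: dict[str, float] = {}
    for d in range(1, 10):
        frac = survey.high_fraction(d)
        if frac >= tiering.high_threshold:
            factor = tiering.high_factor
        elif tiering.low_threshold is None or frac < tiering.low_threshold:
            factor = tiering.low_factor
        else:
            factor = tiering.mid_factor
        weights[f"w{d}"] = factor
    note = (
        f"derived from staff survey (n={survey.n_respondents}); "
        f"thresholds high>={tiering.high_threshold:.3f}"
        + ("" if tiering.low_threshold is None else f", low<{tiering.low_threshold:.3f}")
        + f"; factors {tiering.high_factor}/{tiering.mid_factor}/{tiering.low_factor}"
    )
    return WeightConfig(**weights, note=note)
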