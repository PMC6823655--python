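"""Population-level aggregation of composite and domain scores.

Emits the tabular data behind the standard population charts: composite
score band counts (0-1, 1-2, 2+), per-domain score distributions
(weighted and unweighted), and the per-client delta between weighted
and unweighted composites.  Chart rendering itself is presentation and
is left to the caller.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .composite import CompositeResult, WeightConfig, composite_weighted, max_weighted_ccs
from .scoring import DomainScoreVector

__all__ = [
    "BAND_LABELS",
    "DOMAIN_BAND_LABELS",
    "PopulationReport",
    "interval_histogram",
    "domain_breakdown",
    "delta_report",
    "build_report",
    "export_report",
]

#: Composite score bands: [0,1), [1,2), [2, max]; the labels follow the
#: conventional "0-1 / 1-2 / 2+" presentation.
BAND_LABELS = ("0-1", "1-2", "2+")

#: Domain-score bands on the 0-4 scale: [0,1), [1,2), [2,3), [3, max].
DOMAIN_BAND_LABELS = ("0-1", "1-2", "2-3", "3+")


def interval_histogram(
    scores: Sequence[float], upper: float = 3.0, tol: float = 1e-9
) -> dict[str, int]:
    """Count composite scores into the 0-1 / 1-2 / 2+ bands.

    Bands are half-open below ([0,1), [1,2)) with the top band closed at
    ``upper`` (3.0 for unweighted scores; pass ``max_weighted_ccs(w)``
    for weighted scores, whose maximum slightly exceeds 3).
    """
    counts = dict.fromkeys(BAND_LABELS, 0)
    for s in scores:
        if s < 0 or s > upper + tol:
            raise ValueError(f"composite score {s} outside [0, {upper}]")
        if s < 1:
            counts["0-1"] += 1
        elif s < 2:
            counts["1-2"] += 1
        else:
            counts["2+"] += 1
    return counts


def domain_breakdown(
    vectors: Sequence[DomainScoreVector], w: Optional[WeightConfig] = None
) -> pd.DataFrame:
    """Per-domain distribution of raw and weighted domain scores.

    Weighted domain score = w_i * q_i (the weighted adjusted value
    scaled back to the 0-4 axis).  Returns a tidy frame with one row per
    (domain, band) and unweighted/weighted client counts; each domain's
    counts sum to the number of input clients.
    """
    if w is None:
        w = WeightConfig()
    factors = w.as_tuple()

    def band(x: float) -> str:
        if x < 1:
            return "0-1"
        if x < 2:
            return "1-2"
        if x < 3:
            return "2-3"
        return "3+"

    rows = []
    for d in range(9):
        raw_counts = dict.fromkeys(DOMAIN_BAND_LABELS, 0)
        wtd_counts = dict.fromkeys(DOMAIN_BAND_LABELS, 0)
        for vec in vectors:
            q = vec.as_tuple()[d]
            raw_counts[band(q)] += 1
            wtd_counts[band(factors[d] * q)] += 1
        for label in DOMAIN_BAND_LABELS:
            rows.append(
                {
                    "domain": f"q{d + 1}",
                    "band": label,
                    "count_unweighted": raw_counts[label],
                    "count_weighted": wtd_counts[label],
                }
            )
    return pd.DataFrame(rows, columns=["domain", "band", "count_unweighted", "count_weighted"])


def delta_report(results: Sequence[CompositeResult]) -> pd.DataFrame:
    """Per-client weighted-vs-unweighted composite deltas.

    Requires fully populated results (weighted and unweighted); the
    frame carries one row per client in input order.
    """
    rows = []
    for i, r in enumerate(results):
        if r.ccs_weighted is None:
            raise ValueError(f"result {i} has no weighted composite")
        rows.append(
            {
                "ccs_unweighted": r.ccs_unweighted,
                "ccs_weighted": r.ccs_weighted,
                "delta": r.delta,
            }
        )
    return pd.DataFrame(rows, columns=["ccs_unweighted", "ccs_weighted", "delta"])


class PopulationReport(BaseModel):
    """Aggregated population outputs for one scoring run."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_clients: int
    interval_counts_unweighted: dict[str, int]
    interval_counts_weighted: dict[str, int]
    domain_table: pd.DataFrame
    per_client: pd.DataFrame  # client_id, ccs_unweighted, ccs_weighted, delta
    delta_summary: dict[str, float]


def build_report(
    client_ids: Sequence[str],
    vectors: Sequence[DomainScoreVector],
    w: Optional[WeightConfig] = None,
) -> PopulationReport:
    """Score composites for a cohort and aggregate every report table."""
    if len(client_ids) != len(vectors):
        raise ValueError("client_ids and vectors differ in length")
    if w is None:
        w = WeightConfig()
    results = [composite_weighted(vec, w) for vec in vectors]
    deltas = delta_report(results)
    per_client = deltas.copy()
    per_client.insert(0, "client_id", list(client_ids))
    if len(results):
        summary = {
            "mean": float(deltas["delta"].mean()),
            "min": float(deltas["delta"].min()),
            "max": float(deltas["delta"].max()),
        }
    else:
        summary = {"mean": 0.0, "min": 0.0, "max": 0.0}
    return PopulationReport(
        n_clients=len(vectors),
        interval_counts_unweighted=interval_histogram([r.ccs_unweighted for r in results]),
        interval_counts_weighted=interval_histogram(
            [r.ccs_weighted for r in results], upper=max_weighted_ccs(w)
        ),
        domain_table=domain_breakdown(vectors, w),
        per_client=per_client,
        delta_summary=summary,
    )


def export_report(report: PopulationReport, path: str | Path, format: str = "csv") -> list[Path]:
    """Write the report tables under ``path``; returns the files written.

    CSV format emits one file per table plus a JSON summary; JSON format
    emits a single document holding every table.
    """
    path = Path(path)
    written: list[Path] = []
    band_frame = pd.DataFrame(
        {
            "band": list(BAND_LABELS),
            "count_unweighted": [report.interval_counts_unweighted[b] for b in BAND_LABELS],
            "count_weighted": [report.interval_counts_weighted[b] for b in BAND_LABELS],
        }
    )
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        targets = {
            "band_counts.csv": band_frame,
            "domain_breakdown.csv": report.domain_table,
            "per_client.csv": report.per_client,
        }
        for name, frame in targets.items():
            out = path / name
            frame.to_csv(out, index=False)
            written.append(out)
        summary_path = path / "summary.json"
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(
                {"n_clients": report.n_clients, "delta": report.delta_summary},
                fh,
                indent=1,
            )
            fh.write("\n")
        written.append(summary_path)
    elif format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = {
            "n_clients": report.n_clients,
            "band_counts": band_frame.to_dict(orient="records"),
            "domain_breakdown": report.domain_table.to_dict(orient="records"),
            "per_client": report.per_client.to_dict(orient="records"),
            "delta_summary": report.delta_summary,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
        written.append(path)
    else:
        raise ValueError(f"unknown report format {format!r}")
    return written
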