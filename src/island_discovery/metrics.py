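"""Descriptive discovery-history metrics.

Accumulation curves of first records / type collections / publications,
description lags (years between first collection and valid publication),
collector and author contribution tallies ("big hitters"), and per-island
normalized discovery curves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import Island, SpecimenRecord

logger = logging.getLogger(__name__)

EVENT_KINDS = ("earliest", "type", "publication")
ROLES = ("first_record", "type_specimen", "description")

_ROLE_FIELDS = {
    "first_record": ("earliest_collector", "earliest_year"),
    "type_specimen": ("type_collector", "type_year"),
    "description": ("describing_author", "publication_year"),
}


@dataclass
class AccumulationCurve:
    """Cumulative number of taxa whose event year is <= each year."""

    event_kind: str
    years: np.ndarray      # sorted ints
    cumulative: np.ndarray  # non-decreasing ints, same length

    def value_at(self, year: int) -> int:
        """Cumulative count at an arbitrary year (step-function lookup)."""
        idx = np.searchsorted(self.years, year, side="right") - 1
        return 0 if idx < 0 else int(self.cumulative[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "cumulative": self.cumulative,
                             "event_kind": self.event_kind})


@dataclass
class LagSummary:
    per_taxon_lag: dict[str, int]
    mean_lag: float
    fraction_exceeding: dict[int, float]


@dataclass
class CollectorTally:
    """Per-person event counts and shares for one role, sorted by descending
    count (ties alphabetical)."""

    role: str
    counts: dict[str, int]
    share: dict[str, float]
    n_events: int = field(init=False)

    def __post_init__(self):
        self.n_events = sum(self.counts.values())


def _event_year(record: SpecimenRecord, event_kind: str) -> int | None:
    if event_kind == "earliest":
        return record.earliest_year
    if event_kind == "type":
        return record.type_year
    if event_kind == "publication":
        return record.publication_year
    raise ValueError(f"unknown event_kind {event_kind!r}; "
                     f"expected one of {EVENT_KINDS}")


def accumulation_curve(records: list[SpecimenRecord],
                       event_kind: str) -> AccumulationCurve:
    """Cumulative discovery curve for one event kind."""
    if event_kind not in EVENT_KINDS:
        raise ValueError(f"unknown event_kind {event_kind!r}; "
                         f"expected one of {EVENT_KINDS}")
    years = sorted(y for r in records
                   if (y := _event_year(r, event_kind)) is not None)
    if not years:
        return AccumulationCurve(event_kind, np.array([], dtype=int),
                                 np.array([], dtype=int))
    uniq, counts = np.unique(np.asarray(years, dtype=int), return_counts=True)
    return AccumulationCurve(event_kind, uniq, np.cumsum(counts))


def lag_summary(records: list[SpecimenRecord],
                thresholds: list[int] = (100,)) -> LagSummary:
    """Description lags per taxon, their mean, and tail fractions.

    ``fraction_exceeding[t]`` is the proportion of taxa whose lag is strictly
    greater than ``t`` years.
    """
    lags = {r.taxon_id: r.lag for r in records if r.lag is not None}
    if not lags:
        return LagSummary({}, float("nan"), {int(t): 0.0 for t in thresholds})
    values = np.array(list(lags.values()), dtype=float)
    return LagSummary(
        per_taxon_lag=lags,
        mean_lag=float(values.mean()),
        fraction_exceeding={int(t): float((values > t).mean())
                            for t in thresholds},
    )


def big_hitters(records: list[SpecimenRecord], role: str) -> CollectorTally:
    """Tally of events per person for a role.

    A multi-collector string ("A & B") counts as one verbatim person; no name
    disambiguation is attempted.  Records missing the role's year are still
    tallied if the person field is non-empty.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    person_field, _ = _ROLE_FIELDS[role]
    counts: dict[str, int] = {}
    for r in records:
        person = getattr(r, person_field)
        if not person or person.lower() in ("nan", "na", ""):
            continue
        counts[person] = counts.get(person, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(c for _, c in ordered)
    counts = dict(ordered)
    share = {p: c / total for p, c in ordered} if total else {}
    return CollectorTally(role=role, counts=counts, share=share)


def top_k_share(tally: CollectorTally, k: int) -> float:
    """Combined share of the k largest contributors."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(tally.share)
    if k > n:
        logger.warning("top_k_share: k=%d exceeds %d persons; clamped", k, n)
        k = n
    return float(sum(list(tally.share.values())[:k]))


def island_fraction_curves(records: list[SpecimenRecord],
                           islands: list[Island]
                           ) -> dict[str, AccumulationCurve]:
    """Per-island cumulative fraction of first records through time.

    Each island's curve is its first-record accumulation curve divided by its
    final total, so every island with at least one record ends at exactly 1.
    Islands with no records map to an empty curve.
    """
    curves: dict[str, AccumulationCurve] = {}
    by_island: dict[str, list[int]] = {isl.code: [] for isl in islands}
    for r in records:
        if r.earliest_year is not None and r.earliest_island in by_island:
            by_island[r.earliest_island].append(r.earliest_year)
    for code, years in by_island.items():
        if not years:
            curves[code] = AccumulationCurve(
                "earliest", np.array([], dtype=int), np.array([]))
            continue
        uniq, counts = np.unique(np.asarray(years, dtype=int),
                                 return_counts=True)
        cum = np.cumsum(counts)
        curves[code] = AccumulationCurve("earliest", uniq, cum / cum[-1])
    return curves


def write_metrics_report(records: list[SpecimenRecord], islands: list[Island],
                         out_dir, thresholds: list[int] = (100,),
                         top_k: int = 5) -> dict:
    """Export curves and tallies as tidy CSVs plus a JSON summary.

    Returns the summary dict (mean lag, tail fractions, top-k shares and the
    person counts they are computed over).
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames = [accumulation_curve(records, k).to_frame() for k in EVENT_KINDS]
    pd.concat(frames, ignore_index=True).to_csv(
        out / "accumulation_curves.csv", index=False)

    rows = []
    for code, curve in island_fraction_curves(records, islands).items():
        for y, f in zip(curve.years, curve.cumulative):
            rows.append({"island": code, "year": int(y),
                         "fraction": round(float(f), 4)})
    pd.DataFrame(rows, columns=["island", "year", "fraction"]).to_csv(
        out / "island_fraction_curves.csv", index=False)

    lag = lag_summary(records, thresholds)
    summary = {"n_records": len(records),
               "mean_lag_years": lag.mean_lag,
               "fraction_exceeding": {str(t): f for t, f
                                      in lag.fraction_exceeding.items()},
               "roles": {}}
    tally_rows = []
    for role in ROLES:
        tally = big_hitters(records, role)
        for person, c in tally.counts.items():
            tally_rows.append({"role": role, "person": person, "count": c,
                               "share": round(tally.share[person], 4)})
        summary["roles"][role] = {
            "n_persons": len(tally.counts),
            "n_events": tally.n_events,
            f"top_{top_k}_share": (round(top_k_share(tally, top_k), 4)
                                   if tally.counts else None),
            f"top_{top_k}": list(tally.counts)[:top_k],
        }
    pd.DataFrame(tally_rows, columns=["role", "person", "count", "share"]
                 ).to_csv(out / "collector_tallies.csv", index=False)

    with open(out / "metrics_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
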