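"""Decision rules classifying each tracked fish's fate.

Each track ends in one of three categories:

* **located** — the fish was followed to a spawning site: it stopped (no
  subsequent fix moved more than 1 km of chainage from the stop point) for
  strictly more than 2 days, entered a tributary, or was recaptured /
  its tag retrieved in a tributary;
* **censoring** — tracking ended before arrival: at least three fixes
  including the release point over at least two days and then lost,
  recapture in the main river, or scheduled/premature release of the tag
  package mid-migration;
* **not_located** — everything else: signal lost the day after release,
  the fish never left the release area, or the tag was recovered
  downstream of the release point.

Sub-outcomes mirror the tracking-summary table of the field study.  The
located/censored records feed right-censored time- and distance-to-event
samples; a carcass found upriver of the last fix replaces the censored
distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import math

import numpy as np
import pandas as pd

__all__ = [
    "FateRecord",
    "classify_fate",
    "classify_cohort",
    "summarize_fates",
    "censored_sample_from_fates",
]

LOCATED = "located"
CENSORING = "censoring"
NOT_LOCATED = "not_located"

_TRIBUTARY_ANNOTATIONS = {"tributary_entry", "recapture_tributary", "tag_retrieval_tributary"}
_DOWNSTREAM_ANNOTATIONS = {"recovered_downstream"}


@dataclass
class FateRecord:
    fish_id: str
    category: str
    subcategory: str
    last_chainage_km: float
    last_day: float            # days since release of the event/last fix
    month: str = ""
    carcass_chainage_km: float = math.nan
    natural_habitat: bool | None = None
    recaptured: bool = False

    def __post_init__(self):
        if self.last_day < 0:
            raise ValueError("last_day must be non-negative")
        if self.category not in (LOCATED, CENSORING, NOT_LOCATED):
            raise ValueError(f"unknown category {self.category!r}")


def classify_fate(
    track: pd.DataFrame,
    annotations: Iterable[Mapping] | None = None,
    stop_radius_km: float = 1.0,
    stop_days: float = 2.0,
    release_radius_km: float = 1.0,
) -> FateRecord:
    """Classify a single fish's track.

    ``track`` needs columns ``day`` (days since release, the release fix at
    day 0) and ``chainage_km``; optional ``fish_id`` and ``month`` columns
    are carried through.  ``annotations`` are mappings with at least a
    ``type`` key (tributary_entry, recapture_tributary,
    tag_retrieval_tributary, recapture_main, tag_release,
    recovered_downstream, carcass) and optionally ``day`` and
    ``chainage_km``.
    """
    if len(track) < 1:
        raise ValueError("track must contain at least one fix")
    track = track.sort_values("day")
    days = track["day"].to_numpy(float)
    chain = track["chainage_km"].to_numpy(float)
    fish_id = str(track["fish_id"].iloc[0]) if "fish_id" in track else ""
    month = str(track["month"].iloc[0]) if "month" in track else ""

    ann = [dict(a) for a in (annotations or [])]
    types = {a["type"] for a in ann}
    if types & _TRIBUTARY_ANNOTATIONS and types & _DOWNSTREAM_ANNOTATIONS:
        raise ValueError(
            f"{fish_id}: contradictory annotations (tributary outcome together "
            "with downstream tag recovery)"
        )

    carcass = next(
        (float(a.get("chainage_km", math.nan)) for a in ann if a["type"] == "carcass"),
        math.nan,
    )
    last_day = float(days[-1])
    last_chain = float(chain[-1])

    def record(category, subcategory, day=None, chainage=None):
        return FateRecord(
            fish_id=fish_id,
            category=category,
            subcategory=subcategory,
            last_chainage_km=last_chain if chainage is None else float(chainage),
            last_day=last_day if day is None else float(day),
            month=month,
            carcass_chainage_km=carcass,
            recaptured="recapture_tributary" in types or "recapture_main" in types,
        )

    # -- located -----------------------------------------------------------
    if "recapture_tributary" in types:
        return record(LOCATED, "Recaptured at tributary")
    if "tag_retrieval_tributary" in types:
        return record(LOCATED, "Tag retrieval at tributary")
    if "tributary_entry" in types:
        return record(LOCATED, "Arrival at spawning site")
    stop = _find_stop(days, chain, stop_radius_km, stop_days, release_radius_km)
    if stop is not None:
        stop_day, stop_chain = stop
        return record(LOCATED, "Arrival at spawning site", day=stop_day, chainage=stop_chain)

    # -- censoring -----------------------------------------------------------
    if "recapture_main" in types:
        return record(CENSORING, "Recaptured in the main river")
    if "tag_release" in types and last_chain > release_radius_km:
        return record(
            CENSORING,
            "Scheduled time-release of tag packages (tag retrieval in the main river)",
        )
    if len(days) >= 3 and last_day >= 2.0 and last_chain > release_radius_km:
        return record(CENSORING, "Loss of VHF signal after several days of tracking")

    # -- not located ---------------------------------------------------------
    if "recovered_downstream" in types:
        return record(NOT_LOCATED, "Tag retrieval downriver of release point")
    if np.all(chain <= release_radius_km) and last_day >= 2.0:
        return record(NOT_LOCATED, "Presumed dead soon after release")
    return record(NOT_LOCATED, "Loss of VHF signal on the next day after release")


def _find_stop(days, chain, radius_km, min_days, release_radius_km):
    """Earliest fix opening a terminal stationary segment: every fix from it
    onward stays within ``radius_km`` of the segment's median position, the
    segment spans strictly more than ``min_days``, and the stop lies upriver
    of the release area.  The median is the stop-position estimate, so a
    single noisy fix does not break the stationarity check."""
    for i in range(len(days)):
        seg = chain[i:]
        centre = float(np.median(seg))
        if centre <= release_radius_km:
            continue
        if np.all(np.abs(seg - centre) <= radius_km) and days[-1] - days[i] > min_days:
            return float(days[i]), centre
    return None


def classify_cohort(
    tracks: pd.DataFrame, annotations: Mapping[str, Iterable[Mapping]] | None = None
) -> list[FateRecord]:
    """Classify every fish in a projected-track table (grouped by fish_id)."""
    annotations = annotations or {}
    records = []
    for fish_id, sub in tracks.groupby("fish_id", sort=True):
        ann = list(annotations.get(fish_id, []))
        # tag_release may also travel inline in an 'annotation' column
        if "annotation" in sub:
            for _, row in sub[sub["annotation"].astype(str).str.len() > 0].iterrows():
                ann.append({"type": row["annotation"], "day": row["day"]})
        records.append(classify_fate(sub, ann))
    return records


class FateSummary(NamedTuple):
    counts: pd.DataFrame
    category_totals: pd.Series
    recapture_rate_percent: float
    natural_habitat_percent: float


def summarize_fates(
    records: list[FateRecord],
    cohort_meta: Mapping | None = None,
) -> FateSummary:
    """Cohort summary: per-category/subcategory/month counts and headline rates.

    ``cohort_meta`` may supply ``released_total`` (all marked fish,
    including any without electronic tags) and ``recaptured_total``; they
    default to the tracked records.  The recapture rate is printed to one
    decimal percent, the natural-habitat proportion (located fish settling
    outside hatchery-enhanced habitat) to the nearest integer percent.
    """
    if not records:
        raise ValueError("no fate records to summarise")
    meta = dict(cohort_meta or {})
    df = pd.DataFrame(
        {
            "category": [r.category for r in records],
            "subcategory": [r.subcategory for r in records],
            "month": [r.month for r in records],
        }
    )
    counts = (
        df.groupby(["category", "subcategory", "month"]).size().rename("n").reset_index()
    )
    category_totals = df.groupby("category").size()

    released = int(meta.get("released_total", len(records)))
    recaptured = int(meta.get("recaptured_total", sum(r.recaptured for r in records)))
    recapture_rate = round(100.0 * recaptured / released, 1) if released else math.nan

    located = [r for r in records if r.category == LOCATED]
    natural = [r for r in located if r.natural_habitat]
    flagged = [r for r in located if r.natural_habitat is not None]
    if located and flagged:
        natural_pct = float(round(100.0 * len(natural) / len(located)))
    else:
        natural_pct = math.nan
    return FateSummary(
        counts=counts,
        category_totals=category_totals,
        recapture_rate_percent=recapture_rate,
        natural_habitat_percent=natural_pct,
    )


def censored_sample_from_fates(records: list[FateRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Right-censored (time, distance) samples for product-limit analysis.

    Located fish contribute events at their stop day/chainage; censored
    fish contribute censored observations at the last fix, with a carcass
    found upriver of it replacing the censored distance.  Not-located fish
    carry no usable migration record and are excluded.
    """
    time_rows, dist_rows = [], []
    for r in records:
        if r.category == NOT_LOCATED:
            continue
        event = r.category == LOCATED
        if event and not np.isfinite(r.last_chainage_km):
            raise ValueError(f"{r.fish_id}: located record lacks an arrival chainage")
        distance = r.last_chainage_km
        if not event and np.isfinite(r.carcass_chainage_km):
            distance = max(distance, r.carcass_chainage_km)
        time_rows.append(
            {"fish_id": r.fish_id, "value": r.last_day, "event": event, "group": r.month}
        )
        dist_rows.append(
            {"fish_id": r.fish_id, "value": distance, "event": event, "group": r.month}
        )
    return pd.DataFrame(time_rows), pd.DataFrame(dist_rows)
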