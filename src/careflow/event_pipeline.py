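"""Cleaning and classification of per-patient care-event timelines.

The unit of analysis is the *event series*: the stretch of a patient's timeline
that starts at an *index event* (an event preceded by more than ``gap_days``
event-free days, and by at least ``gap_days`` days from the start of
observation) and ends at the next such event-free stretch, at death, or at the
end of observation.  Each series is labelled by the order of first occurrence
of the three care categories (E, NI, I), yielding one of 15 pathway types.

Two API levels are provided: per-timeline functions operating on lists of
:class:`RawEvent` (the contract definitions), and :func:`process_registry`,
which applies them to a whole registry table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .reference import (
    CATEGORY_RANK,
    DEATH,
    PROCEDURE_CATEGORY,
    SERIES_TYPES,
)

DEFAULT_GAP_DAYS = 180
#: per-procedure phantom-merge windows in days; SPECT defaults to 2 days to
#: collapse the two recording days of a two-day SPECT protocol into one event.
DEFAULT_MERGE_WINDOWS: Mapping[str, int] = {"SPECT": 2}

GAP = "gap"
DEATH_TERMINATED = "death"
END_OF_OBSERVATION = "end_of_observation"


class RawEvent(NamedTuple):
    patient_id: str
    day: int
    zip: str
    provider_id: str
    procedure: str
    death: int = 0


@dataclass
class EventSeries:
    """A gap-delimited care episode of one patient."""

    patient_id: str
    index_day: int
    events: list = field(default_factory=list)
    terminated_by: str = END_OF_OBSERVATION

    @property
    def last_day(self) -> int:
        return self.events[-1].day

    @property
    def care_events(self) -> list:
        return [e for e in self.events if not e.death]


def categorize_event(procedure: str) -> str:
    """Map a procedure code to its care category (E, NI or I)."""
    try:
        return PROCEDURE_CATEGORY[procedure]
    except KeyError:
        raise ValueError(f"unknown procedure code: {procedure!r}") from None


def _sort_key(event: RawEvent):
    # same-day ties: care events ordered E < NI < I then by code; a death
    # event sorts last on its day (it is the terminal record of the patient)
    if event.death:
        return (event.day, 99, "")
    return (event.day, CATEGORY_RANK[categorize_event(event.procedure)], event.procedure)


def sort_timeline(events: Iterable[RawEvent]) -> list:
    """Stable chronological ordering with the fixed same-day tie-break."""
    return sorted(events, key=_sort_key)


def merge_phantom_events(
    timeline: Sequence[RawEvent],
    merge_windows: Mapping[str, int] | None = None,
) -> list:
    """Collapse administrative duplicate ("phantom") events.

    Two same-procedure events of one patient separated by at most the
    procedure's window are collapsed into the earlier one, greedily from the
    left; an event absorbed into a kept event does not itself absorb later
    ones.
    """
    windows = DEFAULT_MERGE_WINDOWS if merge_windows is None else merge_windows
    for proc, w in windows.items():
        if w < 0:
            raise ValueError(f"negative merge window for {proc}: {w}")
    last_kept: dict = {}
    out = []
    for e in sort_timeline(timeline):
        if e.death:
            out.append(e)
            continue
        w = windows.get(e.procedure, 0)
        prev = last_kept.get(e.procedure)
        if prev is not None and e.day - prev <= w:
            continue
        last_kept[e.procedure] = e.day
        out.append(e)
    return out


def extract_event_series(
    timeline: Sequence[RawEvent],
    gap_days: int = DEFAULT_GAP_DAYS,
    observation_end: int | None = None,
) -> list:
    """Split a merged, sorted timeline into gap-delimited event series.

    An event opens a series iff no event of the patient fell in the preceding
    ``gap_days`` days and its day is at least ``gap_days`` (the event-free
    prefix must be observable).  Events before the first index event are
    discarded but still block later candidates.  Death events never open a
    series; a death inside an open series terminates it.
    """
    events = sort_timeline(timeline)
    if not events:
        return []
    max_day = max(e.day for e in events)
    if observation_end is None:
        observation_end = max_day
    if observation_end < max_day:
        raise ValueError(
            f"observation_end={observation_end} precedes last event day {max_day}"
        )
    series: list = []
    cur: EventSeries | None = None
    prev_day: int | None = None
    for e in events:
        if cur is not None and e.day - prev_day <= gap_days:
            cur.events.append(e)
            if e.death:
                cur.terminated_by = DEATH_TERMINATED
                series.append(cur)
                cur = None
        else:
            if cur is not None:
                cur.terminated_by = GAP
                series.append(cur)
                cur = None
            qualifies = (
                not e.death
                and e.day >= gap_days
                and (prev_day is None or e.day - prev_day > gap_days)
            )
            if qualifies:
                cur = EventSeries(e.patient_id, e.day, [e])
        prev_day = e.day
    if cur is not None:
        cur.terminated_by = END_OF_OBSERVATION
        series.append(cur)
    return series


def classify_series(series: EventSeries | Sequence[RawEvent]) -> str:
    """Pathway-type label: categories joined in order of first occurrence."""
    events = series.events if isinstance(series, EventSeries) else list(series)
    seen: list = []
    for e in events:
        if getattr(e, "death", 0):
            continue
        cat = categorize_event(e.procedure)
        if cat not in seen:
            seen.append(cat)
    if not seen:
        raise ValueError("cannot classify a series without care events")
    label = "-".join(seen)
    assert label in SERIES_TYPES
    return label


# --- registry-table level -------------------------------------------------

REGISTRY_COLUMNS = ["patient_id", "day", "zip", "provider_id", "procedure", "death"]


def process_registry(
    registry: pd.DataFrame,
    gap_days: int = DEFAULT_GAP_DAYS,
    observation_end: int | None = None,
    merge_windows: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge, extract and classify every patient's series in a registry table.

    Returns ``(series, membership)``:

    * ``series`` -- one row per event series: patient_id, series_idx,
      index_day, last_day, series_type, terminated_by, n_events, zip,
      death_day (the patient's death day, NaN if alive in observation);
    * ``membership`` -- one row per retained care event: the registry columns
      plus series_id (row index into ``series``).
    """
    if registry.empty:
        empty = pd.DataFrame(
            columns=["patient_id", "series_idx", "index_day", "last_day",
                     "series_type", "terminated_by", "n_events", "zip", "death_day"]
        )
        return empty, pd.DataFrame(columns=REGISTRY_COLUMNS + ["series_id"])
    if observation_end is None:
        observation_end = int(registry["day"].max())
    if int(registry["day"].max()) > observation_end:
        raise ValueError("observation_end precedes the last event day")

    windows = DEFAULT_MERGE_WINDOWS if merge_windows is None else merge_windows
    for proc, w in windows.items():
        if w < 0:
            raise ValueError(f"negative merge window for {proc}: {w}")

    df = registry.copy()
    is_death = df["death"].to_numpy() != 0
    rank = np.where(
        is_death, 99, df["procedure"].map(PROCEDURE_CATEGORY).map(CATEGORY_RANK)
    )
    unknown = df.loc[~is_death & pd.isna(df["procedure"].map(PROCEDURE_CATEGORY)), "procedure"]
    if len(unknown):
        raise ValueError(f"unknown procedure code: {unknown.iloc[0]!r}")
    df["_rank"] = rank
    df = df.sort_values(["patient_id", "day", "_rank", "procedure"], kind="stable")

    pid = df["patient_id"].to_numpy()
    day = df["day"].to_numpy()
    zips = df["zip"].to_numpy()
    proc = df["procedure"].to_numpy()
    death = df["death"].to_numpy() != 0
    starts = np.concatenate(([0], np.flatnonzero(pid[1:] != pid[:-1]) + 1, [len(df)]))
    cat = df["procedure"].map(PROCEDURE_CATEGORY).to_numpy()
    window_of = {p: int(windows.get(p, 0)) for p in set(proc)}

    rows = []
    member_idx: list = []
    member_sid: list = []
    for s0, s1 in zip(starts[:-1], starts[1:]):
        death_day = np.nan
        # phantom-merge: greedy left-to-right within (patient, procedure)
        last_kept: dict = {}
        kept = []
        for i in range(s0, s1):
            if death[i]:
                death_day = float(day[i])
                kept.append(i)
                continue
            prev = last_kept.get(proc[i])
            if prev is not None and day[i] - prev <= window_of[proc[i]]:
                continue
            last_kept[proc[i]] = day[i]
            kept.append(i)
        # gap-delimited series extraction + first-occurrence classification
        open_series = False
        prev_day = None
        cur: list = []
        seen: list = []

        def close(terminated_by, cur=None, seen=None):
            care = [i for i in cur if not death[i]]
            if not care:
                return
            sid = len(rows)
            rows.append(
                (pid[s0], None, int(day[care[0]]), int(day[cur[-1]]), "-".join(seen),
                 terminated_by, len(care), zips[care[0]], death_day)
            )
            member_idx.extend(care)
            member_sid.extend([sid] * len(care))

        for i in kept:
            if open_series and day[i] - prev_day <= gap_days:
                cur.append(i)
                if death[i]:
                    close(DEATH_TERMINATED, cur, seen)
                    open_series = False
                elif cat[i] not in seen:
                    seen.append(cat[i])
            else:
                if open_series:
                    close(GAP, cur, seen)
                    open_series = False
                if (
                    not death[i]
                    and day[i] >= gap_days
                    and (prev_day is None or day[i] - prev_day > gap_days)
                ):
                    open_series = True
                    cur = [i]
                    seen = [cat[i]]
            prev_day = day[i]
        if open_series:
            close(END_OF_OBSERVATION, cur, seen)

    series = pd.DataFrame(
        rows,
        columns=["patient_id", "series_idx", "index_day", "last_day",
                 "series_type", "terminated_by", "n_events", "zip", "death_day"],
    )
    if len(series):
        series["series_idx"] = series.groupby("patient_id").cumcount()
    membership = df.iloc[member_idx][REGISTRY_COLUMNS].reset_index(drop=True)
    membership["series_id"] = member_sid
    return series, membership


def write_series(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False)
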