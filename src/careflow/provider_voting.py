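"""Dominant de facto care-center assignment by majority vote.

Each ZIP area is served, per care level (primary = E, secondary = NI,
tertiary = I), by the provider that wins a majority vote in which every
resident patient with at least one event of that level casts one vote for the
provider of their chronologically first such event.  Ties are broken toward
the lexicographically smallest provider id so the assignment is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .reference import LEVEL_CATEGORY, PROCEDURE_CATEGORY

logger = logging.getLogger(__name__)


@dataclass
class CenterAssignment:
    level: str
    #: zip -> winning provider id
    zip_center: dict = field(default_factory=dict)
    #: zip -> (votes for winner, total votes)
    vote_counts: dict = field(default_factory=dict)

    @property
    def centers(self) -> set:
        return set(self.zip_center.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (z, self.level, c, self.vote_counts[z][0], self.vote_counts[z][1])
            for z, c in sorted(self.zip_center.items())
        ]
        return pd.DataFrame(
            rows, columns=["zip", "level", "center_id", "votes_for_winner", "total_votes"]
        )


def aggregate_departments(provider_id: str, institution_map: Mapping[str, str] | None) -> str:
    """Map a department-level provider id to its institution (identity default)."""
    if institution_map is None:
        return provider_id
    return institution_map.get(provider_id, provider_id)


def assign_dominant_centers(
    registry: pd.DataFrame,
    level: str = "primary",
    institution_map: Mapping[str, str] | None = None,
) -> CenterAssignment:
    """Vote the dominant provider of each ZIP area at one care level.

    A patient's ZIP is taken from their first event (patients do not move).
    ZIP areas without any voter at this level are omitted (logged).
    """
    category = LEVEL_CATEGORY[level]
    df = registry.copy()
    df = df[df["death"] == 0]
    df["category"] = df["procedure"].map(PROCEDURE_CATEGORY)
    if institution_map is not None:
        df["provider_id"] = df["provider_id"].map(
            lambda p: aggregate_departments(p, institution_map)
        )

    # residential zip: the zip of each patient's chronologically first event
    order = df.sort_values(["day", "procedure"], kind="stable")
    patient_zip = order.groupby("patient_id", sort=False)["zip"].first()

    votes = order[order["category"] == category].groupby("patient_id", sort=False)[
        "provider_id"
    ].first()

    assignment = CenterAssignment(level=level)
    tally = pd.DataFrame({"zip": patient_zip.reindex(votes.index), "provider": votes})
    for zid, grp in tally.groupby("zip", sort=True):
        counts = grp["provider"].value_counts()
        top = counts.max()
        # tie-break: smallest provider id among the leaders
        winner = min(counts[counts == top].index)
        assignment.zip_center[zid] = winner
        assignment.vote_counts[zid] = (int(top), int(len(grp)))
    voters_zips = set(assignment.zip_center)
    silent = sorted(set(registry["zip"].unique()) - voters_zips)
    if silent:
        logger.info("%d ZIP area(s) had no %s-level voters: %s",
                    len(silent), level, silent[:10])
    return assignment


def attribute_series_to_centers(
    series: pd.DataFrame, assignment: CenterAssignment
) -> pd.DataFrame:
    """Attach the ZIP's dominant center to each event series.

    Spectra characterize the population served by a center, so series are
    attributed to the dominant center of the patient's ZIP, not to the
    provider that performed the events.  Series from ZIPs with no assigned
    center are dropped (logged).
    """
    out = series.copy()
    out["center_id"] = out["zip"].map(assignment.zip_center)
    dropped = out["center_id"].isna()
    if dropped.any():
        logger.info("dropping %d series from unassigned ZIPs", int(dropped.sum()))
    return out[~dropped].reset_index(drop=True)
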