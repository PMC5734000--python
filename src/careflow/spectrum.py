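"""Center pathway spectra and outcome statistics.

A center's *spectrum* is its relative-frequency vector over the 15 pathway
types (canonical order), the feature vector later correlated between centers.
Outcome statistics per scope (center, cluster, whole population) are the
revascularization rate, the 365-day mortality after the index event, and the
average reimbursement cost of an event series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reference import (
    CA,
    REVASCULARIZATION_PROCEDURES,
    SERIES_TYPES,
    TARIFF_EUR,
    TARIFF_HUF,
)

logger = logging.getLogger(__name__)

REVASC_WINDOW_DAYS = 180
MORTALITY_WINDOW_DAYS = 365


@dataclass
class TariffTable:
    """Per-procedure reimbursement costs (HUF, with an optional EUR column)."""

    huf: Mapping[str, float]
    eur: Mapping[str, float] | None = None

    @classmethod
    def default(cls) -> "TariffTable":
        return cls(huf=dict(TARIFF_HUF), eur=dict(TARIFF_EUR))

    @classmethod
    def from_csv(cls, path) -> "TariffTable":
        df = pd.read_csv(path)
        eur = dict(zip(df["procedure"], df["eur"])) if "eur" in df.columns else None
        return cls(huf=dict(zip(df["procedure"], df["huf"])), eur=eur)

    def validate(self) -> None:
        for proc, cost in self.huf.items():
            if cost <= 0:
                raise ValueError(f"non-positive tariff for {proc}: {cost}")

    def cost_of(self, procedure: str) -> float:
        try:
            return float(self.huf[procedure])
        except KeyError:
            raise ValueError(f"no tariff entry for procedure {procedure!r}") from None


def series_cost(procedures: Iterable[str], tariff: TariffTable) -> float:
    """Total reimbursement cost of one series' care events (death costs 0)."""
    return sum(tariff.cost_of(p) for p in procedures if p != "DEATH")


def series_costs(membership: pd.DataFrame, tariff: TariffTable | None = None) -> pd.Series:
    """Cost per series_id, summed over the series' (post-merge) events."""
    tariff = tariff or TariffTable.default()
    known = set(tariff.huf)
    unknown = set(membership["procedure"].unique()) - known - {"DEATH"}
    if unknown:
        raise ValueError(f"no tariff entry for procedure(s) {sorted(unknown)}")
    costs = membership["procedure"].map(tariff.huf).fillna(0.0)
    return costs.groupby(membership["series_id"]).sum()


@dataclass
class CenterSpectrum:
    center_id: str
    counts: np.ndarray  # 15-vector, canonical type order
    n_series: int

    @property
    def ratios(self) -> np.ndarray:
        if self.n_series == 0:
            return np.zeros(len(SERIES_TYPES))
        return self.counts / self.n_series

    @property
    def empty(self) -> bool:
        return self.n_series == 0


def compute_spectrum(series_types: Iterable[str], center_id: str = "") -> CenterSpectrum:
    """Count pathway types into the canonical 15-vector."""
    counts = np.zeros(len(SERIES_TYPES))
    index = {t: i for i, t in enumerate(SERIES_TYPES)}
    n = 0
    for label in series_types:
        counts[index[label]] += 1
        n += 1
    if n == 0:
        logger.info("center %s has no series; excluded from the network", center_id)
    return CenterSpectrum(center_id=center_id, counts=counts, n_series=n)


def spectra_table(series_with_center: pd.DataFrame) -> pd.DataFrame:
    """Per-center spectra: one row per center, counts pivoted to the canonical
    order, plus ``n_series``.  Ratio columns carry the type names."""
    pivot = (
        series_with_center.pivot_table(
            index="center_id", columns="series_type", aggfunc="size", fill_value=0
        )
        .reindex(columns=list(SERIES_TYPES), fill_value=0)
        .sort_index()
    )
    n = pivot.sum(axis=1)
    ratios = pivot.div(n, axis=0)
    ratios["n_series"] = n
    return ratios


def revascularization_rate(
    series: pd.DataFrame,
    events: pd.DataFrame,
    window_days: int = REVASC_WINDOW_DAYS,
) -> tuple[float, int, int]:
    """Share of CA-containing series followed by PCI/CABG within the window.

    The follow-up may fall in a later series of the same patient (the linkage
    is by patient, not by series).  Returns ``(rate, numerator, denominator)``;
    with no CA anywhere the rate is NaN (undefined), not 0.
    """
    ca = events[events["procedure"] == CA][["patient_id", "day", "series_id"]]
    denominator_series = ca["series_id"].unique()
    if len(denominator_series) == 0:
        return float("nan"), 0, 0
    rv = events[events["procedure"].isin(REVASCULARIZATION_PROCEDURES)][
        ["patient_id", "day"]
    ].rename(columns={"day": "rv_day"})
    linked = ca.merge(rv, on="patient_id", how="inner")
    hit = linked[
        (linked["rv_day"] >= linked["day"])
        & (linked["rv_day"] - linked["day"] <= window_days)
    ]
    numerator_series = hit["series_id"].unique()
    keep = set(series.index) if series.index.size else set()
    num = sum(1 for s in numerator_series if s in keep)
    den = sum(1 for s in denominator_series if s in keep)
    if den == 0:
        return float("nan"), 0, 0
    return num / den, num, den


def mortality_365(series: pd.DataFrame, window_days: int = MORTALITY_WINDOW_DAYS) -> tuple[float, int, int]:
    """Share of series whose patient dies within the window after the index
    event.  Returns ``(rate, deaths, n_series)``."""
    n = len(series)
    if n == 0:
        return float("nan"), 0, 0
    died = (
        series["death_day"].notna()
        & (series["death_day"] - series["index_day"] <= window_days)
    )
    return float(died.mean()), int(died.sum()), n


def direct_standardize(
    stratum_rates: Mapping, stratum_weights: Mapping
) -> float:
    """Directly standardized rate: sum of stratum rates weighted by a fixed
    reference distribution over the same strata."""
    total = sum(stratum_weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"reference weights sum to {total}, expected 1")
    missing = [s for s in stratum_weights if s not in stratum_rates]
    if missing:
        raise ValueError(f"missing stratum rate(s) for strata: {missing}")
    return float(sum(stratum_weights[s] * stratum_rates[s] for s in stratum_weights))


@dataclass
class OutcomeSummary:
    scope: str
    revasc_rate: float
    mort365: float
    avg_cost: float
    n_series: int


def outcome_summary(
    series: pd.DataFrame,
    membership: pd.DataFrame,
    tariff: TariffTable | None = None,
    scope: str = "population",
) -> OutcomeSummary:
    """Pooled outcomes for one scope (the rows of a cluster summary table).

    ``series`` is the scope's subset (indexed by series_id); ``membership``
    must be the *full* event table so that revascularization follow-ups that
    fall in a later series of the same patient are still found.
    """
    tariff = tariff or TariffTable.default()
    costs = series_costs(membership, tariff)
    in_scope = costs.reindex(series.index)
    rate, _, _ = revascularization_rate(series, membership)
    mort, _, _ = mortality_365(series)
    return OutcomeSummary(
        scope=scope,
        revasc_rate=rate,
        mort365=mort,
        avg_cost=float(in_scope.mean()) if len(series) else float("nan"),
        n_series=len(series),
    )
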