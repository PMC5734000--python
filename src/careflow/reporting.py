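"""Cluster characterization tables and the machine-readable analysis report.

Produces the two summary products of the pipeline: a per-cluster
characterization (pathway-type percentages pooled over member centers' series
counts, revascularization rate, 365-day mortality, average series cost, and
the intra-cluster average correlation) with a pooled whole-population column,
and the pairwise percent-difference table with two-sided Fisher exact
p-values on the underlying 2x2 counts (cost rows carry no test).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network_clustering import Partition, cluster_correlation_summary
from .reference import SERIES_TYPES
from .spectrum import (
    TariffTable,
    mortality_365,
    revascularization_rate,
    series_costs,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


def percent_difference(a: float, b: float) -> float:
    """Relative difference of two rates as a percent of the reference b:
    ``100 (a − b) / b``.  Undefined (NaN, logged) when b is 0."""
    if b == 0:
        logger.info("percent difference undefined against a zero reference")
        return float("nan")
    return 100.0 * (a - b) / b


def exact_test(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p-value on [[count_a, n_a−count_a],
    [count_b, n_b−count_b]]."""
    if count_a > n_a or count_b > n_b:
        raise ValueError("counts exceed totals")
    table = [[count_a, n_a - count_a], [count_b, n_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pooled_from_cluster_columns(cluster_values: dict, cluster_n: dict) -> float:
    """The n-weighted mean that pools per-cluster rates (or costs) into the
    whole-population value: Σ n_k v_k / Σ n_k."""
    total = sum(cluster_n.values())
    return sum(cluster_n[k] * cluster_values[k] for k in cluster_values) / total


@dataclass
class ClusterSummary:
    """Per-cluster characterization plus the pooled whole-population column.

    ``clusters[c]`` and ``whole`` map feature names ("<type>_pct",
    "revasc_rate_pct", "mort365_pct", "avg_cost_huf", "n_series",
    "intra_cluster_corr", and the underlying counts) to values.
    """

    clusters: dict = field(default_factory=dict)
    whole: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"cluster_{c}": vals for c, vals in sorted(self.clusters.items())}
        cols["whole_population"] = self.whole
        return pd.DataFrame(cols)


def _scope_stats(sub: pd.DataFrame, membership: pd.DataFrame, costs: pd.Series) -> dict:
    n = len(sub)
    out: dict = {"n_series": n}
    counts = sub["series_type"].value_counts()
    for t in SERIES_TYPES:
        c = int(counts.get(t, 0))
        out[f"{t}_count"] = c
        out[f"{t}_pct"] = 100.0 * c / n
    rate, num, den = revascularization_rate(sub, membership)
    out["revasc_rate_pct"] = 100.0 * rate if rate == rate else float("nan")
    out["revasc_num"], out["revasc_den"] = num, den
    mort, deaths, _ = mortality_365(sub)
    out["mort365_pct"] = 100.0 * mort
    out["mort365_deaths"] = deaths
    out["avg_cost_huf"] = float(costs.reindex(sub.index).mean())
    return out


def summarize_clusters(
    series_with_center: pd.DataFrame,
    partition: Partition,
    membership: pd.DataFrame,
    tariff: TariffTable | None = None,
    corr=None,
) -> ClusterSummary:
    """Pool member centers' series into per-cluster characterizations.

    Percentages are series-count-weighted pools of the member centers' counts,
    not unweighted means of their ratio vectors, so the whole-population
    column is exactly the n-weighted mean of the cluster columns.
    """
    tariff = tariff or TariffTable.default()
    costs = series_costs(membership, tariff)
    cluster_of = partition.assignment
    df = series_with_center.copy()
    df["cluster"] = df["center_id"].map(cluster_of)
    if df["cluster"].isna().any():
        missing = sorted(df.loc[df["cluster"].isna(), "center_id"].unique())
        raise ValueError(f"centers not covered by the partition: {missing}")

    summary = ClusterSummary()
    for c in sorted(set(cluster_of.values())):
        sub = df[df["cluster"] == c]
        if sub.empty:
            raise ValueError(f"cluster {c} has no series")
        summary.clusters[int(c)] = _scope_stats(sub, membership, costs)
    summary.whole = _scope_stats(df, membership, costs)

    if corr is not None:
        intra, _ = cluster_correlation_summary(corr, partition)
        for c, v in intra.items():
            if c in summary.clusters:
                summary.clusters[c]["intra_cluster_corr"] = v
        summary.whole["intra_cluster_corr"] = float("nan")
    return summary


#: features of the pairwise table; cost rows are printed without a p-value
PAIRWISE_FEATURES = [f"{t}_pct" for t in SERIES_TYPES] + [
    "revasc_rate_pct",
    "mort365_pct",
    "avg_cost_huf",
]


def pairwise_comparisons(summary: ClusterSummary) -> pd.DataFrame:
    """Percent differences of cluster features for every cluster pair, with
    two-sided Fisher exact tests reconstructed from the pooled 2x2 counts
    (pathway type vs all other series; revascularized vs not among CA series;
    died vs survived)."""
    rows = []
    ids = sorted(summary.clusters)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ca, cb = summary.clusters[a], summary.clusters[b]
            for feat in PAIRWISE_FEATURES:
                pdiff = percent_difference(ca[feat], cb[feat])
                if feat == "avg_cost_huf":
                    p = float("nan")
                elif feat == "revasc_rate_pct":
                    p = exact_test(ca["revasc_num"], ca["revasc_den"],
                                   cb["revasc_num"], cb["revasc_den"])
                elif feat == "mort365_pct":
                    p = exact_test(ca["mort365_deaths"], ca["n_series"],
                                   cb["mort365_deaths"], cb["n_series"])
                else:
                    t = feat[:-4]
                    p = exact_test(ca[f"{t}_count"], ca["n_series"],
                                   cb[f"{t}_count"], cb["n_series"])
                rows.append((feat, a, b, pdiff, p))
    return pd.DataFrame(
        rows, columns=["feature", "cluster_a", "cluster_b", "percent_difference", "p_value"]
    )


REQUIRED_STAGES = ("config", "summary", "pairwise", "partition", "correlation_summary")


def write_report(path, **stages) -> dict:
    """Assemble and write the versioned JSON analysis report.

    Expected stage keyword arguments: ``config`` (echo of the run
    configuration incl. seed), ``summary`` (:class:`ClusterSummary`),
    ``pairwise`` (DataFrame), ``partition`` (dict with per-level assignments
    and Q), ``correlation_summary`` (intra/inter averages), and optionally
    ``centrality_percentiles``.  Raises if a required stage is missing.
    """
    missing = [s for s in REQUIRED_STAGES if s not in stages or stages[s] is None]
    if missing:
        raise ValueError(f"cannot write report; missing pipeline stage(s): {missing}")

    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, pd.DataFrame):
            return clean(obj.to_dict(orient="records"))
        if isinstance(obj, ClusterSummary):
            return clean({"clusters": obj.clusters, "whole_population": obj.whole})
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating, float)):
            v = float(obj)
            return None if v != v else v
        return obj

    report = {"schema_version": REPORT_SCHEMA_VERSION}
    for name, value in sorted(stages.items()):
        report[name] = clean(value)
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
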