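"""End-to-end orchestration: registry -> series -> spectra -> network ->
clusters -> characterization.  Used by the analysis scripts, the CLI and the
acceptance machinery; every step delegates to the stage modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import network_clustering as netmod
from .event_pipeline import DEFAULT_GAP_DAYS, process_registry
from .provider_voting import assign_dominant_centers, attribute_series_to_centers
from .reporting import pairwise_comparisons, summarize_clusters, write_report
from .spectrum import TariffTable, spectra_table
from .synthetic_registry import SimulationConfig, generate_registry


@dataclass
class PipelineResult:
    registry: pd.DataFrame
    truth: object
    series: pd.DataFrame
    membership: pd.DataFrame
    assignment: object
    spectra: pd.DataFrame
    corr: netmod.CorrelationMatrix
    network: netmod.WeightedNetwork
    partitions: list  # levels 1..3
    intra: dict
    inter: dict
    summary: object
    pairwise: pd.DataFrame
    centrality: netmod.CentralityReport
    params: dict = field(default_factory=dict)

    @property
    def partition(self) -> netmod.Partition:
        return self.partitions[0]

    def report(self, path=None) -> dict:
        levels = {
            f"level{p.level}": {str(k): int(v) for k, v in sorted(p.assignment.items())}
            for p in self.partitions
        }
        percentiles = {
            scope: df[["node", "degree_percentile", "betweenness_percentile"]]
            for scope, df in self.centrality.scopes.items()
        }
        return write_report(
            path,
            config=self.params,
            summary=self.summary,
            pairwise=self.pairwise,
            partition={"q": self.partition.q, "assignments": levels},
            correlation_summary={
                "intra": self.intra,
                "inter": {f"{a}-{b}": v for (a, b), v in self.inter.items()},
            },
            centrality_percentiles=percentiles,
        )


def run_pipeline(
    registry: pd.DataFrame | None = None,
    truth=None,
    config: SimulationConfig | None = None,
    gap_days: int = DEFAULT_GAP_DAYS,
    profile_transform: str = netmod.DEFAULT_PROFILE_TRANSFORM,
    transform_offset: float = netmod.DEFAULT_OFFSET,
    weight_transform=None,
    n_random_starts: int = netmod.DEFAULT_RANDOM_STARTS,
    n_iterations: int = netmod.DEFAULT_ITERATIONS,
    max_depth: int = 3,
    seed: int = 0,
    tariff: TariffTable | None = None,
) -> PipelineResult:
    """Run the whole analysis on a registry table (generated if not given)."""
    if registry is None:
        config = config or SimulationConfig(seed=seed)
        registry, truth = generate_registry(config)
    tariff = tariff or TariffTable.default()

    series, membership = process_registry(registry, gap_days=gap_days)
    assignment = assign_dominant_centers(registry, level="primary")
    series_c = attribute_series_to_centers(series, assignment)
    spectra = spectra_table(series_c)
    spectra = spectra[spectra["n_series"] > 0]

    corr = netmod.correlation_matrix(spectra, transform=profile_transform)
    network = netmod.build_network(corr, transform_offset, weight_transform)
    part = netmod.louvain_cluster(network, n_random_starts, n_iterations, seed=seed)
    partitions = netmod.hierarchical_cluster(
        network, part, max_depth, n_random_starts, n_iterations, seed=seed
    )
    intra, inter = netmod.cluster_correlation_summary(corr, part)
    summary = summarize_clusters(series_c, part, membership, tariff, corr=corr)
    pairwise = pairwise_comparisons(summary)
    centrality = netmod.centralities(network, part)

    params = {
        "seed": seed,
        "gap_days": gap_days,
        "profile_transform": profile_transform,
        "transform_offset": transform_offset,
        "n_random_starts": n_random_starts,
        "n_iterations": n_iterations,
        "max_depth": max_depth,
        "n_centers": len(corr.ids),
        "n_series": int(len(series_c)),
    }
    return PipelineResult(
        registry=registry, truth=truth, series=series_c, membership=membership,
        assignment=assignment, spectra=spectra, corr=corr, network=network,
        partitions=partitions, intra=intra, inter=inter, summary=summary,
        pairwise=pairwise, centrality=centrality, params=params,
    )
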