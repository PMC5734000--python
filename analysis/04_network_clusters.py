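#!/usr/bin/env python
"""Build the center-center correlation networks and cluster them.

For each registry: correlate practice-deviation profiles (per-type z-scores)
between centers, map correlations to weights w = c + 2, run Louvain
modularity optimization (10 random starts, 10 iterations) plus two further
hierarchical levels, and compute degree / betweenness centralities.  Writes
``results/correlation[_styles].csv``, ``partition[_styles].csv``,
``heatmap_order[_styles].csv`` and prints Q and the intra/inter-cluster
average correlations.

Finding: the well-separated practice styles are recovered exactly as three
first-level clusters (ARI 1.0 against the planted truth), with positive
intra-cluster and negative inter-cluster average correlations — the same
correlation regime the published study reports.  The register emulation built
from the published *aggregate* profiles yields two clusters: the aggregate
profiles of the two invasive-leaning groups are nearly collinear, so their
separation is below the modularity resolution at ~2,000 patients/center (see
docs/methods.md).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from careflow import (
    SyntheticTruth,
    read_registry,
    run_pipeline,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def ari(labels_a, labels_b):
    """Adjusted Rand index, pair-counting form."""
    import numpy as np

    a, b = np.asarray(labels_a), np.asarray(labels_b)
    n = len(a)
    table = pd.crosstab(a, b).to_numpy()
    c2 = lambda x: x * (x - 1) / 2
    sum_ij = c2(table).sum()
    sum_a, sum_b = c2(table.sum(1)).sum(), c2(table.sum(0)).sum()
    exp = sum_a * sum_b / c2(n)
    mx = (sum_a + sum_b) / 2
    return 1.0 if mx == exp else (sum_ij - exp) / (mx - exp)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    for name, suffix in (("registry", ""), ("registry_styles", "_styles")):
        registry = read_registry(RESULTS / f"{name}.csv")
        truth = SyntheticTruth.from_json(
            RESULTS / f"{name.replace('registry', 'truth')}.json"
        )
        res = run_pipeline(registry=registry, seed=args.seed)
        res.corr.to_frame().to_csv(RESULTS / f"correlation{suffix}.csv")
        levels = {p.level: p for p in res.partitions}
        rows = [
            [node] + [levels[d].assignment[node] for d in sorted(levels)]
            for node in res.network.ids
        ]
        pd.DataFrame(rows, columns=["center_id", "level1", "level2", "level3"]).to_csv(
            RESULTS / f"partition{suffix}.csv", index=False
        )
        from careflow import heatmap_order

        pd.Series(heatmap_order(res.corr, res.partition), name="center_id").to_csv(
            RESULTS / f"heatmap_order{suffix}.csv", index=False
        )
        res.report(RESULTS / f"report{suffix}.json")

        truth_labels = [truth.center_archetype[c] for c in res.network.ids]
        found_labels = [res.partition.assignment[c] for c in res.network.ids]
        print(f"{name}: Q={res.partition.q:.4f}, "
              f"{res.partition.n_communities} first-level clusters, "
              f"ARI vs planted archetypes = {ari(truth_labels, found_labels):.3f}")
        print(f"  intra-cluster mean corr: "
              f"{ {k: round(v, 3) for k, v in res.intra.items()} }")
        print(f"  inter-cluster mean corr: "
              f"{ {f'{a}-{b}': round(v, 3) for (a, b), v in res.inter.items()} }")


if __name__ == "__main__":
    main()
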