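"""Center-center correlation network, modularity and Louvain clustering.

Centers are compared by Pearson correlation of their pathway spectra.  Raw
pathway shares carry a dominant common component (the single-stress-test share
is ~3/4 everywhere), under which the plain correlation of two centers is close
to +1 regardless of practice style; the default profile transform therefore
standardizes each pathway type across centers (z-score) so the correlation
measures similarity of *practice deviations*.  The raw, mean-centered and
arcsine-sqrt (variance-stabilized) variants are available as options.

Correlations are mapped to strictly positive edge weights, ``w_ij = c_ij +
offset`` (offset 2 by default), and the complete weighted graph is clustered
by native modularity optimization (Louvain: greedy local moves plus community
aggregation, with seeded random restarts), then re-clustered hierarchically
inside each community.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .reference import SERIES_TYPES

logger = logging.getLogger(__name__)

PROFILE_TRANSFORMS = ("raw", "center", "zscore", "arcsine")
DEFAULT_PROFILE_TRANSFORM = "zscore"
DEFAULT_OFFSET = 2.0
DEFAULT_RANDOM_STARTS = 10
DEFAULT_ITERATIONS = 10

_MOVE_TOL = 1e-12


# --- correlation ----------------------------------------------------------


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson's r via the raw-sums formula.

    ``r = (n Σxy − Σx Σy) / (sqrt(n Σx² − (Σx)²) sqrt(n Σy² − (Σy)²))``.
    Constant vectors have no defined correlation and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    sx, sy = x.sum(), y.sum()
    vx = n * (x * x).sum() - sx * sx
    vy = n * (y * y).sum() - sy * sy
    if vx <= 0 or vy <= 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((n * (x * y).sum() - sx * sy) / (math.sqrt(vx) * math.sqrt(vy)))


@dataclass
class CorrelationMatrix:
    ids: list
    c: np.ndarray  # symmetric, diagonal 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.c, index=self.ids, columns=self.ids)


def transform_profiles(ratios: np.ndarray, transform: str = DEFAULT_PROFILE_TRANSFORM) -> np.ndarray:
    """Map center spectra (rows) to the profile space that is correlated."""
    X = np.asarray(ratios, dtype=float)
    if transform == "raw":
        return X
    if transform == "center":
        return X - X.mean(axis=0)
    if transform == "zscore":
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [SERIES_TYPES[i] for i in np.flatnonzero(~keep) if i < len(SERIES_TYPES)]
            logger.info("dropping zero-variance pathway type(s) from profiles: %s", dropped)
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        return Z
    if transform == "arcsine":
        T = np.arcsin(np.sqrt(np.clip(X, 0.0, 1.0)))
        return T - T.mean(axis=0)
    raise ValueError(f"unknown profile transform {transform!r}; use one of {PROFILE_TRANSFORMS}")


def correlation_matrix(
    spectra: pd.DataFrame,
    transform: str = DEFAULT_PROFILE_TRANSFORM,
) -> CorrelationMatrix:
    """Pearson correlation matrix of center profiles.

    ``spectra`` is the per-center ratio table (one row per center, the 15
    canonical ratio columns; an ``n_series`` column is ignored).  Centers with
    a constant profile (undefined correlation) are excluded with a log line.
    """
    ratio_cols = [t for t in SERIES_TYPES if t in spectra.columns]
    X = spectra[ratio_cols].to_numpy(dtype=float)
    ids = list(spectra.index)
    P = transform_profiles(X, transform)
    sd = P.std(axis=1)
    keep = sd > 0
    if not keep.all():
        excluded = [ids[i] for i in np.flatnonzero(~keep)]
        logger.info("excluding constant-profile center(s): %s", excluded)
        P, ids = P[keep], [i for i, k in zip(ids, keep) if k]
    C = np.corrcoef(P)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(ids=ids, c=C)


def correlation_confidence(
    corr: CorrelationMatrix, n_obs: int = len(SERIES_TYPES), level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z confidence bounds for each coefficient (recorded, not used to
    prune edges: the network keeps every edge)."""
    from scipy import stats

    z = np.arctanh(np.clip(corr.c, -0.999999, 0.999999))
    se = 1.0 / math.sqrt(max(n_obs - 3, 1))
    q = stats.norm.ppf(0.5 + level / 2.0)
    return np.tanh(z - q * se), np.tanh(z + q * se)


# --- weighted network -----------------------------------------------------


@dataclass
class WeightedNetwork:
    ids: list
    w: np.ndarray  # symmetric, zero diagonal, strictly positive off-diagonal

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.ids)
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.w[i, j] != 0:  # zero means no edge
                    G.add_edge(self.ids[i], self.ids[j], weight=float(self.w[i, j]))
        return G

    def edge_list(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.w[i, j] != 0:
                    rows.append((self.ids[i], self.ids[j], self.w[i, j]))
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


def build_network(
    corr: CorrelationMatrix,
    transform_offset: float = DEFAULT_OFFSET,
    weight_transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> WeightedNetwork:
    """Complete graph with ``w_ij = f(c_ij + offset)`` (f identity by default).

    No correlation cutoff is applied.  The offset must exceed 1 so that even a
    perfect negative correlation maps to a positive weight.
    """
    if transform_offset <= 1.0:
        raise ValueError("transform_offset must be > 1 so all weights stay positive")
    if len(corr.ids) < 2:
        raise ValueError("need at least 2 centers to build a network")
    w = corr.c + transform_offset
    if weight_transform is not None:
        w = np.asarray(weight_transform(w), dtype=float)
    if (w[~np.eye(len(w), dtype=bool)] <= 0).any():
        raise ValueError("weight transform produced non-positive edge weights")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(ids=list(corr.ids), w=w)


# --- modularity and Louvain ----------------------------------------------


@dataclass
class Partition:
    """A community assignment with its modularity Q and hierarchy level."""

    assignment: dict
    q: float
    level: int = 1

    def labels_for(self, ids: Sequence) -> np.ndarray:
        return np.asarray([self.assignment[i] for i in ids], dtype=int)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> dict:
        out: dict = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return out


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities contiguously from 0 in order of first appearance."""
    mapping: dict = {}
    out = np.empty_like(labels)
    for i, c in enumerate(labels):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    return out


def modularity(network: WeightedNetwork, partition: Partition | np.ndarray) -> float:
    """Newman-Girvan modularity of a partition on the weighted graph.

    Computed community-wise as ``Σ_c [Σin_c/2m − (Σtot_c/2m)²]`` which is
    algebraically identical to the double-sum definition and evaluates to 0
    exactly (not merely approximately) for the all-in-one partition.
    """
    labels = (
        partition.labels_for(network.ids)
        if isinstance(partition, Partition)
        else np.asarray(partition, dtype=int)
    )
    W = network.w
    k = W.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        sin = W[np.ix_(idx, idx)].sum(axis=1).sum()
        stot = k[idx].sum()
        q += sin / two_m - (stot / two_m) ** 2
    return float(q)


def _local_move_pass(B: np.ndarray, comm: np.ndarray, k: np.ndarray, two_m: float,
                     sigma_tot: np.ndarray, order: np.ndarray) -> bool:
    """One sweep of greedy node moves; mutates comm/sigma_tot in place."""
    moved = False
    for u in order:
        a = comm[u]
        sigma_tot[a] -= k[u]
        wu = B[u].copy()
        wu[u] = 0.0
        k_uc = np.bincount(comm, weights=wu, minlength=len(sigma_tot))
        gains = k_uc - sigma_tot * (k[u] / two_m)
        best = int(np.argmax(gains))  # first max = smallest community id
        if gains[best] > gains[a] + _MOVE_TOL and best != a:
            comm[u] = best
            sigma_tot[best] += k[u]
            moved = True
        else:
            comm[u] = a
            sigma_tot[a] += k[u]
    return moved


def _louvain_single(W: np.ndarray, rng: np.random.Generator, n_iterations: int) -> np.ndarray:
    """One seeded Louvain run: local moving (capped passes) + aggregation,
    repeated until aggregation no longer changes anything."""
    n = len(W)
    node_comm = np.arange(n)  # original node -> current flat community
    B = W.copy()
    while True:
        m = len(B)
        comm = np.arange(m)
        k = B.sum(axis=1)
        two_m = k.sum()
        if two_m <= 0:
            break
        sigma_tot = k.copy()
        any_move = False
        for _ in range(n_iterations):
            order = rng.permutation(m)
            if not _local_move_pass(B, comm, k, two_m, sigma_tot, order):
                break
            any_move = True
        if not any_move:
            break
        comm = _canonical_labels(comm)
        n_comm = comm.max() + 1
        if n_comm == m:
            break
        # aggregate: communities become super-nodes; internal weight (both
        # directions) lands on the diagonal and keeps degrees consistent
        M = np.zeros((m, n_comm))
        M[np.arange(m), comm] = 1.0
        B = M.T @ B @ M
        node_comm = comm[node_comm]
    return _canonical_labels(node_comm)


def louvain_cluster(
    network: WeightedNetwork,
    n_random_starts: int = DEFAULT_RANDOM_STARTS,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    level: int = 1,
) -> Partition:
    """Best-of-``n_random_starts`` greedy modularity optimization.

    Restart r uses seed ``seed + r`` and a fresh node visit order; the
    highest-Q final partition is returned (first winner on exact ties).
    """
    W = network.w
    off_diag = W[~np.eye(len(W), dtype=bool)]
    if len(off_diag) and off_diag.min() < 0:
        raise ValueError("Louvain requires positive edge weights; apply the offset transform")
    if len(W) > 1 and nx.number_connected_components(nx.from_numpy_array(W)) > 1:
        raise ValueError("Louvain requires a connected graph")
    best_labels, best_q = None, -np.inf
    for r in range(n_random_starts):
        rng = np.random.default_rng(seed + r)
        labels = _louvain_single(W, rng, n_iterations)
        q = modularity(network, labels)
        if q > best_q:
            best_labels, best_q = labels, q
    assignment = {node: int(c) for node, c in zip(network.ids, best_labels)}
    return Partition(assignment=assignment, q=best_q, level=level)


def subnetwork(network: WeightedNetwork, nodes: Sequence) -> WeightedNetwork:
    pos = {node: i for i, node in enumerate(network.ids)}
    idx = [pos[n] for n in nodes]
    return WeightedNetwork(ids=list(nodes), w=network.w[np.ix_(idx, idx)].copy())


def hierarchical_cluster(
    network: WeightedNetwork,
    partition: Partition,
    max_depth: int = 3,
    n_random_starts: int = DEFAULT_RANDOM_STARTS,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> list:
    """Re-run Louvain inside each community to the requested depth.

    Level-d communities are Louvain partitions of the induced (weight
    preserving) subnetworks of level-(d-1) communities; singletons pass
    through unchanged.  Returns ``[level1, level2, ..., level max_depth]``.
    """
    levels = [partition]
    for depth in range(2, max_depth + 1):
        prev = levels[-1]
        assignment: dict = {}
        next_id = 0
        for c, members in sorted(prev.communities().items()):
            if len(members) == 1:
                assignment[members[0]] = next_id
                next_id += 1
                continue
            sub = subnetwork(network, members)
            sub_part = louvain_cluster(
                sub, n_random_starts, n_iterations, seed=seed + 1000 * depth + c
            )
            for node in members:
                assignment[node] = next_id + sub_part.assignment[node]
            next_id += sub_part.n_communities
        levels.append(
            Partition(
                assignment=assignment,
                q=modularity(network, Partition(assignment, 0.0)),
                level=depth,
            )
        )
    return levels


# --- centralities and summaries ------------------------------------------


@dataclass
class CentralityReport:
    """Weighted degree and betweenness per node, with percentile ranks, on the
    whole network and on each first-level cluster subnetwork."""

    scopes: dict = field(default_factory=dict)  # scope name -> DataFrame

    def frame(self, scope: str = "network") -> pd.DataFrame:
        return self.scopes[scope]


def _centrality_frame(network: WeightedNetwork, betweenness_lengths: str) -> pd.DataFrame:
    from scipy.stats import rankdata

    G = network.to_networkx()
    degree = dict(G.degree(weight="weight"))
    if betweenness_lengths == "inverse_weight":
        for _, _, d in G.edges(data=True):
            d["length"] = 1.0 / d["weight"]
        btw = nx.betweenness_centrality(G, weight="length", normalized=True)
    else:
        btw = nx.betweenness_centrality(G, weight=None, normalized=True)
    df = pd.DataFrame(
        {
            "node": network.ids,
            "degree": [degree[n] for n in network.ids],
            "betweenness": [btw[n] for n in network.ids],
        }
    )
    n = len(df)
    df["degree_percentile"] = rankdata(df["degree"]) / n * 100.0
    df["betweenness_percentile"] = rankdata(df["betweenness"]) / n * 100.0
    return df


def centralities(
    network: WeightedNetwork,
    partition: Partition | None = None,
    betweenness_lengths: str = "inverse_weight",
) -> CentralityReport:
    """Centrality measures; strong correlation counts as a short path by
    default (edge length 1/w; set ``betweenness_lengths='unit'`` for hop
    counts)."""
    report = CentralityReport()
    report.scopes["network"] = _centrality_frame(network, betweenness_lengths)
    if partition is not None:
        for c, members in sorted(partition.communities().items()):
            if len(members) < 2:
                continue
            report.scopes[f"cluster_{c}"] = _centrality_frame(
                subnetwork(network, members), betweenness_lengths
            )
    return report


def cluster_correlation_summary(
    corr: CorrelationMatrix, partition: Partition
) -> tuple[dict, dict]:
    """Intra-cluster and inter-cluster simple averages of the correlation
    coefficients (diagonal excluded; singleton clusters have undefined intra
    averages, returned as NaN)."""
    labels = partition.labels_for(corr.ids)
    intra: dict = {}
    inter: dict = {}
    for a in np.unique(labels):
        ia = np.flatnonzero(labels == a)
        if len(ia) < 2:
            logger.info("cluster %d is a singleton; intra-cluster average undefined", a)
            intra[int(a)] = float("nan")
        else:
            block = corr.c[np.ix_(ia, ia)]
            intra[int(a)] = float(block[np.triu_indices(len(ia), k=1)].mean())
        for b in np.unique(labels):
            if b <= a:
                continue
            ib = np.flatnonzero(labels == b)
            inter[(int(a), int(b))] = float(corr.c[np.ix_(ia, ib)].mean())
    return intra, inter


def heatmap_order(corr: CorrelationMatrix, partition: Partition) -> list:
    """Cluster-contiguous center ordering for the correlation heat map:
    by cluster id, then by descending average correlation to the rest of the
    cluster, then by center id."""
    labels = partition.labels_for(corr.ids)
    keys = []
    for i, node in enumerate(corr.ids):
        same = np.flatnonzero(labels == labels[i])
        others = same[same != i]
        avg = corr.c[i, others].mean() if len(others) else 0.0
        keys.append((labels[i], -avg, str(node), node))
    return [k[3] for k in sorted(keys, key=lambda t: t[:3])]
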