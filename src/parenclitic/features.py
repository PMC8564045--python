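"""Topological characteristics of sample networks and their summaries.

Eight characteristics are computed per network.  Shortest-path quantities
(closeness, betweenness, edge betweenness) treat edge weights as DISTANCES;
spectral and flow quantities (page rank, eigenvector centrality, authority
score) treat them as CONNECTION STRENGTHS.  Six descriptive statistics
(zeros, min, max, mean, sd, coefvar) of each characteristic give the
48-dimensional characteristic feature vector of a network, with every
NA / +-Inf replaced by 0 so the vector is always finite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .networks import PairModelSet, SampleNetwork, build_sample_network
from .table import FeatureTable

#: Canonical characteristic order (fixed: column order of the 48-vector).
CHARACTERISTICS = (
    "closeness",
    "betweenness",
    "edge_betweenness",
    "page_rank",
    "eigen_centrality",
    "authority_score",
    "strength",
    "edge_weights",
)

#: Canonical statistic order within each characteristic.
STATS = ("zeros", "min", "max", "mean", "sd", "coefvar")

#: |x| below this counts as an exact zero in the ``zeros`` statistic.
ZERO_TOL = 1e-12

PAGERANK_DAMPING = 0.85


@dataclass
class CharacteristicSet:
    """The eight raw characteristic vectors of one network (unsanitized)."""

    closeness: np.ndarray
    betweenness: np.ndarray
    edge_betweenness: np.ndarray
    page_rank: np.ndarray
    eigen_centrality: np.ndarray
    authority_score: np.ndarray
    strength: np.ndarray
    edge_weights: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHARACTERISTICS}


def _principal_direction(M: np.ndarray, use_svd: bool) -> np.ndarray:
    """Leading eigen/singular direction, sign-fixed, scaled to max |.| = 1."""
    if use_svd:
        u, s, _ = np.linalg.svd(M)
        vec, lead = u[:, 0], s[0]
    else:
        vals, vecs = np.linalg.eigh(M)
        k = int(np.argmax(vals))
        vec, lead = vecs[:, k], vals[k]
    if abs(lead) < ZERO_TOL:
        return np.zeros(M.shape[0])
    top = np.argmax(np.abs(vec))
    if vec[top] < 0:
        vec = -vec
    return vec / np.abs(vec).max()


def compute_characteristics(net: SampleNetwork) -> CharacteristicSet:
    """All eight characteristics of one complete weighted network.

    The graph is complete, so every vertex is reachable; zero-weight edges
    are legitimate zero-length paths.  Values may still be infinite (e.g.
    closeness when all distances are 0) — sanitization happens downstream.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("a network needs at least 2 nodes")
    W = net.weights
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        g.add_edge(i, j, weight=float(W[i, j]))

    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    sum_dist = np.array([sum(dist[i].values()) for i in range(n)])
    with np.errstate(divide="ignore"):
        closeness = 1.0 / sum_dist  # inf when every distance is 0

    btw = nx.betweenness_centrality(g, weight="weight", normalized=False)
    betweenness = np.array([btw[i] for i in range(n)])

    ebtw = nx.edge_betweenness_centrality(g, weight="weight", normalized=False)
    edge_betweenness = np.array(
        [ebtw.get((i, j), ebtw.get((j, i), 0.0))
         for i, j in itertools.combinations(range(n), 2)])

    pr = nx.pagerank(g, alpha=PAGERANK_DAMPING, weight="weight",
                     tol=1e-12, max_iter=1000)
    page_rank = np.array([pr[i] for i in range(n)])

    eigen_centrality = _principal_direction(W, use_svd=False)
    authority_score = _principal_direction(W, use_svd=True)

    iu = np.triu_indices(n, k=1)
    return CharacteristicSet(
        closeness=closeness,
        betweenness=betweenness,
        edge_betweenness=edge_betweenness,
        page_rank=page_rank,
        eigen_centrality=eigen_centrality,
        authority_score=authority_score,
        strength=W.sum(axis=1),
        edge_weights=W[iu],
    )


def sanitize(x: float) -> float:
    """Replace NA / NaN / +-Inf by 0; pass finite values through."""
    if x is None:
        return 0.0
    x = float(x)
    return x if np.isfinite(x) else 0.0


def descriptive_stats(v) -> dict[str, float]:
    """zeros, min, max, mean, sd (n-1), coefvar = sd/mean of a vector.

    A length-1 vector has sd 0 by convention; coefvar of an all-zero vector
    sanitizes (0/0) to 0.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("descriptive_stats of an empty vector")
    zeros = int((np.abs(v) < ZERO_TOL).sum())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    mean = float(v.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        coefvar = np.divide(sd, mean)
    return {
        "zeros": float(zeros),
        "min": sanitize(v.min()),
        "max": sanitize(v.max()),
        "mean": sanitize(mean),
        "sd": sanitize(sd),
        "coefvar": sanitize(coefvar),
    }


def characteristic_feature_vector(net: SampleNetwork) -> pd.Series:
    """The 48 named statistics of one network, finite by construction.

    Characteristic vectors are sanitized element-wise first (the convention
    for NA/Inf characteristic values), then summarized; the summary itself
    is sanitized again so e.g. coefvar of an all-zero vector is 0.
    """
    chars = compute_characteristics(net)
    out = {}
    for cname, vec in chars.as_dict().items():
        clean = np.array([sanitize(x) for x in np.asarray(vec, dtype=float)])
        stats = descriptive_stats(clean)
        for sname in STATS:
            out[f"{cname}_{sname}"] = stats[sname]
    return pd.Series(out)


def characteristic_table(models: PairModelSet, table: FeatureTable) -> pd.DataFrame:
    """48-statistic rows for every sample of a table (plus id/label/fold)."""
    rows = []
    for k in range(len(table)):
        row = table.features.iloc[k].copy()
        row["sample_id"] = table.sample_ids[k]
        net = build_sample_network(models, row)
        rows.append(characteristic_feature_vector(net))
    stats = pd.DataFrame(rows).reset_index(drop=True)
    meta = pd.DataFrame({
        "sample_id": table.sample_ids,
        "label": table.labels,
        "fold": table.folds,
    })
    return pd.concat([meta, stats], axis=1)
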