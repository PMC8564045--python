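"""Per-sample network assembly: fit all pairwise models, build graphs.

For a table with n features, every unordered feature pair gets one fitted
edge model (C(n, 2) models).  Each sample's individual network is the
complete weighted graph whose edge (i, j) carries the pair model's weight at
the sample's (value_i, value_j).  The vertex strength — the sum of incident
edge weights — is the main per-feature summary carried downstream.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .edges import fit_kde_edge, fit_linear_edge, fit_svm_edge
from .errors import (
    DegeneracyWarning,
    DegenerateFitError,
    InsufficientDataError,
    InvalidLabelsError,
    SchemaError,
)
from .table import FeatureTable

#: The three construction methods: regression-residual parenclitic,
#: KDE parenclitic, and SVM synolytic.
METHODS = ("wLRPA", "wKDEPA", "wSA")


@dataclass
class DegenerateEdgeModel:
    """Placeholder for a pair whose fit degenerated: constant-zero weight.

    Keeps the complete-graph contract — an edge for any sample always
    exists — while contributing nothing to strengths.
    """

    reason: str = ""

    def weight(self, x, y):
        out = np.zeros_like(np.atleast_1d(np.asarray(x, dtype=float)))
        return out if np.ndim(x) else 0.0


@dataclass
class PairModelSet:
    """All fitted pair models for one method over one feature list."""

    method: str
    feature_names: list[str]
    models: dict[tuple[int, int], object]
    fit_metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def pairs(self):
        """Canonical (i, j), i < j, in column order — also the edge order."""
        return itertools.combinations(range(self.n_features), 2)


def _pair_seed(base_seed: int, pair_index: int) -> int:
    """Deterministic per-pair seed, independent of evaluation order."""
    return int(np.random.SeedSequence([base_seed, pair_index]).generate_state(1)[0]
               % 2**31)


def fit_pair_models(train_table: FeatureTable, method: str,
                    seed: int = 0, **config) -> PairModelSet:
    """Fit one edge model per unordered feature pair on TRAIN samples.

    wLRPA and wKDEPA fit on TRAIN controls only; wSA uses both classes.
    Pairs whose fit degenerates (zero spread) are kept as constant-zero
    placeholders and recorded in ``fit_metadata['degenerate_pairs']``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    names = train_table.feature_names
    if len(names) < 2:
        raise SchemaError("need at least 2 feature columns")
    X = train_table.X
    y = train_table.labels

    if method == "wSA":
        if len(set(y)) < 2:
            raise InvalidLabelsError("wSA requires both classes in TRAIN")
        fit_rows = np.arange(len(y))
    else:
        fit_rows = np.flatnonzero(y == 0)
        if len(fit_rows) < (3 if method == "wLRPA" else 5):
            raise InvalidLabelsError(
                f"too few TRAIN controls for {method} ({len(fit_rows)})")

    models: dict[tuple[int, int], object] = {}
    degenerate: list[tuple[int, int]] = []
    for k, (i, j) in enumerate(itertools.combinations(range(len(names)), 2)):
        pts = X[fit_rows][:, [i, j]]
        try:
            if method == "wLRPA":
                models[(i, j)] = fit_linear_edge(pts, **config)
            elif method == "wKDEPA":
                models[(i, j)] = fit_kde_edge(pts, **config)
            else:
                models[(i, j)] = fit_svm_edge(
                    pts, y[fit_rows], seed=_pair_seed(seed, k), **config)
        except (DegenerateFitError, InsufficientDataError) as exc:
            warnings.warn(f"pair ({names[i]}, {names[j]}) degenerated: {exc}",
                          DegeneracyWarning, stacklevel=2)
            models[(i, j)] = DegenerateEdgeModel(reason=str(exc))
            degenerate.append((i, j))
    return PairModelSet(
        method=method,
        feature_names=list(names),
        models=models,
        fit_metadata={"seed": seed, "config": config,
                      "n_fit_samples": len(fit_rows),
                      "degenerate_pairs": degenerate},
    )


@dataclass
class SampleNetwork:
    """One sample's complete weighted graph over the feature nodes."""

    weights: np.ndarray
    node_names: list[str]
    sample_id: str
    method: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Edge weights in canonical (i < j) order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        strengths = self.weights.sum(axis=1)
        for i, name in enumerate(self.node_names):
            g.add_node(name, strength=float(strengths[i]))
        for i, j in itertools.combinations(range(self.n_nodes), 2):
            g.add_edge(self.node_names[i], self.node_names[j],
                       weight=float(self.weights[i, j]))
        return g


def build_sample_network(models: PairModelSet, sample_row) -> SampleNetwork:
    """Evaluate every pair model at the sample's values."""
    if isinstance(sample_row, pd.Series):
        missing = [f for f in models.feature_names if f not in sample_row.index]
        if missing:
            raise SchemaError(f"sample is missing features: {missing}")
        values = sample_row[models.feature_names].to_numpy(dtype=float)
        sample_id = str(sample_row.get("sample_id", sample_row.name))
    else:
        values = np.asarray(sample_row, dtype=float)
        if values.shape != (models.n_features,):
            raise SchemaError("sample row length does not match the model set")
        sample_id = ""
    n = models.n_features
    W = np.zeros((n, n))
    for (i, j), model in models.models.items():
        w = float(model.weight(values[i], values[j]))
        W[i, j] = W[j, i] = w
    return SampleNetwork(weights=W, node_names=list(models.feature_names),
                         sample_id=sample_id, method=models.method)


def strengths(net: SampleNetwork) -> np.ndarray:
    """Vertex strengths: row sums of the weight matrix (always finite)."""
    return net.weights.sum(axis=1)


def strength_matrix(models: PairModelSet, table: FeatureTable) -> FeatureTable:
    """Strengths of every sample's network, computed pair-by-pair in batch.

    Equivalent to building each network and summing rows, but evaluates each
    pair model once for all samples.  Labels, folds and sample ids are
    carried over so the result drops into the same classifier harness as the
    raw table.
    """
    if table.feature_names != models.feature_names:
        raise SchemaError("table features do not match the fitted model set")
    X = table.X
    S = np.zeros_like(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegeneracyWarning)
        for (i, j), model in models.models.items():
            w = np.asarray(model.weight(X[:, i], X[:, j]), dtype=float)
            S[:, i] += w
            S[:, j] += w
    return FeatureTable(
        features=pd.DataFrame(S, columns=models.feature_names),
        labels=table.labels,
        folds=table.folds,
        sample_ids=table.sample_ids,
    )


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_network(net: SampleNetwork, path: str | Path,
                   format: str = "graphml") -> None:
    """Write a network as GraphML (node strengths, edge weights) or edge CSV."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.to_graph(), path)
    elif format == "edge_csv":
        rows = [(net.node_names[i], net.node_names[j], net.weights[i, j])
                for i, j in itertools.combinations(range(net.n_nodes), 2)]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def import_network(path: str | Path, format: str = "graphml",
                   sample_id: str = "", method: str = "") -> SampleNetwork:
    """Read back an exported network (lossless to float round-trip)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        names = list(g.nodes)
    elif format == "edge_csv":
        df = pd.read_csv(path)
        g = nx.from_pandas_edgelist(df, "source", "target", edge_attr="weight")
        seen = dict.fromkeys(df["source"])
        seen.update(dict.fromkeys(df["target"]))
        names = list(seen)
    else:
        raise ValueError(f"unknown format {format!r}")
    index = {name: k for k, name in enumerate(names)}
    W = np.zeros((len(names), len(names)))
    for u, v, data in g.edges(data=True):
        W[index[u], index[v]] = W[index[v], index[u]] = float(data["weight"])
    return SampleNetwork(weights=W, node_names=names, sample_id=sample_id,
                         method=method)
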