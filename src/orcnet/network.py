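"""Differential gene-correlation network construction.

Builds the weighted network the curvature analysis runs on: filter lowly
expressed genes on raw counts, quantile-normalize the normalized expression
values, form per-patient on-minus-pre difference vectors, restrict a
confidence-filtered protein-interaction topology to a core gene set plus its
neighbors, attach per-edge Pearson correlations of the expression changes,
convert them to transport distances, and precompute all-pairs shortest paths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

DISTANCE_FLOOR = 1e-6  # floor on rho_shifted before inversion

__all__ = [
    "ExpressionMatrix",
    "CorrelationNetwork",
    "filter_low_expression",
    "quantile_normalize",
    "compute_delta",
    "build_topology",
    "expand_core_genes",
    "edge_correlations",
    "shift_correlation",
    "edge_distance",
    "shortest_paths",
    "attach_correlations",
    "build_network",
]


@dataclass
class ExpressionMatrix:
    """Normalized expression with sample→condition/patient metadata.

    ``values`` is genes x samples; ``condition`` maps sample id to
    ``"pre"`` or ``"on"``; ``patient`` maps sample id to patient id.
    """

    values: pd.DataFrame
    condition: dict[str, str]
    patient: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        for s in self.values.columns:
            if self.condition.get(s, "").lower() not in {"pre", "on"}:
                raise ValueError(f"sample {s!r} lacks a pre/on condition label")

    def matched_patients(self) -> list[str]:
        """Patients with exactly one pre and one on sample."""
        by_patient: dict[str, dict[str, list[str]]] = {}
        for s in self.values.columns:
            cond = self.condition[s].lower()
            by_patient.setdefault(self.patient[s], {}).setdefault(cond, []).append(s)
        return sorted(
            p for p, conds in by_patient.items()
            if len(conds.get("pre", [])) == 1 and len(conds.get("on", [])) == 1
        )


@dataclass
class CorrelationNetwork:
    """Connected gene network with correlation-derived transport distances.

    ``graph`` carries per-edge attributes ``rho`` (Pearson correlation of
    expression changes), ``rho_shifted`` ((1+rho)/2) and ``weight``
    (transport distance, the inverse shifted correlation).  ``d`` is the
    all-pairs shortest-path matrix over ``weight``, indexed by ``nodes``.
    """

    graph: nx.Graph
    nodes: list[str]
    d: np.ndarray
    is_core: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.nodes)}

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges()]

    def edge_arrays(self):
        """(i, j, rho_shifted, weight) arrays in a fixed edge order."""
        edges = sorted(self.edges)
        i = np.array([self.index[a] for a, _ in edges])
        j = np.array([self.index[b] for _, b in edges])
        rs = np.array([self.graph.edges[e]["rho_shifted"] for e in edges])
        w = np.array([self.graph.edges[e]["weight"] for e in edges])
        return edges, i, j, rs, w

    def distance(self, u: str, v: str) -> float:
        return float(self.d[self.index[u], self.index[v]])


def filter_low_expression(
    raw_counts: pd.DataFrame, min_count: int = 10, min_sample_frac: float = 0.10
) -> list[str]:
    """Genes with count >= min_count in at least min_sample_frac of samples.

    Mirrors the usual low-expression pre-filter: a gene survives unless it
    falls below ``min_count`` raw reads in more than ``1 - min_sample_frac``
    of samples.
    """
    if raw_counts.empty:
        raise ValueError("empty count matrix")
    if (raw_counts.to_numpy() < 0).any():
        raise ValueError("raw counts must be nonnegative")
    frac = (raw_counts >= min_count).mean(axis=1)
    return list(raw_counts.index[frac >= min_sample_frac])


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties within a column receive the mean of the reference
    values at the tied ranks (so the operation is idempotent).
    """
    if values.shape[1] < 1:
        raise ValueError("need at least one sample")
    arr = values.to_numpy(dtype=float)
    reference = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    for c in range(arr.shape[1]):
        col = arr[:, c]
        order = np.argsort(col, kind="stable")
        ranked = reference.copy()
        # average reference over runs of equal input values
        sorted_col = col[order]
        boundaries = np.r_[0, np.nonzero(np.diff(sorted_col))[0] + 1, len(col)]
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            if hi - lo > 1:
                ranked[lo:hi] = reference[lo:hi].mean()
        out[order, c] = ranked
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def compute_delta(expr: ExpressionMatrix) -> pd.DataFrame:
    """On-treatment minus pre-treatment expression, one column per matched patient."""
    patients = expr.matched_patients()
    if len(patients) < 2:
        raise ValueError("need at least 2 patients with matched pre/on samples")
    sample_of = {
        (expr.patient[s], expr.condition[s].lower()): s for s in expr.values.columns
    }
    cols = {
        p: expr.values[sample_of[(p, "on")]] - expr.values[sample_of[(p, "pre")]]
        for p in patients
    }
    return pd.DataFrame(cols, index=expr.values.index)


def build_topology(
    ppi_edges: pd.DataFrame, confidence_cutoff: float, min_degree: int = 5,
    iterative: bool = False,
) -> nx.Graph:
    """Confidence-filter a PPI edge list, then drop low-degree vertices.

    ``ppi_edges`` needs columns (geneA, geneB, confidence); self-loops and
    duplicate pairs are removed.  The degree filter is a single pass on the
    confidence-filtered graph by default; ``iterative=True`` applies it as a
    k-core peel instead.
    """
    if ppi_edges.empty:
        raise ValueError("empty PPI edge list")
    a, b, conf = ppi_edges.columns[:3]
    kept = ppi_edges[ppi_edges[conf] >= confidence_cutoff]
    graph = nx.Graph()
    graph.add_edges_from(
        (u, v) for u, v in zip(kept[a], kept[b]) if u != v
    )
    if iterative:
        graph = nx.k_core(graph, k=min_degree).copy()
    else:
        low = [v for v, deg in graph.degree() if deg < min_degree]
        graph.remove_nodes_from(low)
    graph.remove_nodes_from(list(nx.isolates(graph)))
    if graph.number_of_edges() == 0:
        raise ValueError("no edges survive confidence/degree filtering")
    return graph


def expand_core_genes(
    topology: nx.Graph, core: set[str], expressed: set[str]
) -> nx.Graph:
    """Core genes plus their topology neighbors, largest connected component.

    Vertices are (core ∩ topology ∩ expressed) together with their topology
    neighbors that are expressed; the induced subgraph's largest connected
    component is returned (ties broken by lexicographically smallest vertex
    set) with a boolean ``is_core`` node attribute.
    """
    if not core:
        raise ValueError("core gene set is empty")
    present = core & set(topology) & expressed
    if not present:
        raise ValueError("no core gene present in both topology and expression data")
    vertices = set(present)
    for g in present:
        vertices.update(n for n in topology.neighbors(g) if n in expressed)
    sub = topology.subgraph(vertices)
    components = sorted(nx.connected_components(sub), key=lambda c: (-len(c), sorted(c)))
    if len(components) > 1:
        logger.info("expand_core_genes: keeping largest of %d components", len(components))
    skeleton = sub.subgraph(components[0]).copy()
    nx.set_node_attributes(skeleton, {v: v in present for v in skeleton}, "is_core")
    return skeleton


def edge_correlations(delta: pd.DataFrame, skeleton: nx.Graph) -> dict[tuple[str, str], float]:
    """Pearson correlation of patient expression changes, per skeleton edge only."""
    if delta.shape[1] < 3:
        raise ValueError("need at least 3 patients for edge correlations")
    missing = [v for v in skeleton if v not in delta.index]
    if missing:
        raise ValueError(f"skeleton genes missing from delta matrix: {missing[:5]}")
    arr = delta.loc[list(skeleton.nodes)].to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(skeleton.nodes)}
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    if flat.any():
        genes = [g for g in skeleton.nodes if flat[idx[g]]]
        warnings.warn(
            f"{len(genes)} zero-variance gene(s) (e.g. {genes[0]}); "
            "their edge correlations are set to 0",
            stacklevel=2,
        )
    rho: dict[tuple[str, str], float] = {}
    for u, v in skeleton.edges():
        i, j = idx[u], idx[v]
        if flat[i] or flat[j]:
            r = 0.0
        else:
            r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
            r = min(1.0, max(-1.0, r))
        rho[tuple(sorted((u, v)))] = r
    return rho


def shift_correlation(rho):
    """Map Pearson correlation linearly from [-1, 1] onto [0, 1]: (1 + rho) / 2."""
    rho = np.asarray(rho, dtype=float)
    if (np.abs(rho) > 1).any():
        raise ValueError("correlation outside [-1, 1]")
    out = (1.0 + rho) / 2.0
    return float(out) if out.ndim == 0 else out


def edge_distance(rho_shifted, floor: float = DISTANCE_FLOOR):
    """Transport distance as the inverse shifted correlation, floored at ``floor``."""
    rs = np.asarray(rho_shifted, dtype=float)
    if ((rs < 0) | (rs > 1)).any():
        raise ValueError("shifted correlation outside [0, 1]")
    out = 1.0 / np.maximum(rs, floor)
    return float(out) if out.ndim == 0 else out


def shortest_paths(graph: nx.Graph, nodes: list[str]) -> np.ndarray:
    """All-pairs Dijkstra over the ``weight`` edge attribute, as a dense matrix."""
    index = {g: i for i, g in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, w in graph.edges(data="weight"):
        if w <= 0:
            raise ValueError("edge weights must be positive")
        rows.append(index[u]); cols.append(index[v]); vals.append(w)
    n = len(nodes)
    adj = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    d = dijkstra(adj, directed=False)
    if not np.isfinite(d).all():
        raise ValueError("graph is disconnected; take the largest component first")
    return d


def attach_correlations(
    skeleton: nx.Graph, delta: pd.DataFrame, distance_floor: float = DISTANCE_FLOOR
) -> CorrelationNetwork:
    """Decorate a topology with rho / rho_shifted / weight and shortest paths."""
    rho = edge_correlations(delta, skeleton)
    graph = skeleton.copy()
    for e, r in rho.items():
        rs = shift_correlation(r)
        graph.edges[e].update(
            rho=r, rho_shifted=rs, weight=edge_distance(rs, distance_floor)
        )
    nodes = sorted(graph.nodes)
    d = shortest_paths(graph, nodes)
    is_core = {v: bool(graph.nodes[v].get("is_core", False)) for v in nodes}
    return CorrelationNetwork(graph=graph, nodes=nodes, d=d, is_core=is_core)


def build_network(
    raw_counts: pd.DataFrame | None,
    normalized: pd.DataFrame,
    condition: dict[str, str],
    patient: dict[str, str],
    ppi_edges: pd.DataFrame,
    core: set[str],
    confidence_cutoff: float = 700.0,
    min_degree: int = 5,
    min_count: int = 10,
    min_sample_frac: float = 0.10,
    quantile: bool = True,
) -> tuple[CorrelationNetwork, pd.DataFrame]:
    """End-to-end construction from expression + PPI inputs.

    Filtering happens on raw counts first (skipped when ``raw_counts`` is
    None), then normalized values are quantile-normalized, differenced per
    matched patient, and the core-expanded PPI skeleton is decorated with
    correlation-derived distances.  Returns the network and delta matrix.
    """
    values = normalized
    if raw_counts is not None:
        kept = filter_low_expression(raw_counts, min_count, min_sample_frac)
        values = values.loc[values.index.intersection(kept)]
    if quantile:
        values = quantile_normalize(values)
    expr = ExpressionMatrix(values=values, condition=condition, patient=patient)
    delta = compute_delta(expr)
    topology = build_topology(ppi_edges, confidence_cutoff, min_degree)
    skeleton = expand_core_genes(topology, core, set(delta.index))
    network = attach_correlations(skeleton, delta)
    return network, delta
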