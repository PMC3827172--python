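"""Species co-occurrence correlation networks from occurrence-probability fields.

Each species is characterised by its vector of occurrence probabilities over
the (viable) cells; pairs whose Pearson correlation exceeds a threshold in
absolute value are connected by a signed edge.  Positive-edge connected
components recover guilds of species with shared spatial distributions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .simulator import OccupancyField

__all__ = [
    "CorrelationNetwork",
    "occurrence_correlation",
    "build_network",
    "export_network",
    "read_network",
    "positive_components",
]


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (a, b, r) with a < b
    threshold: float

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, r in self.edges:
            g.add_edge(a, b, weight=float(r), sign=1 if r > 0 else -1)
        return g


def occurrence_correlation(
    field: OccupancyField,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson correlation between species' per-cell occurrence vectors.

    ``mask`` selects the cells to correlate over (typically the viable
    cells).  Species whose vector has zero variance get NaN rows/columns
    (flagged missing), apart from the unit diagonal.
    """
    probs = field.probability
    if mask is None:
        x = probs.reshape(probs.shape[0], -1)
    else:
        x = probs[:, np.asarray(mask, dtype=bool)]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 cells to correlate over")
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.asarray(corr, dtype=float)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=field.species_ids, columns=field.species_ids)


def build_network(corr: pd.DataFrame, threshold: float = 0.5) -> CorrelationNetwork:
    """Signed edge for every unordered species pair with ``|r| > threshold``.

    Pairs with undefined correlation (zero-variance species) are skipped.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ids = list(corr.index)
    vals = corr.to_numpy()
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = vals[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                a, b = sorted((ids[i], ids[j]))
                edges.append((a, b, float(r)))
    edges.sort()
    return CorrelationNetwork(nodes=ids, edges=edges, threshold=threshold)


def positive_components(net: CorrelationNetwork) -> list[set[str]]:
    """Connected components of the positive-edge subgraph (singletons dropped)."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((a, b) for a, b, r in net.edges if r > 0)
    return [c for c in nx.connected_components(g) if len(c) > 1]


def export_network(net: CorrelationNetwork, path: str | Path, fmt: str = "pajek") -> Path:
    """Write the network as a Pajek ``.net`` file or a CSV edge list."""
    path = Path(path)
    if fmt == "pajek":
        nx.write_pajek(net.to_graph(), path)
    elif fmt == "edge-list":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["species_a", "species_b", "r"])
            for a, b, r in net.edges:
                w.writerow([a, b, repr(r)])
    else:
        raise ValueError("fmt must be 'pajek' or 'edge-list'")
    return path


def read_network(path: str | Path, fmt: str = "pajek", threshold: float = 0.5) -> CorrelationNetwork:
    """Read back a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "pajek":
        g = nx.Graph(nx.read_pajek(path))
        nodes = sorted(g.nodes)
        edges = sorted(
            (*sorted((a, b)), float(d.get("weight", 1.0))) for a, b, d in g.edges(data=True)
        )
        return CorrelationNetwork(nodes=nodes, edges=edges, threshold=threshold)
    if fmt == "edge-list":
        nodes: set[str] = set()
        edges = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                a, b, r = row["species_a"], row["species_b"], float(row["r"])
                nodes.update((a, b))
                edges.append((*sorted((a, b)), r))
        return CorrelationNetwork(nodes=sorted(nodes), edges=sorted(edges), threshold=threshold)
    raise ValueError("fmt must be 'pajek' or 'edge-list'")
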