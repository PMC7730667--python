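"""Centrality indices and shared layout for estimated symptom networks.

Conventions (field-standard for weighted psychopathology networks):

* strength(j)   = sum_k |beta_jk|  — sign-blind connectedness;
* edge length   = 1 / |weight|, so strong edges are short; distances are
  weighted shortest paths (unweighted hop counts are available via
  ``weighted=False``);
* closeness(j)  = 1 / sum_k d(j,k); a node that cannot reach every other
  node gets closeness 0 (disconnected convention);
* betweenness   = fractional shortest-path counts over unordered pairs of
  other nodes (ties split evenly, Brandes accumulation).

Standardized ("z-score") tables use the population SD across the network's
nodes.  Shortest paths, betweenness and the force-directed layout are
delegated to networkx.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ising_elasso import IsingNetwork


def strength(net: IsingNetwork) -> np.ndarray:
    return np.abs(net.beta).sum(axis=1)


def _length_graph(net: IsingNetwork, weighted: bool) -> nx.Graph:
    g = net.to_graph(absolute=True)
    for _, _, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"] if weighted else 1.0
    return g


def shortest_distances(net: IsingNetwork, weighted: bool = True) -> np.ndarray:
    """p x p matrix of shortest-path distances; +inf where unreachable."""
    g = _length_graph(net, weighted)
    acr = list(net.labels.acronyms)
    dist = np.full((net.p, net.p), np.inf)
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        i = acr.index(src)
        for dst, d in lengths.items():
            dist[i, acr.index(dst)] = d
    return dist


def closeness(net: IsingNetwork, weighted: bool = True) -> np.ndarray:
    dist = shortest_distances(net, weighted)
    total = dist.sum(axis=1)
    out = np.zeros(net.p)
    finite = np.isfinite(total) & (total > 0)
    out[finite] = 1.0 / total[finite]
    return out


def betweenness(net: IsingNetwork, weighted: bool = True) -> np.ndarray:
    g = _length_graph(net, weighted)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[a] for a in net.labels.acronyms])


@dataclass
class CentralityTable:
    """Raw and standardized strength/closeness/betweenness per node."""

    raw: pd.DataFrame           # index: acronyms; columns: the three indices
    standardized: pd.DataFrame  # same shape, z-scores across nodes

    def to_csv(self, path: str | Path) -> None:
        self.raw.to_csv(path, index_label="symptom")

    def standardized_long(self) -> pd.DataFrame:
        """Long format (symptom, index, z) mirroring centrality profile plots."""
        df = self.standardized.reset_index(names="symptom")
        return df.melt(id_vars="symptom", var_name="index", value_name="z")


def _zscores(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        sd = v.std()  # population SD across nodes
        if sd == 0:
            warnings.warn(f"{col}: zero variance across nodes; z-scores set to 0")
            out[col] = np.zeros_like(v)
        else:
            out[col] = (v - v.mean()) / sd
    return pd.DataFrame(out, index=df.index)


def standardize(table: CentralityTable) -> CentralityTable:
    """Return the table with z-scored values (idempotent up to rounding)."""
    if len(table.raw) < 2:
        raise ValueError("standardization needs at least two nodes")
    z = _zscores(table.raw)
    return CentralityTable(raw=table.raw, standardized=_zscores(z))


def centrality_table(net: IsingNetwork, weighted: bool = True) -> CentralityTable:
    if net.p < 2:
        raise ValueError("centrality needs at least two nodes")
    raw = pd.DataFrame(
        {
            "strength": strength(net),
            "closeness": closeness(net, weighted),
            "betweenness": betweenness(net, weighted),
        },
        index=list(net.labels.acronyms),
    )
    return CentralityTable(raw=raw, standardized=_zscores(raw))


@dataclass
class NetworkLayout:
    """Per-node (x, y) coordinates in the unit square."""

    coordinates: pd.DataFrame  # index: acronyms; columns: x, y

    def to_csv(self, path: str | Path) -> None:
        self.coordinates.to_csv(path, index_label="symptom")

    def positions(self) -> dict[str, tuple[float, float]]:
        return {a: (r.x, r.y) for a, r in self.coordinates.iterrows()}


def shared_layout(reference: IsingNetwork, seed: int = 0) -> NetworkLayout:
    """Deterministic force-directed layout of the reference (pooled) network.

    The point of a *shared* layout: compute coordinates once on the pooled
    network and reuse them for every stratum network, so stratum plots are
    visually comparable.  An edgeless reference falls back to a circle.
    """
    g = reference.to_graph(absolute=True)
    if g.number_of_edges() == 0:
        pos = nx.circular_layout(g)
    else:
        pos = nx.spring_layout(g, weight="weight", seed=seed)
    coords = pd.DataFrame(
        [(a, *pos[a]) for a in reference.labels.acronyms],
        columns=["symptom", "x", "y"],
    ).set_index("symptom")
    # rescale into the unit square
    for c in ("x", "y"):
        lo, hi = coords[c].min(), coords[c].max()
        coords[c] = 0.5 if hi == lo else (coords[c] - lo) / (hi - lo)
    return NetworkLayout(coords)


def plot_network(
    net: IsingNetwork,
    layout: NetworkLayout,
    path: str | Path,
    title: str | None = None,
    max_width: float = 6.0,
) -> None:
    """Schematic network rendering: edge width ~ |weight|, sign by color."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = layout.positions()
    fig, ax = plt.subplots(figsize=(5, 5))
    wmax = np.abs(net.beta).max() or 1.0
    acr = net.labels.acronyms
    for j in range(net.p):
        for k in range(j + 1, net.p):
            w = net.beta[j, k]
            if w == 0:
                continue
            (x1, y1), (x2, y2) = pos[acr[j]], pos[acr[k]]
            ax.plot(
                [x1, x2], [y1, y2],
                color="seagreen" if w > 0 else "firebrick",
                linewidth=max_width * abs(w) / wmax,
                alpha=0.8, zorder=1,
            )
    for a in acr:
        x, y = pos[a]
        ax.scatter([x], [y], s=600, color="lightsteelblue", zorder=2,
                   edgecolors="black")
        ax.annotate(a, (x, y), ha="center", va="center", zorder=3)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_centrality_profiles(
    tables: dict[str, CentralityTable], path: str | Path
) -> None:
    """Standardized centrality profiles, one line per group per index."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    indices = ["strength", "closeness", "betweenness"]
    fig, axes = plt.subplots(1, 3, figsize=(10, 4), sharey=True)
    for ax, idx in zip(axes, indices):
        for name, tab in tables.items():
            ax.plot(tab.standardized[idx], tab.standardized.index, marker="o",
                    label=name)
        ax.set_title(idx)
        ax.grid(alpha=0.3)
    axes[0].set_ylabel("symptom")
    axes[-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
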