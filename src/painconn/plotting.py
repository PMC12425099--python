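"""Optional diagnostic plots (group network, per-patient edge-count histogram)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

from .cohort_aggregation import CohortSummary

__all__ = ["plot_group_graph", "plot_per_patient_histogram"]


def plot_group_graph(graph: nx.Graph, path: str | Path, seed: int = 0) -> None:
    """Spring-layout plot: node size ~ weighted degree, edge width ~ recurrence."""
    fig, ax = plt.subplots(figsize=(8, 8))
    if graph.number_of_nodes():
        pos = nx.spring_layout(graph, seed=seed)
        degrees = dict(graph.degree(weight="weight"))
        nx.draw_networkx_nodes(
            graph, pos, ax=ax,
            node_size=[100 + 60 * degrees[n] for n in graph.nodes],
            node_color="#7fb3d5",
        )
        widths = [0.5 + 0.5 * d["weight"] for _, _, d in graph.edges(data=True)]
        nx.draw_networkx_edges(graph, pos, ax=ax, width=widths, alpha=0.7)
        nx.draw_networkx_labels(graph, pos, ax=ax, font_size=8)
        nx.draw_networkx_edge_labels(
            graph, pos, ax=ax, font_size=7,
            edge_labels={(a, b): d["weight"] for a, b, d in graph.edges(data=True)},
        )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_per_patient_histogram(summary: CohortSummary, path: str | Path) -> None:
    """Distribution of atypical-edge counts per patient."""
    counts = list(summary.per_patient_counts.values())
    fig, ax = plt.subplots(figsize=(6, 4))
    if counts:
        ax.hist(counts, bins=range(0, max(counts) + 2), color="#7fb3d5",
                edgecolor="black", align="left")
    ax.set_xlabel("atypical connections per patient")
    ax.set_ylabel("number of patients")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
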