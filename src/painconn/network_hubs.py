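"""Region-group network construction and hub scoring.

Recurrent atypical edges are mapped onto the 18 anatomical location groups;
the resulting weighted graph (self-loops allowed, e.g. thalamus-thalamus) is
thresholded and each group receives a hub score: its weighted degree
normalized by the maximum weighted degree, so the top hub scores exactly 1.0.
Self-loops contribute twice to degree, the standard graph convention.
"""
from __future__ import annotations

from collections import Counter

import networkx as nx
import pandas as pd

from .core_io import RoiTable
from .errors import ValidationError

__all__ = [
    "map_edges_to_groups",
    "build_group_graph",
    "hub_scores",
    "edge_prevalence_pct",
]

GroupPair = tuple[str, str]


def _canonical(a: str, b: str) -> GroupPair:
    return (a, b) if a <= b else (b, a)


def map_edges_to_groups(
    edge_counts: dict[tuple[int, int], int],
    seed_table: RoiTable,
    atlas_table: RoiTable,
) -> dict[GroupPair, int]:
    """Aggregate (seed, atlas) edge recurrence counts into unordered group pairs.

    Each edge contributes its patient count to the pair
    ``(group(seed), group(atlas))``; pairs are unordered and self-pairs (both
    ROIs in the same group) are legal.
    """
    pair_counts: Counter = Counter()
    for (si, ai), count in edge_counts.items():
        if not 0 <= si < len(seed_table):
            raise ValidationError(f"seed index {si} out of range")
        if not 0 <= ai < len(atlas_table):
            raise ValidationError(f"atlas index {ai} out of range")
        pair = _canonical(seed_table.group_of(si), atlas_table.group_of(ai))
        pair_counts[pair] += count
    return dict(pair_counts)


def build_group_graph(
    pair_counts: dict[GroupPair, int], min_count: int = 4
) -> nx.Graph:
    """Weighted group graph keeping pairs observed more than ``min_count`` times."""
    if min_count < 0:
        raise ValidationError("min_count must be >= 0")
    graph = nx.Graph()
    for (a, b), count in sorted(pair_counts.items()):
        if count > min_count:
            graph.add_edge(a, b, weight=int(count))
    return graph


def hub_scores(graph: nx.Graph, weighted: bool = True) -> dict[str, float]:
    """Max-normalized degree centrality per group.

    Weighted degree sums incident edge weights (self-loops counted twice);
    the unweighted variant counts incident edges instead. The maximum score
    is exactly 1.0 for any non-empty graph.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("hub scores undefined for an empty graph")
    weight = "weight" if weighted else None
    degrees = dict(graph.degree(weight=weight))
    max_deg = max(degrees.values())
    if max_deg == 0:
        raise ValidationError("hub scores undefined when all degrees are zero")
    return {node: deg / max_deg for node, deg in degrees.items()}


def hub_scores_frame(graph: nx.Graph, weighted: bool = True) -> pd.DataFrame:
    scores = hub_scores(graph, weighted=weighted)
    weight = "weight" if weighted else None
    degrees = dict(graph.degree(weight=weight))
    frame = pd.DataFrame(
        {
            "group": list(scores),
            "weighted_degree": [degrees[g] for g in scores],
            "hub_score": [scores[g] for g in scores],
        }
    )
    return frame.sort_values(
        ["hub_score", "group"], ascending=[False, True], ignore_index=True
    )


def edge_prevalence_pct(
    pair_counts: dict[GroupPair, int], n_patients: int
) -> dict[GroupPair, float]:
    """Percentage of patients showing each group pair, rounded to one decimal.

    Rounding is round-half-even (Python's built-in ``round``).
    """
    if n_patients <= 0:
        raise ValidationError("n_patients must be > 0")
    return {
        pair: round(100.0 * count / n_patients, 1)
        for pair, count in pair_counts.items()
    }
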