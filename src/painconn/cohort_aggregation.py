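"""Cohort-level recurrence of atypical edges and nodes.

Per-patient significant edges are pooled across the cohort. A node's
recurrence counts *patients* (a patient with five significant edges touching
the thalamus contributes one), while an edge's recurrence counts patients in
whose significant set it appears. All recurrence thresholds are strict
("more than k" means count > k).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .permutation_stats import EdgeTestResult

__all__ = [
    "PatientAtypicalSet",
    "CohortSummary",
    "aggregate",
    "recurrent_nodes",
    "recurrent_edges",
    "per_patient_distribution",
]


@dataclass(frozen=True)
class PatientAtypicalSet:
    """One patient's set of significant (seed_index, atlas_index) edges."""

    patient_id: str
    edges: frozenset[tuple[int, int]]


@dataclass
class CohortSummary:
    """Recurrence counts of atypical edges and nodes across patients."""

    edge_counts: dict[tuple[int, int], int]
    seed_node_counts: dict[int, int]
    atlas_node_counts: dict[int, int]
    per_patient_counts: dict[str, int]

    @property
    def n_patients(self) -> int:
        return len(self.per_patient_counts)

    def edge_counts_frame(self) -> pd.DataFrame:
        rows = sorted(self.edge_counts.items())
        return pd.DataFrame(
            [(s, a, c) for (s, a), c in rows],
            columns=["seed_index", "atlas_index", "n_patients"],
        )


def _as_atypical_set(result) -> PatientAtypicalSet:
    if isinstance(result, PatientAtypicalSet):
        return result
    if isinstance(result, EdgeTestResult):
        return PatientAtypicalSet(result.patient_id, result.significant_edges())
    raise ValidationError(f"cannot aggregate object of type {type(result).__name__}")


def aggregate(results: list) -> CohortSummary:
    """Pool per-patient significant-edge sets into cohort recurrence counts.

    Accepts :class:`EdgeTestResult` or :class:`PatientAtypicalSet` items.
    Duplicate patient ids are rejected (repeated assessments of one patient
    must be resolved upstream).
    """
    sets = [_as_atypical_set(r) for r in results]
    ids = [s.patient_id for s in sets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicated patient_id in aggregation: {dupes}")

    edge_counts: Counter = Counter()
    seed_counts: Counter = Counter()
    atlas_counts: Counter = Counter()
    per_patient = {}
    for s in sets:
        per_patient[s.patient_id] = len(s.edges)
        edge_counts.update(s.edges)
        seed_counts.update({si for si, _ in s.edges})
        atlas_counts.update({ai for _, ai in s.edges})
    return CohortSummary(
        edge_counts=dict(edge_counts),
        seed_node_counts=dict(seed_counts),
        atlas_node_counts=dict(atlas_counts),
        per_patient_counts=per_patient,
    )


def _sorted_nodes(counts: dict[int, int], min_patients: int) -> list[tuple[int, int]]:
    kept = [(idx, c) for idx, c in counts.items() if c > min_patients]
    return sorted(kept, key=lambda t: (-t[1], t[0]))


def recurrent_nodes(
    summary: CohortSummary, min_patients: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Nodes atypical in more than ``min_patients`` patients (strict).

    Returns ``(seed_nodes, atlas_nodes)``, each a list of (roi_index, count)
    sorted by count descending, ties by index.
    """
    if min_patients < 0:
        raise ValidationError("min_patients must be >= 0")
    return (
        _sorted_nodes(summary.seed_node_counts, min_patients),
        _sorted_nodes(summary.atlas_node_counts, min_patients),
    )


def recurrent_edges(
    summary: CohortSummary, min_count: int
) -> list[tuple[tuple[int, int], int]]:
    """Edges appearing in more than ``min_count`` patients (strict)."""
    if min_count < 0:
        raise ValidationError("min_count must be >= 0")
    kept = [(e, c) for e, c in summary.edge_counts.items() if c > min_count]
    return sorted(kept, key=lambda t: (-t[1], t[0]))


def per_patient_distribution(summary: CohortSummary) -> tuple[dict[int, int], float]:
    """Histogram of atypical-edge counts per patient.

    Returns ``(histogram, fraction_with_any)`` where histogram maps an edge
    count to the number of patients with exactly that count, and
    ``fraction_with_any`` is the fraction of patients with at least one
    atypical edge (0.0 for an empty cohort).
    """
    counts = list(summary.per_patient_counts.values())
    hist = dict(sorted(Counter(counts).items()))
    if not counts:
        return hist, 0.0
    frac = sum(1 for c in counts if c > 0) / len(counts)
    return hist, frac
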