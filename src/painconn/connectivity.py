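"""Seed-to-atlas functional connectivity: Pearson correlation per edge.

One "edge" is one (seed, atlas ROI) pair; a subject's connectivity matrix is
the 76 x 116 table of sample Pearson correlations between each pain-seed
signal and each atlas-ROI signal. The Fisher z transform (atanh) is available
as a variance-stabilized scale for downstream testing.
"""
from __future__ import annotations

import numpy as np

from .core_io import ConnectivityMatrix, SubjectTimeSeries
from .errors import UndefinedCorrelationError, ValidationError

__all__ = ["pearson_edge", "connectivity_matrix", "fisher_z", "inverse_fisher_z"]

_CLIP = 1.0 - 1e-7


def pearson_edge(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation between two signals of equal length T >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 timepoints for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant signal")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z = atanh(r), with r clipped to +/-(1 - 1e-7) to stay finite."""
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    return np.tanh(z)


def connectivity_matrix(
    ts: SubjectTimeSeries,
    seed_labels: list[str],
    atlas_labels: list[str],
    scale: str = "pearson_r",
) -> ConnectivityMatrix:
    """Correlate every seed signal with every atlas signal for one subject.

    Entry (i, j) is ``pearson_edge(seed_i, atlas_j)``; with ``scale="fisher_z"``
    the atanh transform is applied.
    """
    if scale not in ("pearson_r", "fisher_z"):
        raise ValidationError(f"unknown scale {scale!r}")
    index = {lab: k for k, lab in enumerate(ts.region_labels)}
    missing = [lab for lab in list(seed_labels) + list(atlas_labels) if lab not in index]
    if missing:
        raise ValidationError(f"time series is missing region labels: {missing}")

    seeds = ts.data[:, [index[lab] for lab in seed_labels]]
    atlas = ts.data[:, [index[lab] for lab in atlas_labels]]
    if ts.n_timepoints < 3:
        raise ValidationError("need at least 3 timepoints for a correlation")

    def _standardize(block: np.ndarray) -> np.ndarray:
        centred = block - block.mean(axis=0)
        norms = np.sqrt(np.einsum("tj,tj->j", centred, centred))
        if np.any(norms == 0):
            raise UndefinedCorrelationError("constant signal in correlation input")
        return centred / norms

    r = np.clip(_standardize(seeds).T @ _standardize(atlas), -1.0, 1.0)
    values = fisher_z(r) if scale == "fisher_z" else r
    return ConnectivityMatrix(
        subject_id=ts.subject_id,
        values=values,
        scale=scale,
        seed_labels=list(seed_labels),
        atlas_labels=list(atlas_labels),
    )
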