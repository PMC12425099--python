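"""Region metadata, subject containers, and delimited-text readers/writers.

All on-disk tables are tab-separated UTF-8 with a mandatory header row and
``.`` as the decimal separator. Floats are written with 17 significant digits
so that a write/read round trip is exact.

Internal indices are 0-based. MNI coordinates are millimetres, RAS+.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "REGION_GROUPS",
    "N_SEEDS",
    "N_ATLAS",
    "RoiTable",
    "SubjectTimeSeries",
    "ConnectivityMatrix",
    "CohortStack",
    "ClinicalTable",
    "read_roi_table",
    "load_default_seed_table",
    "load_default_atlas_table",
    "read_timeseries",
    "write_timeseries",
    "read_connectivity_matrix",
    "write_connectivity_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "extract_roi_timeseries",
]

#: The 18 anatomical location groups used to summarize seed and atlas ROIs.
REGION_GROUPS: tuple[str, ...] = (
    "Amygdala",
    "Basal Ganglia",
    "Brainstem",
    "Cerebellum",
    "Cingulate Gyrus",
    "Hippocampus",
    "Inferior Frontal Gyrus",
    "Inferior Parietal Lobe",
    "Insula",
    "Middle Frontal Gyrus",
    "Occipital Lobe",
    "Orbitofrontal Cortex",
    "Postcentral Gyrus",
    "Precentral Gyrus",
    "Superior Frontal Gyrus",
    "Superior Parietal Lobe",
    "Temporal Lobe",
    "Thalamus",
)

N_SEEDS = 76
N_ATLAS = 116

_ROW_COUNTS = {"seed": N_SEEDS, "atlas": N_ATLAS}
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RoiTable:
    """Metadata for one set of regions of interest (pain seeds or atlas ROIs).

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns ``roi_id`` (0-based), ``label``, ``x``, ``y``, ``z`` (MNI mm)
        and ``location_group`` (one of the 18 group names).
    roi_kind : str
        Either ``"seed"`` or ``"atlas"``.
    """

    frame: pd.DataFrame
    roi_kind: str

    def __post_init__(self) -> None:
        if self.roi_kind not in _ROW_COUNTS:
            raise ValidationError(f"roi_kind must be 'seed' or 'atlas', got {self.roi_kind!r}")
        required = {"roi_id", "label", "x", "y", "z", "location_group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"RoiTable missing columns: {sorted(missing)}")
        if self.frame["label"].duplicated().any():
            dupes = self.frame.loc[self.frame["label"].duplicated(), "label"].tolist()
            raise ValidationError(f"duplicate ROI labels: {dupes}")
        bad = set(self.frame["location_group"]) - set(REGION_GROUPS)
        if bad:
            raise ValidationError(f"unknown location groups: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> list[str]:
        return self.frame["label"].tolist()

    @property
    def coordinates(self) -> np.ndarray:
        return self.frame[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def groups(self) -> list[str]:
        return self.frame["location_group"].tolist()

    def group_of(self, roi_index: int) -> str:
        return self.frame["location_group"].iloc[roi_index]


@dataclass
class SubjectTimeSeries:
    """One subject's ROI signal table: T timepoints x R regions."""

    subject_id: str
    data: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time-series data must be 2-D (T x R)")
        if self.data.shape[0] < 2:
            raise ValidationError("need at least 2 timepoints")
        if self.data.shape[1] != len(self.region_labels):
            raise ValidationError("region_labels length must match the number of columns")
        if np.isnan(self.data).any():
            raise ValidationError("time series contains NaN values; missing data is rejected")
        sd = self.data.std(axis=0)
        if np.any(sd == 0):
            labels = [self.region_labels[i] for i in np.flatnonzero(sd == 0)]
            raise ValidationError(f"constant (zero-variance) region signal: {labels}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """One subject's seed-to-atlas connectivity matrix (seeds x atlas ROIs)."""

    subject_id: str
    values: np.ndarray
    scale: str = "pearson_r"
    seed_labels: list[str] | None = None
    atlas_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("connectivity values must be 2-D (seeds x atlas)")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if np.isnan(self.values).any():
            raise ValidationError("connectivity matrix contains missing values")
        if self.scale == "pearson_r" and (np.abs(self.values) > 1).any():
            raise ValidationError("pearson_r values must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CohortStack:
    """A stack of control connectivity matrices: n_subjects x seeds x atlas."""

    values: np.ndarray
    subject_ids: list[str]
    scale: str = "pearson_r"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("cohort stack must be 3-D (subjects x seeds x atlas)")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValidationError("first dimension must equal the number of subjects")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_matrices(cls, matrices: Sequence[ConnectivityMatrix]) -> "CohortStack":
        scales = {m.scale for m in matrices}
        if len(scales) != 1:
            raise ValidationError(f"matrices mix scales: {sorted(scales)}")
        return cls(
            values=np.stack([m.values for m in matrices]),
            subject_ids=[m.subject_id for m in matrices],
            scale=scales.pop(),
        )


_CLINICAL_COLUMNS = ["subject_id", "group", "age", "sex", "vas_pct", "womac_pct", "mean_fd"]


@dataclass
class ClinicalTable:
    """Per-subject demographics, motion summary, and pain outcomes.

    ``vas_pct`` / ``womac_pct`` are percent-change pain scores and are present
    only for patients (NaN for controls). ``mean_fd`` is mean framewise
    displacement in mm.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_CLINICAL_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        if self.frame["subject_id"].duplicated().any():
            raise ValidationError("duplicated subject_id in clinical table")
        bad_group = set(self.frame["group"]) - {"patient", "control"}
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        ctl = self.frame[self.frame["group"] == "control"]
        for col in ("vas_pct", "womac_pct"):
            if ctl[col].notna().any():
                raise ValidationError(f"{col} must be absent (NaN) for controls")

    def patients(self) -> pd.DataFrame:
        return self.frame[self.frame["group"] == "patient"].reset_index(drop=True)

    def controls(self) -> pd.DataFrame:
        return self.frame[self.frame["group"] == "control"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    except (pd.errors.ParserError, OSError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return frame


def read_roi_table(path: str | Path, roi_kind: str, strict: bool = True) -> RoiTable:
    """Read a seed or atlas ROI table (label, x, y, z, location_group)."""
    frame = _read_tsv(path)
    required = ["label", "x", "y", "z", "location_group"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("x", "y", "z"):
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise FormatError(f"{path}: non-numeric coordinate column {col!r}")
    expected = _ROW_COUNTS.get(roi_kind)
    if expected is None:
        raise ValidationError(f"roi_kind must be 'seed' or 'atlas', got {roi_kind!r}")
    if strict and len(frame) != expected:
        raise ValidationError(
            f"{path}: expected {expected} rows for roi_kind={roi_kind!r}, got {len(frame)}"
        )
    frame = frame[required].copy()
    frame.insert(0, "roi_id", np.arange(len(frame)))
    return RoiTable(frame=frame, roi_kind=roi_kind)


def _packaged(name: str) -> Path:
    return Path(importlib.resources.files("painconn").joinpath("data", name))


def load_default_seed_table() -> RoiTable:
    """The packaged 76-seed pain-coordinate table (synthetic reconstruction)."""
    return read_roi_table(_packaged("pain_seeds_synthetic.tsv"), "seed")


def load_default_atlas_table() -> RoiTable:
    """The packaged AAL-116 atlas table (synthetic centroid reconstruction)."""
    return read_roi_table(_packaged("aal116_atlas_synthetic.tsv"), "atlas")


def read_timeseries(path: str | Path, subject_id: str | None = None) -> SubjectTimeSeries:
    """Read a T x R region time-series table; header row = region labels."""
    frame = _read_tsv(path)
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise FormatError(f"{path}: non-numeric values in column {col!r}")
    sid = subject_id if subject_id is not None else Path(path).stem
    return SubjectTimeSeries(
        subject_id=sid, data=frame.to_numpy(dtype=float), region_labels=list(frame.columns)
    )


def write_timeseries(ts: SubjectTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=ts.region_labels).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_connectivity_matrix(
    path: str | Path, subject_id: str | None = None, scale: str = "pearson_r"
) -> ConnectivityMatrix:
    """Read a connectivity matrix TSV (first column = seed labels, header = atlas labels)."""
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected a seed-label column plus atlas columns")
    seed_labels = frame.iloc[:, 0].astype(str).tolist()
    values = frame.iloc[:, 1:]
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            raise FormatError(f"{path}: non-numeric values in column {col!r}")
    sid = subject_id if subject_id is not None else Path(path).stem
    return ConnectivityMatrix(
        subject_id=sid,
        values=values.to_numpy(dtype=float),
        scale=scale,
        seed_labels=seed_labels,
        atlas_labels=list(values.columns),
    )


def write_connectivity_matrix(mat: ConnectivityMatrix, path: str | Path) -> None:
    seeds = mat.seed_labels or [f"seed{i:03d}" for i in range(mat.shape[0])]
    atlas = mat.atlas_labels or [f"atlas{j:03d}" for j in range(mat.shape[1])]
    frame = pd.DataFrame(mat.values, columns=atlas)
    frame.insert(0, "seed_label", seeds)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    frame = _read_tsv(path)
    missing = [c for c in _CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return ClinicalTable(frame=frame[_CLINICAL_COLUMNS].copy())


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# image-mode ROI extraction


def extract_roi_timeseries(
    bold_image,
    atlas_image,
    seed_table: RoiTable,
    atlas_table: RoiTable | None = None,
    sphere_radius_mm: float = 6.0,
    subject_id: str = "subject",
) -> SubjectTimeSeries:
    """Extract seed-sphere and atlas-ROI mean signals from a 4-D BOLD image.

    Atlas ROI k's signal is the unweighted mean over voxels whose atlas label
    equals ``k+1`` (labels 1..116 in atlas-table row order). Each seed's signal
    is the unweighted mean over in-brain voxels within ``sphere_radius_mm`` of
    the seed's MNI coordinate; "in-brain" means inside the image grid. Both
    images must share grid shape and affine.

    Parameters accept :class:`nibabel` spatial images or paths loadable by
    ``nibabel.load``.
    """
    import nibabel as nib

    if isinstance(bold_image, (str, Path)):
        bold_image = nib.load(str(bold_image))
    if isinstance(atlas_image, (str, Path)):
        atlas_image = nib.load(str(atlas_image))

    bold = np.asarray(bold_image.get_fdata(), dtype=float)
    labels = np.asarray(atlas_image.get_fdata())
    if bold.ndim != 4:
        raise ValidationError("BOLD image must be 4-D")
    if labels.shape != bold.shape[:3]:
        raise ValidationError("atlas and BOLD images have different grid shapes")
    if not np.allclose(bold_image.affine, atlas_image.affine, atol=1e-4):
        raise ValidationError("atlas and BOLD images have different affines (space mismatch)")

    if atlas_table is None:
        atlas_table = load_default_atlas_table()
    n_atlas = len(atlas_table)
    flat = bold.reshape(-1, bold.shape[3])
    lab_flat = np.rint(labels.reshape(-1)).astype(int)

    atlas_signals = np.empty((bold.shape[3], n_atlas))
    for k in range(n_atlas):
        mask = lab_flat == k + 1
        if not mask.any():
            raise ValidationError(
                f"atlas label {k + 1} ({atlas_table.labels[k]}) has no voxels in the image"
            )
        atlas_signals[:, k] = flat[mask].mean(axis=0)

    # voxel-centre world coordinates via the shared affine
    ii, jj, kk = np.meshgrid(
        np.arange(bold.shape[0]), np.arange(bold.shape[1]), np.arange(bold.shape[2]),
        indexing="ij",
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(lab_flat.size)])
    world = vox @ bold_image.affine.T
    world = world[:, :3]

    coords = seed_table.coordinates
    seed_signals = np.empty((bold.shape[3], len(seed_table)))
    r2 = float(sphere_radius_mm) ** 2
    for s in range(len(seed_table)):
        d2 = np.sum((world - coords[s]) ** 2, axis=1)
        mask = d2 <= r2
        if not mask.any():
            raise ValidationError(
                f"seed {seed_table.labels[s]!r} at {coords[s].tolist()}: sphere of radius "
                f"{sphere_radius_mm} mm contains no in-brain voxels (outside field of view?)"
            )
        seed_signals[:, s] = flat[mask].mean(axis=0)

    data = np.hstack([seed_signals, atlas_signals])
    return SubjectTimeSeries(
        subject_id=subject_id,
        data=data,
        region_labels=list(seed_table.labels) + list(atlas_table.labels),
    )
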