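"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the single-subject test
assumes: a normative cohort of controls whose edge values vary around
per-edge means, and patients drawn from the same distribution except on a
configurable set of injected "atypical" edges shifted by an effect size
``delta``. Two pathways are provided:

``edge_level``
    Draw Fisher-z edge values directly: control edge e for subject s is
    Normal(mu_e, sigma_between), with mu_e drawn once per edge from
    Normal(mu, mu_sd). Patients add ``delta`` on their injected edges only.

``timeseries_level``
    Draw T x (n_seeds + n_atlas) BOLD-like signals from a unit-variance
    multivariate normal whose seed/atlas correlation on injected edges is
    shifted by ``delta`` on the Fisher-z scale in patients.

Clinical outcomes can be linearly coupled to chosen edges with Gaussian
noise, so downstream regression stages have a known generating model.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ClinicalTable, CohortStack, ConnectivityMatrix, SubjectTimeSeries
from .errors import SimulationSpecError

__all__ = [
    "ClinicalCoupling",
    "SimulationSpec",
    "GroundTruth",
    "simulate_edge_level",
    "simulate_timeseries_level",
    "simulate_clinical",
]

Edge = tuple[int, int]


@dataclass(frozen=True)
class ClinicalCoupling:
    """Linear generating model: outcome = intercept + slope * edge + noise."""

    edge: Edge
    slope: float
    intercept: float
    noise_sd: float
    outcome: str = "vas_pct"


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the study design: 20 controls, a 76 x 116 seed-to-atlas
    edge grid, Fisher-z edge means around 0.3 (SD 0.1 across edges) with
    between-subject SD 0.1. ``injected_edges`` is either one sequence of
    (seed_index, atlas_index) pairs applied to every patient, or one sequence
    per patient.
    """

    n_controls: int = 20
    n_patients: int = 1
    n_seeds: int = 76
    n_atlas: int = 116
    mode: str = "edge_level"
    T: int = 200
    mu: float = 0.3
    mu_sd: float = 0.1
    sigma_between: float = 0.1
    injected_edges: Sequence = ()
    delta: float = 0.0
    clinical_coupling: Sequence[ClinicalCoupling] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise SimulationSpecError("n_controls must be >= 2")
        if self.n_patients < 0:
            raise SimulationSpecError("n_patients must be >= 0")
        if self.delta < 0:
            raise SimulationSpecError("delta must be >= 0")
        if self.mode not in ("edge_level", "timeseries_level"):
            raise SimulationSpecError(f"unknown mode {self.mode!r}")
        if self.mode == "timeseries_level" and self.T < 50:
            raise SimulationSpecError("timeseries mode requires T >= 50")
        for edges in self.injected_per_patient():
            for si, ai in edges:
                if not (0 <= si < self.n_seeds and 0 <= ai < self.n_atlas):
                    raise SimulationSpecError(f"injected edge {(si, ai)} out of bounds")

    def injected_per_patient(self) -> list[tuple[Edge, ...]]:
        """Normalize ``injected_edges`` to one edge tuple per patient."""
        inj = self.injected_edges
        if len(inj) == 0:
            return [()] * self.n_patients
        first = inj[0]
        if len(first) == 2 and all(isinstance(v, (int, np.integer)) for v in first):
            shared = tuple((int(s), int(a)) for s, a in inj)
            return [shared] * self.n_patients
        if len(inj) != self.n_patients:
            raise SimulationSpecError(
                "per-patient injected_edges must have one entry per patient"
            )
        return [tuple((int(s), int(a)) for s, a in edges) for edges in inj]


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream validation."""

    injected: dict[str, frozenset[Edge]]
    edge_means: np.ndarray | None = None
    clinical: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "injected": {pid: sorted(map(list, edges)) for pid, edges in self.injected.items()},
            "clinical": self.clinical,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _streams(spec: SimulationSpec, n: int) -> list[np.random.Generator]:
    root = np.random.SeedSequence(spec.rng_seed)
    return [np.random.default_rng(child) for child in root.spawn(n)]


def control_ids(spec: SimulationSpec) -> list[str]:
    return [f"control{c:02d}" for c in range(spec.n_controls)]


def patient_ids(spec: SimulationSpec) -> list[str]:
    return [f"patient{p:02d}" for p in range(spec.n_patients)]


def simulate_edge_level(
    spec: SimulationSpec,
) -> tuple[CohortStack, list[ConnectivityMatrix], GroundTruth]:
    """Draw control and patient connectivity matrices directly on the Fisher-z scale."""
    shape = (spec.n_seeds, spec.n_atlas)
    # stream 0: edge means; streams 1..: one per subject (controls then patients)
    streams = _streams(spec, 1 + spec.n_controls + spec.n_patients)
    mu_e = streams[0].normal(spec.mu, spec.mu_sd, size=shape)

    controls = np.stack(
        [mu_e + streams[1 + c].normal(0.0, spec.sigma_between, size=shape)
         for c in range(spec.n_controls)]
    )
    stack = CohortStack(values=controls, subject_ids=control_ids(spec), scale="fisher_z")

    injected = spec.injected_per_patient()
    patients = []
    truth_injected = {}
    for p in range(spec.n_patients):
        pid = patient_ids(spec)[p]
        values = mu_e + streams[1 + spec.n_controls + p].normal(
            0.0, spec.sigma_between, size=shape
        )
        for si, ai in injected[p]:
            values[si, ai] += spec.delta
        patients.append(
            ConnectivityMatrix(subject_id=pid, values=values, scale="fisher_z")
        )
        truth_injected[pid] = frozenset(injected[p])
    return stack, patients, GroundTruth(injected=truth_injected, edge_means=mu_e)


def _correlation_target(
    spec: SimulationSpec,
    injected: tuple[Edge, ...],
    base_correlations: dict[Edge, float] | None,
) -> np.ndarray:
    """Region-by-region correlation matrix; seeds first, atlas ROIs after."""
    n = spec.n_seeds + spec.n_atlas
    corr = np.eye(n)
    base = dict(base_correlations or {})
    for (si, ai), r0 in base.items():
        corr[si, spec.n_seeds + ai] = corr[spec.n_seeds + ai, si] = r0
    for si, ai in injected:
        r0 = base.get((si, ai), 0.0)
        r1 = np.tanh(np.arctanh(np.clip(r0, -1 + 1e-7, 1 - 1e-7)) + spec.delta)
        corr[si, spec.n_seeds + ai] = corr[spec.n_seeds + ai, si] = r1
    return corr


def simulate_timeseries_level(
    spec: SimulationSpec,
    base_correlations: dict[Edge, float] | None = None,
) -> tuple[list[SubjectTimeSeries], GroundTruth]:
    """Draw per-subject multivariate-normal signal tables (controls then patients).

    ``base_correlations`` optionally sets the generating seed/atlas correlation
    of chosen edges in all subjects; in patients, injected edges are shifted by
    ``delta`` on the Fisher-z scale. All signals have unit generating variance.
    Region labels are ``seed###`` / ``atlas###``.
    """
    if spec.mode != "timeseries_level":
        raise SimulationSpecError("spec.mode must be 'timeseries_level'")
    labels = [f"seed{i:03d}" for i in range(spec.n_seeds)] + [
        f"atlas{j:03d}" for j in range(spec.n_atlas)
    ]
    injected = spec.injected_per_patient()
    streams = _streams(spec, spec.n_controls + spec.n_patients)

    def _chol(corr: np.ndarray) -> np.ndarray:
        try:
            return np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise SimulationSpecError(
                "requested correlation structure is not positive definite; "
                "use smaller couplings"
            ) from exc

    control_corr = _correlation_target(spec, (), base_correlations)
    control_chol = _chol(control_corr)

    subjects = []
    truth_injected = {}
    for c, sid in enumerate(control_ids(spec)):
        z = streams[c].standard_normal((spec.T, len(labels)))
        subjects.append(SubjectTimeSeries(sid, z @ control_chol.T, list(labels)))
    for p, pid in enumerate(patient_ids(spec)):
        chol = (
            control_chol
            if not injected[p]
            else _chol(_correlation_target(spec, injected[p], base_correlations))
        )
        z = streams[spec.n_controls + p].standard_normal((spec.T, len(labels)))
        subjects.append(SubjectTimeSeries(pid, z @ chol.T, list(labels)))
        truth_injected[pid] = frozenset(injected[p])
    return subjects, GroundTruth(injected=truth_injected)


def simulate_clinical(
    ground_truth: GroundTruth,
    patient_matrices: list[ConnectivityMatrix],
    spec: SimulationSpec,
) -> ClinicalTable:
    """Draw a clinical table whose outcomes are linearly coupled to chosen edges.

    Ages are Normal(58, 7) years in both groups, sexes balanced, mean
    framewise displacement |Normal(0.15, 0.05)| mm. Each
    :class:`ClinicalCoupling` sets its outcome column for patients to
    intercept + slope * edge_value + Normal(0, noise_sd); outcome columns
    without a coupling are drawn as Normal(17, 32) percent, loosely matching
    reported percent-change pain-score spreads. The generating slope,
    intercept, and implied R^2 (from the realized edge values) are appended
    to ``ground_truth.clinical``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 2**20 + 7]))
    n_pat = len(patient_matrices)
    ids = [m.subject_id for m in patient_matrices] + control_ids(spec)
    groups = ["patient"] * n_pat + ["control"] * spec.n_controls
    n_total = len(ids)

    frame = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "age": rng.normal(58.0, 7.0, size=n_total),
            "sex": np.where(np.arange(n_total) % 2 == 0, "F", "M"),
            "vas_pct": np.nan,
            "womac_pct": np.nan,
            "mean_fd": np.abs(rng.normal(0.15, 0.05, size=n_total)),
        }
    )

    coupled = {c.outcome for c in spec.clinical_coupling}
    for col in ("vas_pct", "womac_pct"):
        if col not in coupled and n_pat:
            frame.loc[frame["group"] == "patient", col] = rng.normal(17.0, 32.0, n_pat)
    for coupling in spec.clinical_coupling:
        si, ai = coupling.edge
        x = np.array([m.values[si, ai] for m in patient_matrices])
        y = coupling.intercept + coupling.slope * x
        if coupling.noise_sd > 0:
            y = y + rng.normal(0.0, coupling.noise_sd, size=n_pat)
        frame.loc[frame["group"] == "patient", coupling.outcome] = y
        signal_var = coupling.slope**2 * float(np.var(x))
        expected_r2 = (
            1.0 if coupling.noise_sd == 0
            else signal_var / (signal_var + coupling.noise_sd**2)
        )
        ground_truth.clinical.append(
            {
                "edge": [si, ai],
                "outcome": coupling.outcome,
                "slope": coupling.slope,
                "intercept": coupling.intercept,
                "noise_sd": coupling.noise_sd,
                "expected_r2": expected_r2,
            }
        )
    return ClinicalTable(frame=frame)
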