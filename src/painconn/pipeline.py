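"""End-to-end orchestration: simulate/load -> test -> aggregate -> hubs -> clinical.

The pipeline is driven by a :class:`PipelineConfig` (constructed directly,
from a dict, or from a YAML file) and writes all stage outputs plus a JSON
run manifest recording every parameter and the random seed. With a fixed
seed a run is bit-reproducible.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical_stats import confounder_check, correlate_edges_with_outcome
from .cohort_aggregation import aggregate, per_patient_distribution, recurrent_edges
from .connectivity import connectivity_matrix
from .core_io import (
    ClinicalTable,
    CohortStack,
    ConnectivityMatrix,
    RoiTable,
    extract_roi_timeseries,
    load_default_atlas_table,
    load_default_seed_table,
    read_clinical_table,
    read_roi_table,
    read_timeseries,
    write_connectivity_matrix,
)
from .errors import ConfigurationError
from .network_hubs import (
    build_group_graph,
    edge_prevalence_pct,
    hub_scores_frame,
    map_edges_to_groups,
)
from .permutation_stats import PermutationConfig, test_patient
from .synthetic_data import (
    ClinicalCoupling,
    SimulationSpec,
    simulate_clinical,
    simulate_edge_level,
)

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.17g"


@dataclass
class PipelineConfig:
    """All pipeline parameters.

    ``mode`` selects the input pathway: ``synthetic`` (edge-level generator),
    ``timeseries`` (per-subject TSV signal tables), or ``images`` (4-D BOLD +
    atlas NIfTI). ``alpha = 0`` is accepted as a degenerate threshold under
    which no edge is ever significant.
    """

    mode: str = "synthetic"
    out_dir: str = "painconn_out"
    seed: int = 0
    scale: str = "fisher_z"
    n_perm: int = 10_000
    alpha: float = 0.05
    method: str = "monte_carlo"
    p_rule: str = "plus_one"
    null_model: str = "per_edge"
    node_min_patients: int = 10
    edge_min_patients: int = 7
    group_edge_min: int = 4
    sphere_radius_mm: float = 6.0
    drop_initial_volumes: int = 0
    simulation: dict = field(default_factory=dict)
    control_timeseries: list = field(default_factory=list)
    patient_timeseries: list = field(default_factory=list)
    control_images: list = field(default_factory=list)
    patient_images: list = field(default_factory=list)
    atlas_image: str | None = None
    seed_table: str | None = None
    atlas_table: str | None = None
    clinical_table: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "timeseries", "images"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not 0 <= self.alpha < 1:
            raise ConfigurationError("alpha must lie in [0, 1)")
        if self.mode == "timeseries":
            for key in ("control_timeseries", "patient_timeseries"):
                if not getattr(self, key):
                    raise ConfigurationError(f"mode 'timeseries' requires {key}")
        if self.mode == "images":
            for key in ("control_images", "patient_images", "atlas_image"):
                if not getattr(self, key):
                    raise ConfigurationError(f"mode 'images' requires {key}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


def _roi_tables(cfg: PipelineConfig) -> tuple[RoiTable, RoiTable]:
    seed = (
        read_roi_table(cfg.seed_table, "seed") if cfg.seed_table
        else load_default_seed_table()
    )
    atlas = (
        read_roi_table(cfg.atlas_table, "atlas") if cfg.atlas_table
        else load_default_atlas_table()
    )
    return seed, atlas


def _drop_volumes(ts, k: int):
    if k <= 0:
        return ts
    from .core_io import SubjectTimeSeries

    return SubjectTimeSeries(ts.subject_id, ts.data[k:], ts.region_labels)


def _load_inputs(cfg: PipelineConfig, seed_tab: RoiTable, atlas_tab: RoiTable):
    """Returns (stack, patient matrices, clinical table or None, ground truth or None)."""
    if cfg.mode == "synthetic":
        sim_kwargs = dict(cfg.simulation)
        couplings = [
            ClinicalCoupling(edge=tuple(c["edge"]), slope=c["slope"],
                             intercept=c["intercept"], noise_sd=c.get("noise_sd", 0.0),
                             outcome=c.get("outcome", "vas_pct"))
            if isinstance(c, dict) else c
            for c in sim_kwargs.pop("clinical_coupling", [])
        ]
        inj = sim_kwargs.pop("injected_edges", ())
        inj = tuple(tuple(e) for e in inj)
        spec = SimulationSpec(
            rng_seed=cfg.seed, injected_edges=inj,
            clinical_coupling=tuple(couplings), **sim_kwargs
        )
        stack, patients, truth = simulate_edge_level(spec)
        clinical = simulate_clinical(truth, patients, spec) if patients else None
        return stack, patients, clinical, truth

    if cfg.mode == "timeseries":
        def _connect(paths):
            mats = []
            for path in paths:
                ts = _drop_volumes(read_timeseries(path), cfg.drop_initial_volumes)
                mats.append(
                    connectivity_matrix(ts, seed_tab.labels, atlas_tab.labels, cfg.scale)
                )
            return mats

        controls = _connect(cfg.control_timeseries)
        patients = _connect(cfg.patient_timeseries)
    else:  # images
        def _connect_img(paths):
            mats = []
            for path in paths:
                ts = extract_roi_timeseries(
                    path, cfg.atlas_image, seed_tab, atlas_tab,
                    sphere_radius_mm=cfg.sphere_radius_mm,
                    subject_id=Path(path).stem,
                )
                ts = _drop_volumes(ts, cfg.drop_initial_volumes)
                mats.append(
                    connectivity_matrix(ts, seed_tab.labels, atlas_tab.labels, cfg.scale)
                )
            return mats

        controls = _connect_img(cfg.control_images)
        patients = _connect_img(cfg.patient_images)

    stack = CohortStack.from_matrices(controls)
    clinical = read_clinical_table(cfg.clinical_table) if cfg.clinical_table else None
    return stack, patients, clinical, None


def _write(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Run every stage and write results under ``config.out_dir``.

    Returns a dict with the in-memory stage outputs (test results, cohort
    summary, group graph, hub table) and the output directory.
    """
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = config

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_tab, atlas_tab = _roi_tables(cfg)
    stack, patients, clinical, truth = _load_inputs(cfg, seed_tab, atlas_tab)

    perm_cfg = PermutationConfig(
        n_perm=cfg.n_perm,
        alpha=cfg.alpha if cfg.alpha > 0 else 0.05,
        method=cfg.method,
        rng_seed=cfg.seed,
        p_rule=cfg.p_rule,
        null_model=cfg.null_model,
    )

    results = []
    for patient in patients:
        res = test_patient(stack, patient, perm_cfg)
        if cfg.alpha == 0:  # degenerate threshold: nothing is significant
            res.significant = res.p_adj <= 0.0
            res.alpha = 0.0
        results.append(res)
        _write(res.to_frame(seed_tab, atlas_tab), out / "edge_tests" / f"{res.patient_id}.tsv")
        write_connectivity_matrix(patient, out / "edge_tests" / f"{res.patient_id}_matrix.tsv")

    summary = aggregate(results)
    _write(
        pd.DataFrame(
            [(s, a, seed_tab.labels[s], atlas_tab.labels[a], c)
             for (s, a), c in sorted(summary.edge_counts.items())],
            columns=["seed_index", "atlas_index", "seed_label", "atlas_label", "n_patients"],
        ),
        out / "cohort" / "edge_counts.tsv",
    )
    for kind, counts, table in (
        ("seed", summary.seed_node_counts, seed_tab),
        ("atlas", summary.atlas_node_counts, atlas_tab),
    ):
        _write(
            pd.DataFrame(
                [(i, table.labels[i], c) for i, c in sorted(counts.items())],
                columns=["roi_index", "label", "n_patients"],
            ),
            out / "cohort" / f"node_counts_{kind}.tsv",
        )
    hist, frac_any = per_patient_distribution(summary)
    _write(
        pd.DataFrame(sorted(hist.items()), columns=["n_atypical_edges", "n_patients"]),
        out / "cohort" / "per_patient_histogram.tsv",
    )

    kept_edges = recurrent_edges(summary, cfg.edge_min_patients)
    pair_counts = map_edges_to_groups(dict(summary.edge_counts), seed_tab, atlas_tab)
    graph = build_group_graph(pair_counts, cfg.group_edge_min)
    _write(
        pd.DataFrame(
            [(a, b, d["weight"]) for a, b, d in sorted(graph.edges(data=True))],
            columns=["group_a", "group_b", "weight"],
        ),
        out / "network" / "group_graph.tsv",
    )
    hubs = (
        hub_scores_frame(graph)
        if graph.number_of_nodes()
        else pd.DataFrame(columns=["group", "weighted_degree", "hub_score"])
    )
    _write(hubs, out / "network" / "hub_scores.tsv")
    prevalence = edge_prevalence_pct(pair_counts, summary.n_patients) if summary.n_patients else {}
    _write(
        pd.DataFrame(
            [(a, b, pair_counts[(a, b)], pct) for (a, b), pct in sorted(prevalence.items())],
            columns=["group_a", "group_b", "count", "prevalence_pct"],
        ),
        out / "network" / "group_prevalence.tsv",
    )

    clinical_fits = None
    if clinical is not None:
        edges = sorted(summary.edge_counts)
        clinical_fits = correlate_edges_with_outcome(patients, edges, clinical)
        _write(clinical_fits, out / "clinical" / "clinical_fits.tsv")
        _write(confounder_check(clinical), out / "clinical" / "confounders.tsv")

    if truth is not None:
        truth.to_json(out / "ground_truth.json")

    manifest = {
        "painconn_version": __version__,
        "config": asdict(cfg),
        "n_controls": stack.n_subjects,
        "n_patients": len(patients),
        "n_edges_per_patient": int(np.prod(stack.values.shape[1:])),
        "fraction_patients_with_atypical_edge": frac_any,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "out_dir": out,
        "results": results,
        "summary": summary,
        "recurrent_edges": kept_edges,
        "graph": graph,
        "hub_scores": hubs,
        "clinical_fits": clinical_fits,
        "manifest": manifest,
    }
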