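import numpy as np
import pandas as pd
import pytest

from painconn import (
    PermutationConfig,
    PipelineConfig,
    RoiTable,
    SimulationSpec,
    load_default_atlas_table,
    load_default_seed_table,
    run_pipeline,
)

# seed indices 16..25 are the thalamus block of the packaged seed table
THALAMUS_SEEDS = list(range(16, 26))


@pytest.fixture(scope="session")
def seed_table():
    return load_default_seed_table()


@pytest.fixture(scope="session")
def atlas_table():
    return load_default_atlas_table()


def small_roi_table(labels, groups, roi_kind):
    """Build a RoiTable of arbitrary size for toy tests (bypasses row-count checks)."""
    frame = pd.DataFrame(
        {
            "roi_id": np.arange(len(labels)),
            "label": labels,
            "x": np.zeros(len(labels)),
            "y": np.zeros(len(labels)),
            "z": np.zeros(len(labels)),
            "location_group": groups,
        }
    )
    return RoiTable(frame=frame, roi_kind=roi_kind)


@pytest.fixture(scope="session")
def injected_pipeline_run(tmp_path_factory):
    """One fixed-seed synthetic pipeline run with 10 thalamus-heavy injected edges.

    20 controls, 5 patients, delta = 0.5 (5x the between-subject SD), exact
    pooled-null testing so per-edge FDR discoveries are possible.
    """
    injected = [(s, 10 * k + 3) for k, s in enumerate(THALAMUS_SEEDS)]
    cfg = PipelineConfig(
        mode="synthetic",
        out_dir=str(tmp_path_factory.mktemp("pipeline") / "run"),
        seed=11,
        method="exact",
        null_model="pooled_edges",
        simulation=dict(
            n_controls=20,
            n_patients=5,
            delta=0.5,
            injected_edges=injected,
            clinical_coupling=[
                dict(edge=injected[0], slope=67.87, intercept=8.71, noise_sd=0.0)
            ],
        ),
    )
    out = run_pipeline(cfg)
    out["injected"] = injected
    return out
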