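import numpy as np
import pandas as pd
import pytest

from ummetab.feature_io import (
    FeatureTable,
    METADATA_COLUMNS,
    SampleMetadata,
    StandardSet,
)
from ummetab.synthetic_data import SimulationConfig, simulate_cohort


def make_table(
    values,
    ion_mode="positive",
    state="raw",
    feature_ids=None,
    sample_ids=None,
):
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    return FeatureTable(
        feature_ids=feature_ids or [f"F{i:03d}" for i in range(nf)],
        mz=np.linspace(100, 900, nf),
        rt=np.linspace(30, 600, nf),
        ion_mode=ion_mode,
        abundances=values,
        sample_ids=sample_ids or [f"S{j:03d}" for j in range(ns)],
        transform_state=state,
    )


def make_metadata(sample_ids, groups=None, batches=None, roles=None, ltd=None):
    n = len(sample_ids)
    groups = groups or ["control"] * n
    rows = []
    for i, sid in enumerate(sample_ids):
        g = groups[i]
        rows.append(
            {
                "sample_id": sid,
                "group": g,
                "subclass": "BAP1" if g == "UM" else "control",
                "primary_driver": "GNAQ" if g == "UM" else "missing",
                "batch": (batches or ["discovery"] * n)[i],
                "role": (roles or ["study"] * n)[i],
                "storage_time": 1.0,
                "age": 65.0,
                "sex": "F",
                "ltd": (ltd[i] if ltd is not None else (12.0 if g == "UM" else np.nan)),
                "metastasis": "no" if g == "UM" else "unknown",
            }
        )
    return SampleMetadata(pd.DataFrame(rows, columns=METADATA_COLUMNS))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact but structurally complete simulated cohort."""
    cfg = SimulationConfig(
        n_discovery={"control": 12, "BAP1": 8, "SF3B1": 6, "EIF1AX": 6},
        n_replication={"control": 0, "BAP1": 5, "SF3B1": 5, "EIF1AX": 4},
        n_features=60,
        n_informative=15,
        effect_size=1.0,
        ltd_feature_corr=0.6,
        seed=11,
    )
    return simulate_cohort(cfg, return_truth=True)


@pytest.fixture()
def random_raw_table():
    rng = np.random.default_rng(7)
    vals = rng.lognormal(mean=6.0, sigma=1.2, size=(25, 12))
    vals[rng.random(vals.shape) < 0.1] = 0.0
    return make_table(vals)
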