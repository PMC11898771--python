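import numpy as np
import pandas as pd
import pytest

from morphoscreen.io_tables import FeatureTable
from morphoscreen.synthetic import (
    EffectSpec,
    SyntheticCellImageSpec,
    generate_image_set,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(
    conditions=("A", "B"),
    n_images=3,
    n_cells=20,
    n_features=2,
    seed=0,
    feature_values=None,
):
    """Small hand-rolled feature table for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        for im in range(n_images):
            for cid in range(1, n_cells + 1):
                row = {
                    "cell_id": cid,
                    "image_id": f"{cond}_im{im}",
                    "condition": cond,
                    "replicate_day": "d1",
                    "timepoint_h": 72.0,
                }
                for f in range(n_features):
                    if feature_values is not None:
                        row[f"feat_{f}"] = feature_values(cond, im, cid, f)
                    else:
                        row[f"feat_{f}"] = rng.normal()
                rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


@pytest.fixture
def small_table():
    return make_table()


@pytest.fixture
def noiseless_image_set():
    spec = SyntheticCellImageSpec(
        image_size=(220, 220), n_cells=6, noise_sd=0.0, seed=7
    )
    return generate_image_set(spec)


@pytest.fixture
def reference_effect():
    return EffectSpec("ref", n_cells_per_image=50, n_images=3)
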