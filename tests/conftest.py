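import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from arraybsa.io import FeatureAnnotation
from arraybsa.qc import matrix_from_values
from arraybsa.io import annotation_frame

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_layout():
    """Five subtracted features plus one of each control category."""
    layout = [
        FeatureAnnotation(f"FS{i}", "subtracted", (1, 1, i)) for i in range(1, 6)
    ]
    layout += [
        FeatureAnnotation("POS1", "positive_control", (2, 1, 1)),
        FeatureAnnotation("NEG1", "negative_control", (2, 1, 2)),
        FeatureAnnotation("PRT1", "printing_control", (2, 1, 3)),
        FeatureAnnotation("SPIKE1", "spike_in", (2, 1, 4)),
    ]
    return layout


def make_matrix(values_by_hyb, layout, design_rows):
    """Build a FeatureSignalMatrix from {hyb_id: value list} dicts."""
    ann = annotation_frame(layout)
    values = pd.DataFrame(values_by_hyb, index=ann.index, dtype=float)
    design = pd.DataFrame(
        design_rows, index=pd.Index(values.columns, name="hybridization_id")
    )
    return matrix_from_values(values, ann, design)


@pytest.fixture
def two_bulk_matrix(toy_layout):
    """2 bulks x 2 bio x 2 tech, spike-in constant, simple values."""
    n_feat = len(toy_layout)
    rng = np.random.default_rng(42)
    values, design = {}, {"target": [], "biological_replicate": [], "technical_replicate": []}
    hybs = []
    for b in ("DN1", "SD"):
        for i in (1, 2):
            for j in (1, 2):
                hid = f"{b}_b{i}_t{j}"
                v = rng.uniform(10, 30, n_feat)
                v[-1] = 50.0  # spike-in
                values[hid] = v
                design["target"].append(b)
                design["biological_replicate"].append(i)
                design["technical_replicate"].append(j)
                hybs.append(hid)
    return make_matrix(values, toy_layout, design)
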