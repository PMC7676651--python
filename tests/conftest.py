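import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vasokin.features import build_fold_change_matrix, feature_vector
from vasokin.synthetic import default_scenario, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One fixed synthetic 8-vs-7 cohort (patients, counts)."""
    return generate_cohort(default_scenario(seed=12345))


@pytest.fixture(scope="session")
def cd34_feature(default_cohort):
    """(x, y, ids) for the CD34+ H0-vs-B1 log fold-change feature."""
    patients, counts = default_cohort
    matrix = build_fold_change_matrix(counts, "B1")
    feat = feature_vector(matrix, "CD34", "H0")
    groups = dict(zip(patients["patient_id"], patients["group"]))
    ids = list(feat.index)
    x = feat.to_numpy()
    y = np.array([1 if groups[i] == "G2" else 0 for i in ids])
    return x, y, ids
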