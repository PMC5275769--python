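import numpy as np
import pandas as pd
import pytest

import oscc_mirna as om
from oscc_mirna.pipeline import preprocess


def run_pipeline(cfg: om.SimulationConfig):
    """simulate → exclude RBC markers → detection filter → normalize."""
    matrix, truth = om.simulate_counts(cfg)
    result = preprocess(matrix)
    filtered = om.exclude_markers(matrix, om.RBC_MARKERS)
    filtered = om.detection_filter(filtered)
    return matrix, filtered, result, truth


@pytest.fixture(scope="session")
def counts_cohort():
    """Planted-signal count cohort: 10+10 samples, 400 miRNAs, 15 DE at 4x."""
    cfg = om.SimulationConfig(
        n_tumor=10, n_normal=10, n_mirna=400, n_de=15,
        fold_changes=(4.0,), zero_inflation=0.1, seed=11,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def ct_cohort():
    """Planted-signal qPCR cohort: 20 tumor vs 17 normal."""
    cfg = om.SimulationConfig(
        n_tumor=20, n_normal=17, n_mirna=400, n_de=15,
        fold_changes=(4.0,), zero_inflation=0.1, seed=12,
    )
    matrix, truth = om.simulate_ct(cfg)
    result = preprocess(matrix)
    filtered = om.detection_filter(om.exclude_markers(matrix, om.RBC_MARKERS))
    return matrix, filtered, result, truth


@pytest.fixture
def tiny_norm():
    """Small complete log-scale matrix with labels, for classifier unit tests."""
    rng = np.random.default_rng(7)
    n_t, n_n = 6, 6
    X = rng.normal(8.0, 1.0, size=(30, n_t + n_n))
    X[:5, :n_t] += 4.0  # five strongly informative features
    samples = [f"T{i}" for i in range(n_t)] + [f"N{i}" for i in range(n_n)]
    values = pd.DataFrame(X, index=[f"m{i:02d}" for i in range(30)], columns=samples)
    labels = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    return om.NormalizedMatrix(values=values, platform="ct", labels=labels)
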