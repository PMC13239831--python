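import numpy as np
import pytest

import neurofcn as nf
from neurofcn.training import TrainConfig, cohort_graphs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Strong-effect cohort at reduced size: 10 ROIs, 12/group, t=150."""
    cfg = nf.default_config(n_subjects_per_group=12, n_rois=10,
                            n_timepoints=150, n_affected=6, seed=42)
    return nf.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_graphs(small_cohort):
    return cohort_graphs(small_cohort)


@pytest.fixture(scope="session")
def fast_train_config():
    return TrainConfig(epochs=60, seed=7)


@pytest.fixture(scope="session")
def trained_small_model(small_graphs, small_cohort, fast_train_config):
    from neurofcn.training import train_model
    model, summary = train_model(small_graphs, small_cohort.labels,
                                 ("PC", "SR", "GCM"), fast_train_config)
    return model, summary


def random_time_series(rng, t=50, n=8, subject_id="sub-x"):
    return nf.RoiTimeSeries(values=rng.standard_normal((t, n)),
                            roi_labels=[f"R{i}" for i in range(n)],
                            subject_id=subject_id)
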