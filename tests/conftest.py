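import numpy as np
import pytest

from wpaflow.classifier import ClassifierConfig, train
from wpaflow.synthcyto import (CohortConfig, RenderParams, render_training_set,
                               substream)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def noiseless_params():
    return RenderParams().noiseless()


@pytest.fixture()
def small_cohort_config():
    """Zero-dispersion cohort at the default baseline composition, sized so
    per-measurement counts are exactly the configured class means."""
    return CohortConfig(
        n_donors=4,
        baseline_class_means=(8400.0, 200.0, 10.0, 0.0),
        events_per_measurement=8610,
        inter_donor_dispersion=0.0,
        coincidence_fraction=0.0,
        out_of_focus_fraction=0.0,
    )


@pytest.fixture(scope="session")
def trained_model():
    """The reference classifier: trained once per session on 2000 rendered
    images at default noise, shared across classifier and pipeline tests."""
    rng = substream(0, 101)
    images, labels = render_training_set(2000, RenderParams(), CohortConfig(), rng)
    return train(ClassifierConfig(), images, labels)
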