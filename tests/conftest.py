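import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pepxai import (
    MotifSpec,
    PEPExplainer,
    PerturbationConfig,
    SyntheticConfig,
    generate,
    make_stub_blackbox,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: Study conditions for the planted-bump recovery experiment: a 2-class
#: ECG-length dataset where class 1 carries a Gaussian bump of amplitude 2
#: at t=70 over weak noise, and the black box thresholds the peak in a
#: window around it.
BUMP_STUDY = dict(
    n_instances=200,
    series_length=96,
    bump_center=70,
    bump_width=6,
    bump_amplitude=2.0,
    noise_sd=0.1,
    seed=1,
)


def make_bump_dataset(
    n_instances=200,
    series_length=96,
    bump_center=70,
    bump_width=6,
    bump_amplitude=2.0,
    noise_sd=0.1,
    seed=1,
    jitter=0,
):
    cfg = SyntheticConfig(
        n_instances=n_instances,
        series_length=series_length,
        class_motifs={
            0: [],
            1: [MotifSpec("bump", bump_center, bump_width, bump_amplitude, jitter)],
        },
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate(cfg)


def make_bump_blackbox(bump_center=70, bump_amplitude=2.0, window=10):
    return make_stub_blackbox(
        "peak_threshold",
        {"a": bump_center - window, "b": bump_center + window, "tau": bump_amplitude / 2},
    )


@pytest.fixture(scope="session")
def bump_study():
    """The fitted planted-bump recovery pipeline, shared across tests."""
    ds, gt = make_bump_dataset(**BUMP_STUDY)
    predictor = make_bump_blackbox(
        bump_center=BUMP_STUDY["bump_center"], bump_amplitude=BUMP_STUDY["bump_amplitude"]
    )
    bb_labels = predictor.predict(ds)
    explainer = PEPExplainer(random_state=BUMP_STUDY["seed"]).fit(ds, bb_labels)
    return {
        "dataset": ds,
        "ground_truth": gt,
        "predictor": predictor,
        "blackbox_labels": bb_labels,
        "explainer": explainer,
    }


@pytest.fixture
def tiny_dataset():
    from pepxai import TimeSeriesDataset

    values = np.array(
        [
            [0.0, 1.0, 0.0, 2.0],
            [3.0, 2.0, 1.0, 0.0],
            [0.0, 0.0, 1.0, 1.0],
        ]
    )
    return TimeSeriesDataset(values=values, labels=[0, 1, 0], instance_ids=["a", "b", "c"])
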