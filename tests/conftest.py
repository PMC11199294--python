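import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_layout():
    from midstates.simulate import make_layout

    return make_layout(10, seed=0)


def make_tiny_dataset(
    n_per_group=(4, 4),
    n_channels=10,
    fs=200.0,
    window=(0.0, 500.0),
    noise_sd=0.5,
    seed=0,
    boundaries=None,
    amplitudes=(3.0, 3.5, 2.5),
):
    """Small three-class dataset used across test modules."""
    from midstates.simulate import (
        GroundTruth,
        make_layout,
        make_templates,
        simulate_erp_dataset,
    )

    groups = ("patient", "control")
    conditions = ("reward", "loss", "neutral")
    if boundaries is None:
        boundaries = {(g, c): (0.0, 150.0, 350.0, 500.0) for g in groups for c in conditions}
    layout = make_layout(n_channels, seed=seed)
    templates = make_templates(3, layout, seed=seed + 1)
    timeline = {
        cell: [(j + 1, b[j], b[j + 1], amplitudes[j]) for j in range(3)]
        for cell, b in boundaries.items()
    }
    truth = GroundTruth(
        templates, timeline, noise_sd=noise_sd,
        subject_onset_jitter_ms=0.0, subject_log_amp_sd=0.0,
    )
    dataset = simulate_erp_dataset(
        truth, n_per_group, layout, fs=fs, epoch_window_ms=window,
        seed=seed + 2, groups=groups,
    )
    return dataset, truth


@pytest.fixture
def tiny_dataset():
    return make_tiny_dataset()


@pytest.fixture
def noisefree_dataset():
    return make_tiny_dataset(noise_sd=0.0)
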