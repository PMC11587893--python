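import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from facedecode.synthetic import (
    EpochsSet,
    SimulationConfig,
    StimulusDesign,
    build_layout,
    make_design,
)

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_layout():
    """8 gradiometer pairs in two posterior groups plus 4 EEG electrodes."""
    return build_layout(
        n_grad_pairs=8,
        n_eeg=4,
        groups=["left-occipital", "right-occipital"],
        group_size_bounds=(2, 20),
    )


@pytest.fixture(scope="session")
def two_cat_design():
    return make_design(
        StimulusDesign(categories=("AD", "HD"), trials_per_category_per_set=15)
    )


@pytest.fixture
def quiet_config():
    """Identical templates for every category: labels are exchangeable."""
    return SimulationConfig(category_amplitude=0.0)


def make_epochs(data, labels, layout, fs=600.0, t0=-200.0, set_tag=None, subject="S01"):
    """Construct an EpochsSet directly from arrays (test helper)."""
    labels = np.asarray(labels, dtype=object)
    if set_tag is None:
        set_tag = np.array(["color"] * len(labels), dtype=object)
    return EpochsSet(
        subject_id=subject,
        data=np.asarray(data, dtype=float),
        labels=labels,
        set_tag=np.asarray(set_tag, dtype=object),
        layout=layout,
        sampling_rate=fs,
        t0_offset=t0,
    )
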