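import numpy as np
import pandas as pd
import pytest

from alphaconn.cohort import EEGGenParams, SubjectSpec
from alphaconn.synth_bold import BOLDGenParams


@pytest.fixture
def eeg_params():
    """Short-duration EEG parameters for fast unit tests."""
    return EEGGenParams(duration=40.0, seed=101)


@pytest.fixture
def full_eeg_params():
    """Study-scale EEG parameters (150 s at 256 Hz)."""
    return EEGGenParams(seed=101)


@pytest.fixture
def bold_params():
    return BOLDGenParams(seed=202)


@pytest.fixture
def clean_bold_params():
    """BOLD parameters without nuisance or motion leak."""
    return BOLDGenParams(seed=202, nuisance_amp=0.0, motion_leak=0.0)


@pytest.fixture
def subject():
    return SubjectSpec("e4m001", age=45.0, sex="W", genotype="E4minus",
                       true_iapf=10.25, true_alpha_power=1.0)


def make_split_plot(rng, n_per_cell=3, n_within=5, effects=None):
    """Balanced 2x2-between / n_within-level-within toy dataset."""
    effects = effects or {}
    rows = []
    si = 0
    for g in ("gm", "gp"):
        for a in ("young", "old"):
            for _ in range(n_per_cell):
                base = rng.normal(0, 1.0)
                for w in range(n_within):
                    y = base + rng.normal(0, 1.0)
                    y += effects.get("genotype", 0.0) * (g == "gp")
                    y += effects.get("age_group", 0.0) * (a == "old")
                    y += effects.get("band", 0.0) * w
                    y += effects.get("genotype:band", 0.0) * w * (g == "gp")
                    rows.append((f"s{si:03d}", g, a, f"b{w}", y))
                si += 1
    return pd.DataFrame(rows, columns=["subject", "genotype", "age_group", "band", "value"])


@pytest.fixture
def split_plot_factory():
    return make_split_plot
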