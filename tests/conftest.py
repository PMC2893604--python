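import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pripper as pp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_corpus():
    """~60 positives worth of synthetic proteins with planted motifs."""
    proteins, positive_sites = pp.generate_synthetic_corpus(50, seed=11)
    return proteins, positive_sites


@pytest.fixture(scope="session")
def separable_toyset():
    """Linearly separable toy dataset: positives DEVD|GS context, negatives
    unrelated AAAD|AA windows (both keep D at P1)."""
    geom = pp.WindowGeometry(4, 2)
    pos = [f"{a}EVDGS" for a in "DILVWM"] + [f"DE{a}DGA" for a in "VALIST"]
    neg = [f"AAAD{a}W" for a in "AVLIKR"] + [f"KK{a}DPP" for a in "GASTNQ"]
    windows = pos + neg
    y = np.array([1] * len(pos) + [-1] * len(neg))
    return pp.LabeledDataset(
        X=pp.encode_windows(windows),
        y=y,
        geometry=geom,
        windows=windows,
        provenance="separable-toy",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
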