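import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ftirstress as ft

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def recovery_raw() -> ft.SpectrumSet:
    """Raw simulated set under the default recovery design (fixed seed)."""
    return ft.simulate_set(ft.study_design(seed=0))


@pytest.fixture(scope="session")
def recovery_pre(recovery_raw) -> ft.SpectrumSet:
    return ft.preprocess_set(recovery_raw)


@pytest.fixture(scope="session")
def recovery_lda(recovery_pre) -> ft.LdaModel:
    split = ft.split_set(recovery_pre, 0.6, seed=5)
    return ft.lda_fit(recovery_pre, split)


@pytest.fixture(scope="session")
def recovery_discovery(recovery_pre, recovery_lda) -> ft.DiscoveryResult:
    return ft.discover_markers(recovery_pre, recovery_lda)


def flat_set(values: np.ndarray, labels=None, **meta_flags) -> ft.SpectrumSet:
    """Helper: build a set from a (n, 3601) matrix with optional labels."""
    n = values.shape[0]
    meta = pd.DataFrame({"spectrum_id": [f"s{i}" for i in range(n)]})
    if labels is not None:
        meta["class_label"] = labels
    for k, v in meta_flags.items():
        meta[k] = v
    return ft.SpectrumSet(values, meta)
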