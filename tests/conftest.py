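from datetime import datetime

import numpy as np
import pytest

from actitraj import synth
from actitraj.signal import extract_features


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced annotated corpus (8 children, 5-min sessions)."""
    return synth.simulate_annotated_corpus(n_subjects=8, session_s=300, seed=3)


def make_windows(label: str, n: int, seed: int = 0, params=None):
    """Feature windows of one class, as (features, label) LabelledWindows."""
    p = params or synth.DEFAULT_CLASS_PARAMS[label]
    out = []
    for i in range(n):
        xyz = synth.simulate_window_signal(p, 15, 30, seed=seed * 10_000 + i)
        f = extract_features(
            xyz, 30, subject_id=f"T{i % 2}", window_index=i,
            window_start=datetime(2021, 5, 3, 9),
        )
        out.append(synth.LabelledWindow(features=f, label=label, subject_id=f"T{i % 2}"))
    return out


@pytest.fixture(scope="session")
def separable_corpus():
    """SED vs RUN only: disjoint VM-SD ranges, perfectly learnable."""
    return make_windows("SED", 40, seed=1) + make_windows("RUN", 40, seed=2)
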