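import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from freqtag.containers import EpochSet
from freqtag.montage import Montage, standard_montage


@pytest.fixture(scope="session")
def montage32():
    return standard_montage(32)


@pytest.fixture(scope="session")
def montage16():
    return standard_montage(16)


def sphere_montage(n: int, seed: int = 0) -> Montage:
    """Ad-hoc all-scalp montage with n well-spread unit-sphere positions
    on the upper hemisphere."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts[:, 2] = np.abs(pts[:, 2])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return Montage(labels=[f"E{i}" for i in range(n)], positions=pts)


def make_epochs(
    data: np.ndarray,
    sfreq: float,
    montage: Montage,
    conditions=None,
    t_start_ms: float = -200.0,
) -> EpochSet:
    """EpochSet around a raw (trials, channels, samples) array."""
    n_tr, _, n_sm = data.shape
    step = 1000.0 / sfreq
    times = t_start_ms + step * np.arange(n_sm)
    if conditions is None:
        conditions = np.array(["TS", "PS", "NS"] * n_tr)[:n_tr]
    return EpochSet(
        data=data,
        times=times,
        conditions=np.asarray(conditions),
        montage=montage,
        sfreq=sfreq,
    )
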