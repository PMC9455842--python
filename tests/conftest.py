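import numpy as np
import pandas as pd
import pytest

from memdecode.io_formats import EpochSet, Montage, default_montage
from memdecode.sourceloc import build_leadfield, make_source_grid


@pytest.fixture(scope="session")
def montage62() -> Montage:
    return default_montage()


@pytest.fixture(scope="session")
def small_montage(montage62) -> Montage:
    """Eight well-spread channels of the shipped cap (fast tests)."""
    keep = ["Fp1", "Fp2", "C3", "C4", "Pz", "Oz", "T7", "T8"]
    idx = [montage62.index(ch) for ch in keep]
    return Montage(labels=tuple(keep), positions=montage62.positions[idx])


@pytest.fixture(scope="session")
def small_leadfield(small_montage):
    return build_leadfield(small_montage, grid=make_source_grid(60), n_terms=40)


@pytest.fixture(scope="session")
def leadfield162(montage62):
    return build_leadfield(montage62, n_sources=162)


def make_epochs(
    data: np.ndarray,
    fs: float = 250.0,
    t0_offset_ms: float = -1000.0,
    labels=None,
) -> EpochSet:
    n = data.shape[0]
    if labels is None:
        labels = np.array(["unlabeled"] * n, dtype=object)
    meta = pd.DataFrame({"word_id": np.arange(1, n + 1), "phase": "encoding", "is_old": True})
    return EpochSet(
        data=data, fs=fs, t0_offset_ms=t0_offset_ms, labels=np.asarray(labels, object), meta=meta
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
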