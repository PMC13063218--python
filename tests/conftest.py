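import numpy as np
import pytest

from mlpcalr import SpectraSet, SpectrumRecord, WavelengthGrid, default_bone_config, generate_dataset

STRATUM = ("micronir", "skull")


@pytest.fixture(scope="session")
def small_stratum() -> SpectraSet:
    """Two-class synthetic stratum small enough for repeated refits."""
    cfg = default_bone_config("micronir", n_channels=30, n_per_class=10, seed=1)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def medium_stratum() -> SpectraSet:
    """Forty-specimen stratum matching the study's training-set size."""
    cfg = default_bone_config("micronir", n_channels=30, n_per_class=20, seed=3)
    return generate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_toy_set(matrix, labels=None, grid_wl=None, replicate_sets=None) -> SpectraSet:
    """Build a SpectraSet where each row of ``matrix`` is one specimen mean,
    or — with ``replicate_sets`` — a list of per-specimen replicate blocks."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    m = matrix.shape[1]
    wl = np.arange(1, m + 1) * 100.0 if grid_wl is None else np.asarray(grid_wl, float)
    grid = WavelengthGrid("toy", wl)
    records = []
    for i, row in enumerate(matrix):
        label = None if labels is None else int(labels[i])
        if replicate_sets is None:
            reps = [row]
        else:
            reps = replicate_sets[i]
        for k, r in enumerate(reps, start=1):
            records.append(
                SpectrumRecord(f"S{i:03d}", "skull", label, "toy", "s1", k, np.asarray(r, float))
            )
    return SpectraSet(grid, records)
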