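import numpy as np
import pytest

from halomet.halogens import classify_table
from halomet.simulate import GeneratorConfig, generate
from halomet.spectra import MsmsSpectrum


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark (seed 42) with halogen calls precomputed."""
    cfg = GeneratorConfig(seed=42)
    table, truth = generate(cfg)
    calls = classify_table(table)
    return cfg, table, truth, calls


@pytest.fixture(scope="session")
def noiseless_dataset():
    cfg = GeneratorConfig(seed=42).noiseless()
    table, truth = generate(cfg)
    return cfg, table, truth


def random_spectrum(
    rng: np.random.Generator,
    n_peaks: int,
    precursor: float | None = None,
    mz_range=(80.0, 500.0),
) -> MsmsSpectrum:
    mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
    while np.any(np.diff(mz) <= 0):
        mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
    return MsmsSpectrum(
        precursor_mz=precursor if precursor is not None else float(rng.uniform(400, 900)),
        mz=mz,
        intensity=rng.uniform(1.0, 100.0, size=n_peaks),
    )
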