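import numpy as np
import pandas as pd
import pytest

from ramanphen.spectra_io import Spectrum, SpectrumSet


@pytest.fixture
def rng():
    return np.random.default_rng(20241)


@pytest.fixture
def small_grid():
    return np.arange(400.0, 1801.0, 10.0)


@pytest.fixture
def toy_set(small_grid, rng):
    """Six spectra, two conditions, shared grid, mild noise."""
    spectra = []
    meta = []
    for i in range(6):
        cond = "a" if i < 3 else "b"
        base = np.exp(-0.5 * ((small_grid - 1000.0) / 50.0) ** 2)
        bump = np.exp(-0.5 * ((small_grid - 1520.0) / 20.0) ** 2)
        y = base + (2.0 if cond == "b" else 1.0) * bump + 0.01 * rng.normal(size=small_grid.size)
        spectra.append(Spectrum(small_grid, y, sample_id=f"s{i}"))
        meta.append({"sample_id": f"s{i}", "condition": cond})
    return SpectrumSet(spectra, pd.DataFrame(meta))
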