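import numpy as np
import pytest

import leafspec as ls
from leafspec.spectra import WavelengthGrid, window_average

#: small grid for tests that don't need the full 2151-point resolution
SMALL_GRID = WavelengthGrid.regular(350.0, 2500.0, 50.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def demo_study():
    """One desk-scale synthetic study, binned to 10 nm, shared across tests."""
    cfg = ls.demo_config(seed=7)
    lib, ext = ls.generate_study(cfg)
    bin10 = lambda L: L.map_spectra(lambda s: window_average(s, 10.0))
    return bin10(lib), {k: bin10(v) for k, v in ext.items()}


@pytest.fixture(scope="session")
def demo_library(demo_study):
    return demo_study[0]


@pytest.fixture()
def tiny_library(rng):
    """Three-sample library on a coarse grid with one missing trait value."""
    samples = []
    for i in range(3):
        vals = np.clip(0.3 + 0.05 * rng.standard_normal(SMALL_GRID.n_points), 0, 1)
        traits = {t: v for t, v in zip(ls.TRAITS, [2.5, 0.2, 1.5, 0.3, 0.5, 0.2, 75.0, 400.0, 50.0])}
        if i == 1:
            traits["CHL"] = np.nan
        samples.append(
            ls.Sample(
                id=f"s{i}", species="Maize", dataset="d1", year=2019,
                environment="field",
                spectrum=ls.Spectrum(SMALL_GRID, vals),
                traits=ls.TraitVector.from_dict(traits),
            )
        )
    return ls.SpectralLibrary(samples, provenance="tiny fixture")
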