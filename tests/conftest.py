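import numpy as np
import pytest

from plumagediv.spectra import CANONICAL_GRID, PATCHES, PatchSpectraSet, Spectrum
from plumagediv.visual import ConeSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def cones():
    return ConeSet()


def gaussian_spectrum(mu, h, species="sp", sex="male", patch="crown", base=0.05, width=40.0):
    r = base + h * np.exp(-((CANONICAL_GRID - mu) ** 2) / (2 * width**2))
    return Spectrum(CANONICAL_GRID, np.clip(r, 1e-5, 1.0), species, sex, patch)


@pytest.fixture
def random_spectra_set(rng):
    """Four species, both sexes, all six patches, single specimens."""
    grouped = {}
    for sp in ["spA", "spB", "spC", "spD"]:
        for sex in ("male", "female"):
            for patch in PATCHES:
                mu = rng.uniform(350, 650)
                h = rng.uniform(0.2, 0.8)
                grouped[(sp, sex, patch)] = [gaussian_spectrum(mu, h, sp, sex, patch)]
    return PatchSpectraSet(grouped)
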