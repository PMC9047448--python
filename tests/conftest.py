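import numpy as np
import pytest

from msicelltyper import recognizer, synthetic_data
from msicelltyper.preprocess import BinGrid


@pytest.fixture(scope="session")
def panel():
    return synthetic_data.default_panel()


@pytest.fixture(scope="session")
def profiles(panel):
    """The study conditions: 14 cell-line profiles at separation 1.0."""
    return synthetic_data.make_profiles(14, panel, separation=1.0, seed=1)


@pytest.fixture(scope="session")
def library(profiles, panel):
    """Synthetic single-cell library: 14 classes × 16 cells, noise CV 0.05."""
    return synthetic_data.synthetic_library(
        profiles, cells_per_class=16, panel=panel, noise_cv=0.05, seed=1
    )


@pytest.fixture(scope="session")
def cellline_model(library):
    return recognizer.fit_model(library, level="cell_line")


@pytest.fixture(scope="session")
def grid():
    return BinGrid()


@pytest.fixture(scope="session")
def small_tissue(profiles, panel):
    """32×32 tissue image of LINE_01 with a 30% necrotic core."""
    return synthetic_data.synth_tissue_image(
        profiles[0], necrotic_fraction=0.3, panel=panel, size=(32, 32),
        noise_cv=0.05, seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
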