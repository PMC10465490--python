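import numpy as np
import pytest

from barcodewga.barcodes import BarcodeConstraints, BarcodeSet, design_barcodes


@pytest.fixture(scope="session")
def designed_set() -> BarcodeSet:
    """The default 6-mer, distance-3 design (shared; design is deterministic)."""
    return design_barcodes(BarcodeConstraints())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
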