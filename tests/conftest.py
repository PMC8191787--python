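import numpy as np
import pytest

from splintseq.barcodes import generate_code


@pytest.fixture(scope="session")
def code173():
    """The full 173-barcode reference code (96 mRNA + 77 miRNA targets)."""
    genes = [f"mRNA{i:02d}" for i in range(96)] + [f"miR{i:02d}" for i in range(77)]
    return generate_code(8, 3, genes=genes)


@pytest.fixture(scope="session")
def small_code():
    return generate_code(8, 3, genes=[f"g{i}" for i in range(12)])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
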