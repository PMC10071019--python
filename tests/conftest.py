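import numpy as np
import pytest
from hypothesis import settings

from cyp2cphase.genotypes import GenotypeMatrix
from cyp2cphase.panel import cyp2c_only_panel, default_panel, four_snp_panel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def panel6():
    return default_panel()


@pytest.fixture
def panel4():
    return four_snp_panel()


@pytest.fixture
def panel2():
    return cyp2c_only_panel()


@pytest.fixture
def toy_matrix(panel2):
    """Three samples over the 2-SNP panel: (T/T,G/G), (C/T,G/G), (C/T,G/A)."""
    return GenotypeMatrix(
        ["s1", "s2", "s3"], np.array([[2, 0], [1, 0], [1, 1]]), panel2
    )


def make_matrix(panel, dosages, prefix="s"):
    dosages = np.asarray(dosages)
    ids = [f"{prefix}{i + 1}" for i in range(len(dosages))]
    return GenotypeMatrix(ids, dosages, panel)


@pytest.fixture
def make_matrix_fn():
    return make_matrix
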