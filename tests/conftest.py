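import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from xkmir.synth import GeneratorConfig


@pytest.fixture
def small_cfg():
    return GeneratorConfig(
        seed=11,
        n_mirnas=3,
        mirna_length_range=(21, 21),
        gc_range=(0.4, 0.7),
        n_plant_transcripts=8,
        n_human_utrs=8,
        transcript_length=300,
        utr_length=250,
        sites_per_mirna=2,
        n_genes=120,
        n_samples=60,
        n_modules=2,
        module_size_range=(12, 16),
        n_terms=15,
        term_size_range=(8, 20),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])


def random_protein(rng, n):
    return "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, n)])
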