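import numpy as np
import pandas as pd
import pytest

from misphe.simulate import SimConfig, default_trna_loci, generate_proteome


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced dataset: quick to generate, still exercises every event type."""
    return SimConfig(
        seed=11,
        n_proteins=40,
        n_substitutions=20,
        n_oxmet_decoys=4,
        n_val3ox_decoys=4,
        n_transcripts=12,
        cds_length_codons=(100, 160),
    )


@pytest.fixture(scope="session")
def small_proteome(small_config) -> dict[str, str]:
    return generate_proteome(small_config)


@pytest.fixture(scope="session")
def trna_loci() -> pd.DataFrame:
    return default_trna_loci()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
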