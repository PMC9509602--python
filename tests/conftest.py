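import numpy as np
import pandas as pd
import pytest

from urotag import synthdata, tagdb


@pytest.fixture(scope="session")
def small_taxonomy() -> pd.DataFrame:
    return synthdata.make_taxonomy(3, 8, 30, seed=11)


@pytest.fixture(scope="session")
def small_genomes(small_taxonomy) -> dict[str, str]:
    return synthdata.make_genomes(
        small_taxonomy, length_mean=60_000, seed=12, planted_sites=(20, 120)
    )


@pytest.fixture(scope="session")
def primary_db(small_genomes, small_taxonomy) -> tagdb.TagDatabase:
    return tagdb.build_tagdb(small_genomes, small_taxonomy)


@pytest.fixture(scope="session")
def small_design(small_taxonomy) -> synthdata.PairedDesign:
    return synthdata.make_paired_design(
        list(small_taxonomy["species_id"]), n_subjects=6, seed=13, sample_sd=0.4
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
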