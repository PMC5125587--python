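import pandas as pd
import pytest

from codonbias import (
    GeneratorSpec,
    generate,
    load_table1_fixture,
    load_table2_fixture,
)


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    """Packaged per-strain index table (46 ZIKV polyprotein CDSs)."""
    return load_table1_fixture().frame


@pytest.fixture(scope="session")
def table2():
    """Packaged 59-codon RSCU vectors: ZIKV pool and its three hosts."""
    return load_table2_fixture()


@pytest.fixture(scope="session")
def small_pool():
    """A small deterministic synthetic strain pool shared across tests."""
    return generate(GeneratorSpec(seed=2016, n_sequences=6, length_codons=400))
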