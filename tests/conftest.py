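import numpy as np
import pandas as pd
import pytest

from d2finemap import io as fio
from d2finemap.linkage import GenotypeTable


@pytest.fixture(scope="session")
def family_fixture():
    """Summarized F3 families of the fine-mapping cross (one row per batch)."""
    return fio.load_f3_family_fixture()


@pytest.fixture(scope="session")
def haplotype_fixture():
    """Allele matrix of three tall and three dwarf inbred lines, 12 loci."""
    return fio.load_haplotype_fixture()


@pytest.fixture(scope="session")
def tift_table():
    """Synthetic 23-plant informative set (one crossover per plant)."""
    return fio.load_genotype_fixture("tift")


@pytest.fixture(scope="session")
def pt732b_table():
    """Synthetic 16-plant informative set with two marker clusters."""
    return fio.load_genotype_fixture("pt732b")


def make_table(calls: dict[str, list[str]], modes: dict[str, str] | None = None,
               plants: list[str] | None = None) -> GenotypeTable:
    """Small genotype-table builder for tests."""
    df = pd.DataFrame(calls)
    df.index = plants or [f"p{i}" for i in range(len(df))]
    modes = modes or {c: "codominant" for c in df.columns}
    return GenotypeTable(df, modes)
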