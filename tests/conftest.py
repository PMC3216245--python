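import numpy as np
import pytest

import agalchap as ac
from agalchap.pssm import PssmParams, build_pssm


@pytest.fixture(scope="session")
def table1():
    return ac.load_fixture_table("table1")


@pytest.fixture(scope="session")
def table2():
    return ac.load_fixture_table("table2")


@pytest.fixture(scope="session")
def score_table():
    return ac.load_score_table()


@pytest.fixture(scope="session")
def mixed_profile():
    """40-position profile spanning weak to near-total conservation."""
    return ac.GeneratingProfile.from_conservation(
        np.linspace(0.3, 0.95, 40), seed=7
    )


@pytest.fixture(scope="session")
def small_pssm(mixed_profile):
    """PSSM built from a 13-sequence synthetic alignment."""
    aln = ac.sample_alignment(mixed_profile, 13, gap_rate=0.05, seed=3)
    return build_pssm(aln)


@pytest.fixture()
def toy_fasta(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(
        ">query\nACDEFGHIKL\n>homolog1\nACDEFGHIKL\n>homolog2\nACDEYGHIKV\n"
    )
    return path
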