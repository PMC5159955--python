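import numpy as np
import pytest

from msacontact import (
    ContactModel,
    SyntheticMSASpec,
    encode_sequences,
    generate_msa,
    make_toy_structure,
)


@pytest.fixture(scope="session")
def planted_spec():
    return SyntheticMSASpec(
        L=24, n=400, planted_pairs=((2, 10), (5, 17), (12, 22)),
        coupling=0.9, gap_rate=0.05, seed=11,
    )


@pytest.fixture(scope="session")
def planted_msa(planted_spec):
    msa, truth = generate_msa(planted_spec)
    return msa, truth


@pytest.fixture(scope="session")
def fitted_results(planted_msa):
    msa, _ = planted_msa
    return ContactModel(msa).fit()


@pytest.fixture(scope="session")
def toy_structure(tmp_path_factory):
    """A 24-residue toy chain realising three separated contacts."""
    contacts = [(1, 9), (4, 16), (11, 21)]
    pdb = make_toy_structure(24, contacts, seed=3, sequence="AG" + "A" * 22)
    path = tmp_path_factory.mktemp("pdb") / "toy.pdb"
    path.write_text(pdb)
    return path, contacts, "AG" + "A" * 22


@pytest.fixture
def tiny_msa():
    return encode_sequences(["ACDEFG", "ACDEFG", "GGGGGG"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
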