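import pytest

from ablint import compile_reference
from ablint.synthetic import SyntheticSpec, generate_sequences, make_toy_germline_set


@pytest.fixture(scope="session")
def default_ref():
    return compile_reference()


@pytest.fixture(scope="session")
def toy_germline():
    return make_toy_germline_set(seed=1)


@pytest.fixture(scope="session")
def small_cohort(toy_germline):
    """Ten paired units with planted motifs plus the exact hit ledger."""
    germ, germ_ledger = toy_germline
    spec = SyntheticSpec(seed=7, n_units=10, paired=True)
    units, ledger = generate_sequences(spec, germ, germ_ledger)
    return units, ledger
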