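import numpy as np
import pytest

from tirnakit.feature_quant import UtrContext
from tirnakit.fold_engine import BuiltinEngine, RnaSequence
from tirnakit.synthetic_fixtures import SimSpec, make_toy_utr

# toy study conditions shared across the suite: a 60-nt UTR with an embedded
# consensus SD site plus a 50-nt CDS prefix (110-nt folding context)
TOY_UTR_SEED = 11


@pytest.fixture(scope="session")
def engine():
    return BuiltinEngine()


@pytest.fixture(scope="session")
def toy_utr():
    return make_toy_utr(SimSpec(utr_length=60, seed=TOY_UTR_SEED))


@pytest.fixture(scope="session")
def toy_context(toy_utr, engine):
    utr, cds = toy_utr
    return UtrContext.build(utr, cds, engine=engine)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
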