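import numpy as np
import pytest

from mtlineage.panel import assign_pools, design_panel
from mtlineage.reference import MtReference, load_packaged_reference, load_regions


@pytest.fixture(scope="session")
def reference():
    return load_packaged_reference()


@pytest.fixture(scope="session")
def regions():
    return load_regions()


@pytest.fixture(scope="session")
def default_panel(reference):
    """The documented default design: 108 amplicons, 4 pools."""
    return assign_pools(design_panel(reference), 4)


@pytest.fixture()
def toy_reference():
    """A 300 bp circle, non-repetitive enough for unique 22-mer primers."""
    rng = np.random.default_rng(123)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    return MtReference(name="toy", sequence=seq)
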