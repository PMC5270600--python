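import pytest

import pairprop as pp
from pairprop.kernel_svm import SvmGridConfig

SMALL_SVM = SvmGridConfig(
    gamma_grid=[0.5, 2.0, 8.0], c_grid=[0.25, 1.0, 4.0], cv_folds=3
)


@pytest.fixture(scope="session")
def toy_graphs():
    return {g.mol_id: g for g in pp.toy_molecules()}


@pytest.fixture(scope="session")
def toy_descriptors(toy_graphs):
    return {name: pp.build_descriptor(g) for name, g in toy_graphs.items()}


@pytest.fixture(scope="session")
def pyridine(toy_graphs):
    return toy_graphs["pyridine"]


@pytest.fixture(scope="session")
def ethane(toy_graphs):
    return toy_graphs["ethane"]


@pytest.fixture(scope="session")
def default_weights():
    return pp.WeightVector()


@pytest.fixture
def small_svm_config():
    return SMALL_SVM
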