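import matplotlib

matplotlib.use("Agg")

import pytest

from mospec.fixtures import make_fixture


@pytest.fixture
def two_lovers():
    return make_fixture("TwoLovers")


@pytest.fixture
def seir():
    return make_fixture("SEIR")


@pytest.fixture
def toy():
    return make_fixture("ConstrainedToy")


@pytest.fixture(params=["TwoLovers", "SEIR", "ConstrainedToy"])
def any_fixture(request):
    return make_fixture(request.param)
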