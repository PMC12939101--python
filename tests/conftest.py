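import pytest
from hypothesis import settings

from meatrba import assess_benefits, assess_risks, build_heatmap, load_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_ds():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_benefits(fixture_ds):
    return assess_benefits(*fixture_ds)


@pytest.fixture(scope="session")
def fixture_risks(fixture_ds):
    return assess_risks(*fixture_ds)


@pytest.fixture(scope="session")
def fixture_matrix(fixture_ds, fixture_benefits, fixture_risks):
    ds = fixture_ds
    return build_heatmap(fixture_benefits, fixture_risks, ds.products,
                         ds.components, ds.config)
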