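import hypothesis
import pytest

from rnacarbon import datasets
from rnacarbon.community import TaxonRecord, TrophicLabel
from rnacarbon.mixing import EndMember

hypothesis.settings.register_profile(
    "ci", hypothesis.settings(derandomize=True, deadline=None, max_examples=100)
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def rifle_endmembers():
    return datasets.rifle_endmembers()


@pytest.fixture(scope="session")
def rifle_sample():
    return datasets.rifle_sample()


@pytest.fixture(scope="session")
def dic():
    return EndMember("DIC", -157.7, 1.7, 1)


@pytest.fixture(scope="session")
def doc():
    return EndMember("DOC", -231.0, 1.7, 1)


@pytest.fixture(scope="session")
def soc():
    return EndMember("SOC", -504.4, 173.0, 20)


@pytest.fixture(scope="session")
def plant():
    return EndMember("plant", -55.1, 61.8, 8)


@pytest.fixture(scope="session")
def table1():
    return datasets.table1()


@pytest.fixture
def toy_records():
    """Four taxa: 0.4 auto, 0.3 het, 0.1 auto, 0.2 unknown (sums to 1)."""
    return [
        TaxonRecord("t1", "A", 0.4, 96.0, TrophicLabel.LITHOAUTOTROPH),
        TaxonRecord("t2", "B", 0.3, 99.0, TrophicLabel.HETEROTROPH),
        TaxonRecord("t3", "C", 0.2, None, TrophicLabel.UNKNOWN),
        TaxonRecord("t4", "D", 0.1, 94.0, TrophicLabel.LITHOAUTOTROPH),
    ]
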