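import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from hetsel import datasets  # noqa: E402
from hetsel.io_annotation import extract_orf, translate  # noqa: E402
from hetsel.specificity import partition_classes  # noqa: E402


@pytest.fixture(scope="session")
def hetc_matrix():
    return datasets.incompatibility_matrix()


@pytest.fixture(scope="session")
def hetc_classes(hetc_matrix):
    return partition_classes(hetc_matrix)


@pytest.fixture(scope="session")
def hetc_protein_table():
    return datasets.protein_variant_table()


@pytest.fixture(scope="session")
def hetc_alignment():
    return datasets.nucleotide_alignment()


@pytest.fixture(scope="session")
def hetc_annotation():
    return datasets.ANNOTATION


@pytest.fixture(scope="session")
def hetc_orf(hetc_alignment, hetc_annotation):
    return extract_orf(hetc_alignment, hetc_annotation)


@pytest.fixture(scope="session")
def hetc_proteins(hetc_orf):
    return translate(hetc_orf)
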