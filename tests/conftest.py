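import pytest

from polyseg.datasets import (
    load_a12359_counts,
    load_four_band_phenotypes,
    load_zebra_counts,
)
from polyseg.inference import standard_hypotheses


@pytest.fixture(scope="session")
def hypotheses():
    return standard_hypotheses()


@pytest.fixture(scope="session")
def zebra():
    counts, archived = load_zebra_counts()
    return counts, archived


@pytest.fixture(scope="session")
def a12359():
    counts, archived = load_a12359_counts()
    return counts, archived


@pytest.fixture(scope="session")
def four_band():
    return load_four_band_phenotypes()


@pytest.fixture()
def tiny_table(tmp_path):
    """3 progeny + 1 parent, 2 markers, one missing cell."""
    path = tmp_path / "tiny.tsv"
    path.write_text(
        "sample\tmk1\tmk2\n"
        "P\tAa\tAa\n"
        "s1\tAa\tAA\n"
        "s2\tAA\tM\n"
        "s3\taa\tAa\n"
    )
    return path
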