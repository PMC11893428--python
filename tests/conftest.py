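import pytest

from nanolibkit.fixtures import GERMLINES, load_frameworks, load_references
from nanolibkit.simdata import RepertoireConfig, simulate_repertoire


@pytest.fixture(scope="session")
def references():
    return load_references()


@pytest.fixture(scope="session")
def frameworks():
    return load_frameworks()


@pytest.fixture(scope="session")
def ref_by_name(references):
    return {r.name: r for r in references}


@pytest.fixture(scope="session")
def small_repertoire():
    """200 sequences per germline at the default study rates, with truth."""
    records, truth = [], []
    for gi, g in enumerate(GERMLINES):
        r, t = simulate_repertoire(
            RepertoireConfig(germline=g, n=200, seed=7 + gi)
        )
        records += r
        truth += t
    return records, truth
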