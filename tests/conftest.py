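import pytest
from hypothesis import HealthCheck, settings

from mzhdf import SynthParams, load_bundled_catalog, synth_run

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return load_bundled_catalog()


@pytest.fixture(scope="session")
def small_run():
    """5 survey scans, 2 MS2 children each: the default structural fixture."""
    return synth_run(SynthParams(n_ms1=5, peptides_per_ms1=2, seed=42))


@pytest.fixture(scope="session")
def ms3_run():
    """Run with a full MS1→MS2→MS3 scan-tree stage."""
    return synth_run(SynthParams(n_ms1=3, peptides_per_ms1=2, max_ms_level=3, seed=7))


TOY_OBO = """\
format-version: 1.2
data-version: toy-1

[Term]
id: MS:1000810
name: mass chromatogram

[Term]
id: MS:1000628
name: basepeak chromatogram
is_a: MS:1000810 ! mass chromatogram
"""


@pytest.fixture()
def toy_obo_text():
    return TOY_OBO
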