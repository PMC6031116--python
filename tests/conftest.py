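import pytest

from sipscope import make_study_fixture


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """One synthetic study (genomes + gradients + coverages + truth), seed 3."""
    out = tmp_path_factory.mktemp("study")
    truth = make_study_fixture(out, seed=3)
    return out, truth
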