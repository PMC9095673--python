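import pytest

from degronon.semsim import GoDag
from degronon.synth import SynthConfig


@pytest.fixture
def chain_dag() -> GoDag:
    """root <-is_a- a <-is_a- b, all biological_process."""
    terms = ["root", "a", "b"]
    edges = [("a", "root", "is_a"), ("b", "a", "is_a")]
    ns = {t: "biological_process" for t in terms}
    return GoDag(terms, edges, ns)


@pytest.fixture
def small_cfg() -> SynthConfig:
    return SynthConfig(
        seed=7,
        n_substrates=5,
        n_partners_per_substrate=8,
        n_datasets=5,
        n_modules=2,
        module_size=8,
        n_background=50,
    )
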