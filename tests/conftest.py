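import pytest

from ltrtrace.simulate import SimConfig, make_element, simulate_sample


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def element(default_config):
    """A full-size synthetic element (5216 nt, 349 nt LTRs)."""
    return make_element(default_config)


@pytest.fixture(scope="session")
def sample20():
    """One complete sample: 20 canonical insertions, 30x, 1% error."""
    return simulate_sample(SimConfig(seed=1, n_insertions=20))


@pytest.fixture(scope="session")
def quantified20(sample20):
    from ltrtrace.quantify import quantify_sample

    estimate, snps, profile = quantify_sample(
        sample20.reads,
        sample20.library,
        sample20.element.id,
        sample20.scg_ids,
        mask=sample20.mask,
    )
    return estimate, snps, profile
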