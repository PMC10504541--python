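import pytest

from bflows import WorldSpec, duo_fixture, generate_world


@pytest.fixture
def duo():
    return duo_fixture()


@pytest.fixture
def make_world():
    """Factory for small random worlds keyed by seed."""

    def _make(seed, **kwargs):
        params = dict(n_regions=4, n_sectors=5, food_sector_ids=(0, 1))
        params.update(kwargs)
        return generate_world(WorldSpec(seed=seed, **params))

    return _make
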