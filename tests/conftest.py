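import pytest

from teharm import GenomicInterval, MutationProfile, SyntheticSpec, WindowGrid, simulate


@pytest.fixture
def toy_profiles():
    """Four small elements on a 30 bp consensus."""
    return [
        MutationProfile("e1", (2, 3, 7, 15), percent_identity=1 - 4 / 30),
        MutationProfile("e2", (7, 8), percent_identity=1 - 2 / 30),
        MutationProfile("e3", (), percent_identity=1.0),
        MutationProfile("e4", (1, 29, 30), percent_identity=1 - 3 / 30),
    ]


@pytest.fixture
def toy_grid():
    return WindowGrid(L=30, wsize=5)


@pytest.fixture
def small_dataset():
    """A small synthetic family with a strong planted signal."""
    spec = SyntheticSpec(
        N=30,
        L=120,
        wsize=10,
        planted_regions=(GenomicInterval(50, 69, "planted"),),
        mutation_rate=8.0,
        effect_size=40.0,
        noise_sd=4.0,
        seed=7,
    )
    return simulate(spec)
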