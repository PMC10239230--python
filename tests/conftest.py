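import numpy as np
import pytest

from birdquiz.catalog import SimilarRef, Species, SpeciesCatalog, builtin_catalog


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


def make_tiny_catalog(n=5, similar_pairs=()):
    """n species Sp01..Spnn with optional similar pairs [(i, j, level), ...]
    given as 1-based ids."""
    sims = {}
    for i, j, level in similar_pairs:
        sims.setdefault(i, []).append((j, level))
        sims.setdefault(j, []).append((i, level))
    species = []
    for i in range(1, n + 1):
        species.append(
            Species(
                id=i,
                english_name=f"Species {i}",
                binomial=f"Genus species{i}",
                abbreviation=f"Sp{i:02d}",
                song_type="song",
                similar=tuple(
                    SimilarRef(f"Sp{j:02d}", level) for j, level in sims.get(i, [])
                ),
            )
        )
    return SpeciesCatalog(species)


@pytest.fixture
def tiny5():
    return make_tiny_catalog(5)


@pytest.fixture
def tiny6():
    # Sp02 and Sp03 are an E-level similar pair
    return make_tiny_catalog(6, similar_pairs=[(2, 3, "E")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
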