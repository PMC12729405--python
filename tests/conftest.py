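import pytest

from vhhkit.simulate import (
    GeneratorConfig,
    default_species_profiles,
    generate_repertoire,
    noise_free_profiles,
)

SPECIES = (
    "Vicugna pacos",
    "Camelus bactrianus",
    "Camelus dromedarius",
    "Lama glama",
)


@pytest.fixture(scope="session")
def default_repertoire():
    """Medium cohort at default generator settings (noise + decoys + dups)."""
    cfg = GeneratorConfig(
        seed=101,
        n_per_species={sp: 300 for sp in SPECIES},
        duplicate_rate=0.02,
        n_alphabetical=2,
        n_homopolymer=2,
    )
    return generate_repertoire(cfg)


@pytest.fixture(scope="session")
def clean_repertoire():
    """Cohort at default noise but without injected duplicates or decoys."""
    cfg = GeneratorConfig(
        seed=202,
        n_per_species={sp: 300 for sp in SPECIES},
        duplicate_rate=0.0,
        n_alphabetical=0,
        n_homopolymer=0,
    )
    return generate_repertoire(cfg)


@pytest.fixture(scope="session")
def noise_free_repertoire():
    """Zero substitution noise, no non-canonical cysteines, no decoys."""
    cfg = GeneratorConfig(
        seed=303,
        n_per_species={sp: 150 for sp in SPECIES},
        duplicate_rate=0.0,
        n_alphabetical=0,
        n_homopolymer=0,
        profiles=noise_free_profiles(),
    )
    return generate_repertoire(cfg)


@pytest.fixture(scope="session")
def default_profiles():
    return default_species_profiles()
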