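import numpy as np
import pytest

from amplidiv import SequenceEntry, SimulationConfig
from amplidiv.records import RANKS

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int, positions=None) -> str:
    """Substitute exactly n_subs distinct positions to different bases."""
    chars = list(seq)
    if positions is None:
        positions = rng.choice(len(chars), size=n_subs, replace=False)
    for pos in positions:
        options = [b for b in BASES if b != chars[pos]]
        chars[pos] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def entry(ident: str, bases: str, lineage=("",) * len(RANKS), multiplicity: int = 1) -> SequenceEntry:
    return SequenceEntry(id=ident, bases=bases, lineage=lineage, multiplicity=multiplicity)


@pytest.fixture(scope="session")
def separated_config() -> SimulationConfig:
    """3 families x 3 genera x 3 species with identity targets well
    separated from the 0.96/0.92/0.90 cutoffs, ~500 fragments."""
    return SimulationConfig(
        seed=101,
        n_families=3,
        genera_per_family=3,
        species_per_genus=3,
        within_species_identity=0.97,
        within_genus_identity=0.93,
        within_family_identity=0.905,
        across_family_identity=0.88,
        fragments_per_species=18,
        n_samples=40,
        short_fragment_rate=0.05,
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        n_families=2,
        genera_per_family=2,
        species_per_genus=2,
        fragments_per_species=5,
        n_samples=12,
    )
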