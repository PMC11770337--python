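import numpy as np
import pytest

from pottsbind.potts import Alphabet, PottsModel
from pottsbind.structure import align_slab_to_z
from pottsbind.synthetic import (SMALL_ALPHABET, PlantSpec, make_planted_tables,
                                 make_random_tables, make_toy_system)


@pytest.fixture(scope="session")
def small_alphabet():
    return SMALL_ALPHABET


@pytest.fixture(scope="session")
def random_tables(small_alphabet):
    return make_random_tables(4, small_alphabet, scale=1.0, seed=11)


@pytest.fixture(scope="session")
def random_model(random_tables):
    return PottsModel(tables=random_tables)


@pytest.fixture(scope="session")
def planted_tables(small_alphabet):
    return make_planted_tables(PlantSpec(n=4, alphabet=small_alphabet,
                                         planted_sequence="ACDE", gap=2.0, seed=5))


@pytest.fixture(scope="session")
def toy_conf():
    """Aligned 5-residue peptide over a small slab (session-cached)."""
    return align_slab_to_z(make_toy_system(5, slab_nx=6, slab_ny=6,
                                           slab_layers=2, seed=3))


@pytest.fixture(scope="session")
def tiny_energy_setup():
    """3-residue conformation + energy model over a 4-letter alphabet.

    Building full tables is the expensive step, so tests share one instance.
    """
    from pottsbind.energies import EnergyModel
    conf = align_slab_to_z(make_toy_system(3, slab_nx=5, slab_ny=5,
                                           slab_layers=2, seed=1))
    em = EnergyModel(conf, alphabet=Alphabet("ACKS"))
    tables = em.build_tables()
    return conf, em, tables
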