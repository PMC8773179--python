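import pytest

from gsis_screen import library_layout as ll
from gsis_screen import ssmd_hit_calling as shc
from gsis_screen import synthetic_screen as ss

SCREEN_SEED = 42


@pytest.fixture(scope="session")
def library521():
    return ss.make_synthetic_library(n_genes=521, seed=SCREEN_SEED)


@pytest.fixture(scope="session")
def plate_sets7(library521):
    return ll.assign_wells(library521, replicates=3, capacity=75, seed=SCREEN_SEED)


@pytest.fixture(scope="session")
def default_effects(library521):
    genes = [e.gene_symbol for e in library521]
    candidates = [g for g in genes if g not in ll.CONTROL_GENES and g != ll.NT_GENE]
    return ss.plant_effects(
        genes,
        n_up=23,
        n_down=68,
        viability_killed=candidates[:10],
        seed=SCREEN_SEED,
    )


@pytest.fixture(scope="session")
def default_screen(plate_sets7, default_effects):
    """One full default synthetic screen at the session seed."""
    measurements = ss.simulate_screen(
        plate_sets7, default_effects, ss.NoiseConfig(), seed=SCREEN_SEED
    )
    return measurements


@pytest.fixture(scope="session")
def default_scores(default_screen, plate_sets7):
    return shc.score_screen(default_screen, plate_sets7)


@pytest.fixture
def small_library():
    return ss.make_synthetic_library(n_genes=12, seed=7)
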