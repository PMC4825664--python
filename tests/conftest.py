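import pytest
from hypothesis import HealthCheck, settings

import strainkin as sk
from strainkin.simulate import as_rng

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def build_small_pop(seed: int = 1) -> sk.Population:
    """4 founders on 2x100 kb plus one self, clone, cross each.

    Rebuilt per request because deriving strains mutates the registry;
    session fixtures hand out a shared read-only instance.
    """
    rng = as_rng(seed)
    pop = sk.simulate_founders(sk.make_layout(2, 100_000, n_accessory=2), 4,
                               snp_density=0.005, het_rate=0.30, seed=rng)
    pop.derive(sk.PedigreeRecord("S1", "self", ("F01",)), rng)
    pop.derive(sk.PedigreeRecord("C1", "clone", ("F01",), n_mutations=29),
               rng)
    pop.derive(sk.PedigreeRecord("X1", "cross", ("F02", "F03")), rng)
    return pop


@pytest.fixture(scope="session")
def small_pop() -> sk.Population:
    return build_small_pop()


@pytest.fixture(scope="session")
def small_matrix(small_pop) -> sk.GenotypeMatrix:
    return sk.matrix_from_population(small_pop)


@pytest.fixture(scope="session")
def emitted_clean(small_pop, tmp_path_factory):
    """Noise-free emission of the small population (deterministic depths)."""
    out = tmp_path_factory.mktemp("emit_clean")
    return sk.emit_observables(small_pop, out, mean_depth=50,
                               depth_noise=0.0, seed=7)


@pytest.fixture(scope="session")
def family_pop() -> sk.Population:
    from strainkin.scenarios import clone_family_population
    return clone_family_population(21)


@pytest.fixture(scope="session")
def family_matrix(family_pop) -> sk.GenotypeMatrix:
    return sk.matrix_from_population(family_pop)
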