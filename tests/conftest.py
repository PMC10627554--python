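import numpy as np
import pytest

from headwater.demography import (
    ParameterDraw,
    ParameterPrior,
    build_capture_scenario,
    compile_demography,
)
from headwater.genotypes import GenotypeSnpMatrix


@pytest.fixture(scope="session")
def scenario3():
    return build_capture_scenario(3)


@pytest.fixture(scope="session")
def scenario3_draw(scenario3):
    """A fixed, mid-prior scenario-3 instantiation."""
    vals = {"t1": 2.0e6, "t2": 1.2e6, "t3": 5.0e5, "t4": 3.0e5, "db": 400.0}
    for b in ("Paraguacu", "Jequirica", "Almas", "Contas", "Almada"):
        vals[f"N_{b}"] = 4.0e4
    for b in ("Contas", "Almada", "Jequirica", "Almas"):
        vals[f"Nb_{b}"] = 400.0
    return ParameterDraw(3, vals)


def single_pop_demography(n_diploid_samples: int, ne: float):
    """One panmictic population, constant size."""
    from headwater.demography import (
        DemographicEvent,
        PopulationSpec,
        ScenarioModel,
    )

    model = ScenarioModel(
        scenario_id=99,
        populations=[PopulationSpec("pop", n_diploid_samples, "N")],
        events=[],
        priors=[ParameterPrior("N", "uniform", ne, ne)],
    )
    return compile_demography(model, ParameterDraw(99, {"N": ne}))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix():
    """Hand-written 3-locus, 2+2-individual genotype matrix."""
    geno = np.array(
        [[0, 1, 2, 2],
         [0, 0, 0, 0],
         [1, 1, 0, 2]], dtype=np.int8
    )
    return GenotypeSnpMatrix(
        geno,
        samples=["a1", "a2", "b1", "b2"],
        populations=["A", "A", "B", "B"],
    )
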