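import pytest

from gridsimplex.grid import (
    MeasurementTable,
    ResponseDef,
    build_grid,
    code_levels,
)
from gridsimplex.synthetic import SyntheticCaseConfig, generate_case


@pytest.fixture(scope="session")
def case_grid():
    """The 4 x 3 x 4 screening lattice (48 conditions)."""
    return build_grid(
        [
            code_levels([6.9, 7.2, 7.5, 7.8], name="pH"),
            code_levels([100, 150, 300], name="Load"),
            code_levels([2.5, 4.0, 6.0, 10.0], name="Conductivity"),
        ]
    )


@pytest.fixture(scope="session")
def response_defs():
    return (
        ResponseDef(name="Yield", goal="maximize", T=100.0, L=0.0, units="%"),
        ResponseDef(name="HCP", goal="minimize", T=30.0, U=3000.0, units="ppm"),
        ResponseDef(name="DNA", goal="minimize", T=50.0, U=2500.0, units="ppb"),
    )


@pytest.fixture(scope="session")
def synthetic_case():
    """Default noisy duplicated case study, fixed seed."""
    return generate_case(SyntheticCaseConfig(), seed=11)


@pytest.fixture(scope="session")
def noiseless_case():
    """Noise- and gap-free case: replicates identical to the truth surfaces."""
    cfg = SyntheticCaseConfig(
        yield_noise_sd=0.0, impurity_noise_cv=0.0, missing_fraction=0.0
    )
    return generate_case(cfg, seed=3)
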