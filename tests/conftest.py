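import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ddi_inputs():
    from transddi.datasets import load_metformin_ddi

    return load_metformin_ddi()


@pytest.fixture(scope="session")
def sa22():
    """Dosing-solution specific activity: 37 kBq/mL at 100 umol/L -> 22.2 dpm/pmol."""
    from transddi.uptake import SpecificActivity

    return SpecificActivity.from_solution(37.0, 100.0)


@pytest.fixture
def oct2_truth():
    """Noiseless OCT2 assay truth (Km 1608, Vmax 32918 as generating values)."""
    from transddi.synthetic import AssayTruth

    return AssayTruth(
        transporter="OCT2",
        km_true=1608.0,
        vmax_true=32918.0,
        control_fraction=1.0 / 17.0,
        protein_cv=0.0,
        noise_cv=0.0,
        seed=7,
    )
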