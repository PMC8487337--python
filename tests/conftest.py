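import numpy as np
import pytest

from ctpta import DosingRegimen, PKParameters, load_drug_spec


@pytest.fixture(scope="session")
def ct_spec():
    return load_drug_spec("ceftolozane")


@pytest.fixture(scope="session")
def tz_spec():
    return load_drug_spec("tazobactam")


@pytest.fixture
def regimen():
    return DosingRegimen(dose=2000.0, infusion_duration=1.0, interval=8.0, drug_label="ceftolozane")


@pytest.fixture
def two_cpt_params():
    return PKParameters(cl=5.0, v1=12.0, q=2.0, v2=6.0, k_in=0.3, k_out=0.6, fu_plasma=0.79)


def random_params(rng: np.random.Generator, one_compartment_fraction: float = 0.15) -> PKParameters:
    """A random valid parameter set spanning the plausible PK space."""
    q = 0.0 if rng.random() < one_compartment_fraction else rng.uniform(0.2, 10.0)
    return PKParameters(
        cl=rng.uniform(2.0, 30.0),
        v1=rng.uniform(5.0, 40.0),
        q=q,
        v2=rng.uniform(2.0, 30.0),
        k_in=rng.uniform(0.05, 2.0),
        k_out=rng.uniform(0.05, 2.0),
        fu_plasma=rng.uniform(0.5, 1.0),
    )
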