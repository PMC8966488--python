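import numpy as np
import pytest

from plastinorm import ModelParams, PopulationState


@pytest.fixture
def ref_params() -> ModelParams:
    """Reference parameterization: unit variances, A=0, B=-1, alpha=1,
    selection widths 20, heritability one, zero intercept-slope correlation."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def random_valid_params(rng: np.random.Generator, rho: float = 0.0) -> ModelParams:
    """A random parameter draw kept inside the model's validity region."""
    return ModelParams(
        A=rng.normal(0, 2),
        B=-float(rng.uniform(0.1, 5)),
        alpha=float(rng.uniform(0, 1.5)),
        omega_y2=float(rng.uniform(5, 60)),
        omega_b2=float(rng.uniform(5, 60)),
        sigma_n2=float(rng.uniform(0.3, 2.5)),
        sigma_ai2=float(rng.uniform(0.2, 1.5)),
        sigma_ei2=float(rng.uniform(0, 0.8)),
        sigma_ab2=float(rng.uniform(0.2, 1.5)),
        sigma_eb2=float(rng.uniform(0, 0.8)),
        rho_ib=rho,
    )


def random_state(rng: np.random.Generator) -> PopulationState:
    return PopulationState(float(rng.normal(0, 1.5)), float(rng.normal(-0.5, 0.5)))
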