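import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from gdcoil.relaxation import (ElectronSpinParams, OuterSphereParams,
                               RelaxationModel, SecondSphereParams,
                               kh2_20x_model, mb1_2_model)


@pytest.fixture
def kh2_model():
    return kh2_20x_model()


@pytest.fixture
def mb1_model():
    return mb1_2_model()


def random_model(rng: np.random.Generator) -> RelaxationModel:
    """A random admissible relaxation model (log-uniform over broad but
    physical ranges)."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return RelaxationModel(
        second_sphere=SecondSphereParams(
            q_ss=lu(0.5, 4.0), r_ss_A=lu(2.5, 5.0),
            tau_m_ss=lu(1e-10, 1e-7), tau_rg=lu(1e-9, 5e-8),
            tau_rl=lu(2e-11, 2e-9), s2=float(rng.uniform(0.05, 0.95))),
        outer_sphere=OuterSphereParams(a_A=lu(3.0, 6.0),
                                       d=lu(1e-10, 1e-8)),
        electron=ElectronSpinParams(delta2=lu(1e18, 1e20),
                                    tau_v=lu(5e-12, 1e-10)),
    )
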