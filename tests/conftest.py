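import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
hyp_settings.load_profile("ci")

from mixvpc.datamodel import (
    DoseEvent,
    MixtureParameters,
    Observation,
    ResidualSpec,
    SubjectData,
)
from mixvpc import structural_models as sm
from mixvpc import mixture_inference as mi


@pytest.fixture(scope="session")
def onecmt_params():
    """Single-component one-compartment population (the linear design's
    dominant subpopulation)."""
    return MixtureParameters(
        theta_component=[{"CL": 20.0}],
        theta_shared={"ka": 1.0, "V": 100.0},
        pmix=np.array([1.0]),
        omega={"CL": 0.09},
        sigma=ResidualSpec("proportional", prop_var=0.04),
    )


def make_subject(sid, eta_cl, seed, obs_times=(0.5, 1, 2, 4, 8, 12),
                 sigma=ResidualSpec("proportional", prop_var=0.04)):
    """One simulated subject from the linear design with known eta on CL."""
    rng = np.random.default_rng(seed)
    doses = [DoseEvent(0.0, 100.0)]
    p = sm.StructuralParams1Cmt(1.0, 20.0 * np.exp(eta_cl), 100.0)
    obs = []
    for t in obs_times:
        conc = sm.conc_1cmt_oral(p, doses, t)
        obs.append(Observation(t, float(sm.apply_residual(conc, sigma, rng.standard_normal()))))
    return SubjectData(str(sid), doses, obs)


@pytest.fixture(scope="session")
def toy_subject():
    return make_subject("1", 0.2, seed=3)


@pytest.fixture(scope="session")
def onecmt_model_1eta():
    return mi.ModelSpec("onecmt-oral", "nonmixture", "CL", ("CL",), n_components=1)
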