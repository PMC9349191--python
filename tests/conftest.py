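import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from lineageflux import (
    FitConfig,
    NoiseModel,
    StudyDesign,
    generate_cohort,
    make_toy_model,
)
from lineageflux.model import ErrorModel, LineageModel


@pytest.fixture(scope="session")
def toy():
    """The in-silico toy: (topology, generating rates with steady-state sizes)."""
    return make_toy_model()


@pytest.fixture(scope="session")
def lean_config():
    """Small multistart schedule for unit tests."""
    return FitConfig(n_starts=16, seed=3, scan_max_nfev=10, n_polish=2,
                     polish_max_nfev=300)


@pytest.fixture(scope="session")
def noisefree_table(toy):
    """Single noise-free mouse per timepoint: values equal the model curves."""
    topo, rates = toy
    design = StudyDesign(mice_per_timepoint=1)
    return generate_cohort(topo, rates, design, NoiseModel.zero(), seed=0)


@pytest.fixture(scope="session")
def fixed_error_model():
    """Fixed sigmas at the magnitudes of the default cohort SEMs."""
    return ErrorModel(
        mode="fixed",
        sigma={"label_fraction": 0.010, "rel_size": 0.071, "gfp_retention": 0.018},
        relative_kinds=("rel_size",),
    )


@pytest.fixture(scope="session")
def noisy_table(toy):
    """One default-noise cohort (7 timepoints x 8 mice, all observables)."""
    topo, rates = toy
    return generate_cohort(topo, rates, StudyDesign(), NoiseModel(), seed=42)


@pytest.fixture(scope="session")
def toy_truth_theta(toy, noisefree_table, fixed_error_model):
    """log10 parameter vector of the generating rates in model layout."""
    topo, rates = toy
    model = LineageModel(topo, noisefree_table, error_model=fixed_error_model)
    vals = []
    for name in model.param_names:
        kind, _, key = name.partition(":")
        if kind == "alpha":
            s, t = key.split(">")
            vals.append(rates.alpha[(s, t)])
        elif kind == "p":
            vals.append(rates.p[key])
        elif kind == "delta":
            vals.append(rates.delta[key])
        elif kind == "N0":
            vals.append(rates.N0[key])
        else:
            vals.append(rates.f0[key])
    return model, np.log10(vals)
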