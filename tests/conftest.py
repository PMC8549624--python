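import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from daphtox.design import DesignSpec
from daphtox.model import ModelData
from daphtox.sampler import PosteriorDraws
from daphtox.simulate import make_truth_preset, simulate_dataset


@pytest.fixture(scope="session")
def study_design() -> DesignSpec:
    return DesignSpec.study()


@pytest.fixture(scope="session")
def study_units(study_design):
    """392-unit paper-faithful synthetic dataset (fixed seed)."""
    return simulate_dataset(make_truth_preset("paper_like", seed=11), study_design)


@pytest.fixture(scope="session")
def study_data(study_units) -> ModelData:
    return ModelData(study_units)


@pytest.fixture(scope="session")
def tiny_units():
    """Small dataset (2 populations/class, 2 clones, 1 replicate) for fast fits."""
    spec = DesignSpec(
        n_populations_per_class=2, n_clones_per_population=2, n_replicates=1
    )
    return simulate_dataset(make_truth_preset("paper_like", seed=5), spec)


def make_fake_draws(
    values_by_name: dict[str, np.ndarray], divergent: np.ndarray | None = None
) -> PosteriorDraws:
    """Assemble a PosteriorDraws from per-parameter (chains, draws) arrays."""
    names = list(values_by_name)
    stacked = np.stack([np.asarray(values_by_name[n], float) for n in names], axis=-1)
    return PosteriorDraws(names=names, values=stacked, divergent=divergent)


@pytest.fixture(scope="session")
def zero_draws():
    """All-parameters-zero draws for the full fixed-effect set (except scales)."""
    from daphtox.summaries import sample_fixed_effect_names

    shape = (2, 50)
    vals = {n: np.zeros(shape) for n in sample_fixed_effect_names()}
    vals["sigma_pop"] = np.full(shape, 1.0)
    vals["sigma_clone"] = np.full(shape, 1.0)
    vals["nu"] = np.full(shape, 10.0)
    return make_fake_draws(vals)
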