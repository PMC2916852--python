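import numpy as np
import pytest

from avloc import MEAN_SUBJECT_PARAMS, ModelParams
from avloc.synth import SyntheticSubjectSpec, build_design, generate_subject


@pytest.fixture(scope="session")
def mean_params() -> ModelParams:
    """Typical human-observer parameter set used as the generating condition."""
    return MEAN_SUBJECT_PARAMS


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def matching_subject(mean_params):
    """One full-design synthetic subject generated with the matching strategy."""
    spec = SyntheticSubjectSpec("m0", "matching", mean_params, seed=42)
    return generate_subject(spec, build_design(repetitions=15, seed=7))


def make_subject(strategy, params=MEAN_SUBJECT_PARAMS, seed=0, repetitions=15, design_seed=1):
    spec = SyntheticSubjectSpec(f"{strategy[:2]}{seed}", strategy, params, seed=seed)
    return generate_subject(spec, build_design(repetitions=repetitions, seed=design_seed))
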