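import numpy as np
import pytest

from ontoshift.examples import bistable_additional
from ontoshift.models import (
    AdditionalResourcesParams,
    InterstageSharingParams,
    MultipleHabitatsParams,
    default_params,
)


@pytest.fixture
def additional_baseline() -> AdditionalResourcesParams:
    """Two resources per stage, shared rates r=1, a=0.1, b=0.5, d=0.1, K=10."""
    return default_params("additional")


@pytest.fixture
def multiple_baseline() -> MultipleHabitatsParams:
    return default_params("multiple")


@pytest.fixture
def sharing_baseline() -> InterstageSharingParams:
    return default_params("sharing")


@pytest.fixture
def single_resource_params() -> AdditionalResourcesParams:
    """One resource per stage with the baseline rates (K = 10)."""
    ones = np.ones(1)
    return AdditionalResourcesParams(
        r_J=ones, K_J=10 * ones, a_J=0.1 * ones, b_J=0.5 * ones,
        r_A=ones.copy(), K_A=10 * ones, a_A=0.1 * ones, b_A=0.5 * ones,
        d_J=0.1, d_A=0.1,
    )


@pytest.fixture
def bistable_params() -> AdditionalResourcesParams:
    """A point with two stable interior equilibria separated by a saddle.

    Higher stage mortalities than the plotting baseline pull the system out
    of the oscillatory regime, so both outer equilibria are attracting fixed
    points with O(0.1) stability margins.
    """
    return bistable_additional()


@pytest.fixture
def bistable_multiple() -> MultipleHabitatsParams:
    """Two-habitat version of ``bistable_params`` (homogeneous)."""
    return MultipleHabitatsParams(
        n_J=2, n_A=2, r_J=2.4, K_J=10.0, a_J=0.05, b_J=0.9,
        r_A=2.8, K_A=28.0, a_A=0.1, b_A=1.0, d_J=0.4, d_A=0.23,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
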