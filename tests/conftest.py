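import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from traitshift.synthetic_data import (SynthParams, gen_climate_stack,
                                       gen_specimens)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params() -> SynthParams:
    """Reduced-size study conditions for fast unit tests."""
    return SynthParams(grid_shape=(24, 36),
                       n_records={"pre": 220, "post": 180}, seed=42)


@pytest.fixture(scope="session")
def small_stack(small_params):
    return gen_climate_stack(small_params)


@pytest.fixture(scope="session")
def small_specimens(small_params, small_stack):
    """(specimen table, ground truth) at reduced size."""
    return gen_specimens(small_params, small_stack)


@pytest.fixture(scope="session")
def default_specimens():
    """One draw at the full default study conditions."""
    params = SynthParams(seed=7)
    stack = gen_climate_stack(params)
    table, truth = gen_specimens(params, stack)
    return params, stack, table, truth


@pytest.fixture()
def specimen_csv(tmp_path, small_specimens):
    table, _ = small_specimens
    path = tmp_path / "specimens.csv"
    table.to_csv(path, index=False)
    return path


def simulate_gls_points(seed: int, n: int = 484,
                        beta: dict | None = None,
                        noise_scale: float = 1.5,
                        spatial_range: float = 1.0) -> pd.DataFrame:
    """Shared alias for the package's change-GLS scenario generator."""
    from traitshift.synthetic_data import gen_gls_point_set
    beta = beta or {"intercept": 0.0, "F": 20.0, "F2": -70.0, "P": 10.0,
                    "P2": 8.0, "F:P": -90.0}
    return gen_gls_point_set(seed, n=n, beta=beta, noise_scale=noise_scale,
                             spatial_range=spatial_range)
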