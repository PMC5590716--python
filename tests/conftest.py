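import numpy as np
import pytest

import twopartlong as tpl
from twopartlong.data import build_designs
from twopartlong.simulate import simulate_semicontinuous, simulate_zip


def bern(p):
    return lambda rng, n: rng.binomial(1, p, n).astype(float)


@pytest.fixture(scope="session")
def twopart_panel():
    """Small panel drawn from a correlated two-part mixed model."""
    params = tpl.TwoPartParams(
        theta=[0.5, -0.4], beta=[0.3, 0.2],
        re=tpl.BivariateNormalRE(1.5, 0.4, 0.7), resid_var=0.3,
    )
    ds, truth = simulate_semicontinuous(
        params, 120, times=(0.0, 1.0, 2.0, 3.0),
        covariates={"g": bern(0.5)}, binary_terms=("g",),
        intensity_terms=("g",), seed=11,
    )
    designs = build_designs(ds, ("g",), ("g",))
    return ds, designs, params, truth


@pytest.fixture(scope="session")
def zip_panel():
    params = tpl.ZipParams(
        theta=[-0.5, 0.5], beta=[0.3, -0.4],
        re=tpl.BivariateNormalRE(1.0, 0.6, 0.5),
    )
    ds, truth = simulate_zip(
        params, 120, covariates={"g": bern(0.5)},
        binary_terms=("g",), intensity_terms=("g",), seed=7,
    )
    designs = build_designs(ds, ("g",), ("g",))
    return ds, designs, params, truth
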