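import numpy as np
import pandas as pd
import pytest

from obdecomp import ModelFit, compact_spec, default_ghana_spec, generate_survey
from obdecomp.design import DesignMeta


def make_fit(coefficients: dict, link: str = "linear", group: str = "urban") -> ModelFit:
    """ModelFit wrapper around a hand-specified coefficient vector."""
    terms = list(coefficients)
    cov = pd.DataFrame(np.eye(len(terms)) * 1e-4, index=terms, columns=terms)
    return ModelFit(
        group=group,
        link=link,
        coefficients=dict(coefficients),
        covariance=cov,
        n_obs=100,
        converged=True,
        design_meta=DesignMeta(),
    )


@pytest.fixture(scope="session")
def ghana_spec():
    return default_ghana_spec()


@pytest.fixture(scope="session")
def small_spec():
    return compact_spec()


@pytest.fixture(scope="session")
def small_table(small_spec):
    return generate_survey(small_spec, 4000, seed=1)
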