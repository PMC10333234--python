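import numpy as np
import pytest

import cofluct as cf


@pytest.fixture(scope="session")
def tiny_cohort():
    return cf.make_fixture("tiny")


@pytest.fixture(scope="session")
def worked_cohort():
    return cf.make_fixture("worked")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_random_run(rng, t=50, p=6, tr=0.72, **kwargs):
    return cf.ParcellatedRun(data=rng.standard_normal((t, p)), tr=tr, **kwargs)


@pytest.fixture()
def random_run(rng):
    return make_random_run(rng)
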