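import warnings

import numpy as np
import pytest

import neodx
from neodx.cohort import (_BASELINES, EffectTemplate, GroupSpec,
                          NoiseModel, _default_blocks)


@pytest.fixture(scope="session")
def panel():
    return neodx.default_panel()


@pytest.fixture(scope="session")
def scenarios():
    return neodx.scenario_library()


@pytest.fixture(scope="session")
def hie_table(scenarios):
    """One realisation of the hypoxia time-course cohort (fixed seed)."""
    return scenarios["hie_timecourse"].generate(0)


@pytest.fixture(scope="session")
def default_noise(panel):
    return NoiseModel(baseline=dict(_BASELINES), sdlog=0.3,
                      blocks=_default_blocks(panel))


@pytest.fixture(scope="session")
def glycine_only_template():
    """Two arms at the study's 0 h/6 h sizes with only glycine shifted."""
    return EffectTemplate(
        "gly_only",
        (GroupSpec("control", 10),
         GroupSpec("case", 12, fold={"Gly": 2.0})),
    )


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(20240207)
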