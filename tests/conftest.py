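import numpy as np
import pytest

from trastkit.state_models import (Environment, PARAMETER_PRESETS,
                                   build_rate_matrix, get_model)


@pytest.fixture
def mb_air():
    return PARAMETER_PRESETS["MB_AIR"]


@pytest.fixture
def ir700():
    return PARAMETER_PRESETS["IR700_TABLE1"]


@pytest.fixture
def env_lowph():
    return Environment(pH=3.5, buffer_mM=12.0)


@pytest.fixture
def env_highph():
    return Environment(pH=9.3, buffer_mM=12.0)


#: (model_id, preset name, environment) combinations exercising every model
PRESET_SYSTEMS = [
    ("MB_LOWPH_4", "MB_AIR", Environment(pH=3.5)),
    ("MB_HIGHPH_4", "MB_AIR", Environment(pH=9.3)),
    ("MB_COMPOUND_4", "MB_AIR", Environment(pH=7.0)),
    ("MB_FULL_5", "MB_AIR", Environment(pH=5.0)),
    ("IR700_3", "IR700_TABLE1", Environment(pH=7.2)),
    ("IR700_4", "IR700_TABLE1", Environment(pH=7.2, ascorbate_mM=1.0)),
]


def preset_matrix(model_id, preset, env, irradiance=431.0):
    return build_rate_matrix(get_model(model_id), PARAMETER_PRESETS[preset],
                             env, irradiance)


@pytest.fixture(params=PRESET_SYSTEMS, ids=lambda s: s[0])
def preset_system(request):
    model_id, preset, env = request.param
    return (get_model(model_id), PARAMETER_PRESETS[preset], env,
            preset_matrix(model_id, preset, env))
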