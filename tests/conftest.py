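import pytest

from dpfold.core import FoldConfig
from dpfold.zuker import ToyEnergyModel


@pytest.fixture
def cfg():
    return FoldConfig()


@pytest.fixture
def exact_cfg():
    """Config with the interior-loop size cap disabled (for oracle equality)."""
    return FoldConfig(interior_loop_cap=None)


@pytest.fixture
def toy_models():
    """Three sign-mixed toy energy models exercising every loop term."""
    return [
        ToyEnergyModel(
            hairpin=-1.0, stack=-2.0, internal=1.5,
            multiloop_a=1.0, multiloop_b=0.5, multiloop_c=0.1,
        ),
        ToyEnergyModel(hairpin=2.0, stack=-3.0, internal=0.5),
        ToyEnergyModel(
            hairpin=-0.5, stack=-1.0, internal=-0.25,
            multiloop_a=-0.3, multiloop_b=0.2, multiloop_c=0.05,
        ),
    ]
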