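import numpy as np
import pytest

from tsmod.mechanics import (ExtensibleDomain, PolymerEnvironment,
                             SensorDesign, get_pair)


@pytest.fixture(scope="session")
def clover_pair():
    return get_pair("clover-mruby2")


@pytest.fixture(scope="session")
def design_template(clover_pair):
    """Clover-mRuby2 sensor template with Lp left unset (for fitting)."""
    return SensorDesign(clover_pair, ExtensibleDomain("GGSGGS", 9),
                        PolymerEnvironment.in_cellulo())


@pytest.fixture(scope="session")
def ggsggs9(clover_pair):
    """The nine-repeat cellular sensor at its calibrated Lp."""
    return SensorDesign(clover_pair, ExtensibleDomain("GGSGGS", 9, lp=0.48),
                        PolymerEnvironment.in_cellulo())


@pytest.fixture(scope="session")
def ggsggs_trio(clover_pair):
    env = PolymerEnvironment.in_cellulo()
    return {n: SensorDesign(clover_pair,
                            ExtensibleDomain("GGSGGS", n, lp=0.48), env)
            for n in (5, 7, 9)}


def force_grid(f_max=12.0, n=49):
    return np.linspace(0.0, f_max, n)
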