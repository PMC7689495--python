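import numpy as np
import pytest

import cochlearhorn as ch


@pytest.fixture(scope="session")
def cat_map():
    return ch.TonotopicMap(A=456.0, gamma=0.8, L=25e-3)


@pytest.fixture(scope="session")
def exp_map():
    """Purely exponential tonotopic map (gamma = 0)."""
    return ch.TonotopicMap(A=456.0, gamma=0.0, L=25e-3)


@pytest.fixture(scope="session")
def cat_profile(cat_map):
    return ch.build_geometry(cat_map, ch.TaperParams(), 2048)


@pytest.fixture(scope="session")
def tail_micro():
    return ch.MicromechanicsParams(mode="tail")


@pytest.fixture(scope="session")
def passive_micro():
    return ch.MicromechanicsParams(mode="passive", delta=0.2, rho_f=0.0)


def make_profile(tono, S, h, b, k, n=2048, rho=1000.0, skip_checks=False):
    """Build a GeometryProfile from callables of x on a uniform grid."""
    x = np.linspace(0.0, tono.L, n)
    return ch.GeometryProfile(
        x=x, S=S(x), h=h(x), b=b(x), k=k(x), cf=np.asarray(tono.cf(x)), rho=rho,
        _skip_taper_checks=skip_checks,
    )
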