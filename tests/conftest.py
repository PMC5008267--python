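import numpy as np
import pytest

import trophodyn as td


@pytest.fixture(scope="session")
def webs():
    return td.fixture_webs()


@pytest.fixture(scope="session")
def chain(webs):
    return webs["chain"]


@pytest.fixture(scope="session")
def cycle(webs):
    return webs["cycle"]


@pytest.fixture(scope="session")
def equilibrium(webs):
    return webs["equilibrium"]


@pytest.fixture(scope="session")
def balanced20():
    """A mid-sized generated balanced web used across modules."""
    return td.generate_web(td.GeneratorSpec(S=20, target_connectance=0.2, seed=3))


def build_model(net, form="nonlinear", draw=td.CENTRAL_DRAW, cfg=None):
    params = td.derive_parameters(net, draw.k0)
    if form == "nonlinear":
        fr = td.fit_nonlinear_fr(net, h=draw.h, b=draw.b, q=draw.q)
    else:
        fr = td.fit_linear_fr(net)
    return td.DynamicalModel(net, params, fr, cfg)


@pytest.fixture(scope="session")
def starvation_web():
    """Five producer-specialist pairs plus detritus: every producer removal
    starves exactly one consumer within the next window (linear response)."""
    n = 11
    ids = [f"a_pro{k}" for k in range(5)] + [f"z_con{k}" for k in range(5)] + ["det"]
    cats = ["producer"] * 5 + ["consumer"] * 5 + ["detritus"]
    F = np.zeros((n, n))
    for k in range(5):
        F[k, 5 + k] = 0.1      # producer k feeds its specialist
        F[k, 10] = 0.01        # death to detritus
        F[5 + k, 10] = 0.02    # egestion to detritus
    B = np.ones(n)
    B[10] = 5.0
    GPP = np.array([0.16] * 5 + [0.0] * 6)
    R = np.array([0.05] * 5 + [0.08] * 5 + [0.0])
    return td.make_network(ids, ids, cats, B, GPP, R, np.zeros(n), np.zeros(n), F)
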