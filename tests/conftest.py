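import math

import pytest

from ioncomp import compile_model, fixtures


@pytest.fixture(scope="session")
def hh_compiled():
    return compile_model(fixtures.hh_fixture())


@pytest.fixture(scope="session")
def kr_compiled():
    return compile_model(fixtures.kr_fixture())


def hh_oracle_rhs(t, y_named, stim=0.0):
    """Hand-coded HH right-hand side, written directly from the model's
    printed rate equations (independent of the compiler path).

    ``y_named``: dict state-name suffix -> value (m, h, n, v).
    Returns dict of derivatives keyed the same way.
    """
    m, h, n, v = y_named["m"], y_named["h"], y_named["n"], y_named["v"]
    am = (2.5 - 0.1 * v) / (math.exp(2.5 - 0.1 * v) - 1)
    bm = 0.125 * math.exp(-v / 80)
    ah = 0.07 * math.exp(-v / 20)
    bh = 1 / (math.exp(3 - 0.1 * v) + 1)
    an = (0.1 - 0.01 * v) / (math.exp(1 - 0.1 * v) - 1)
    bn = 0.125 * math.exp(-v / 80)
    i_na = 120.0 * m ** 3 * h * (v - 115.0)
    i_k = 36.0 * n ** 4 * (v - (-12.0))
    i_l = 0.3 * (v - 10.613)
    return {
        "m": am * (1 - m) - bm * m,
        "h": ah * (1 - h) - bh * h,
        "n": an * (1 - n) - bn * n,
        "v": (stim - (i_na + i_k + i_l)) / 1.0,
    }


HH_STATE_SUFFIX = {"m": "Na_gating_m", "h": "Na_gating_2_h",
                   "n": "K_gating_n", "v": "v"}
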