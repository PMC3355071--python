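"""Goldman-Hodgkin-Katz constant-field flux.

``ghk_flux`` gives the current density per unit permeability for an ion of
valence *z* crossing a membrane at potential *v* (mV) with inside/outside
concentrations *ci*, *co* (mM):

    I/P = z^2 F^2 v / (R T) * (ci - co * exp(-z F v / (R T))) / (1 - exp(-z F v / (R T)))

with v converted to volts internally.  The singularity at v = 0 is removable;
for |zFv/RT| below 1e-6 the second-order series

    I/P ~= z F [(ci - co) + u (ci + co) / 2],   u = z F v / (R T)

is used, whose leading term is the analytic limit z F (ci - co).

The same function is registered as the built-in ``ghk`` relation of the
expression language, with argument order ``(v, ci, co, z, celsius)``.
"""

from __future__ import annotations

from math import exp

from .errors import ValidationError
from .expr import BUILTIN_FUNCTIONS

__all__ = ["FARADAY", "GAS_CONSTANT", "ZERO_CELSIUS", "ghk_flux"]

FARADAY = 96485.33212      # C / mol
GAS_CONSTANT = 8.31446     # J / (mol K)
ZERO_CELSIUS = 273.15      # K

_SERIES_THRESHOLD = 1e-6


def ghk_flux(v: float, ci: float, co: float, z: float, celsius: float = 22.0) -> float:
    """Constant-field current density per unit permeability.

    Parameters are membrane potential *v* in mV, concentrations *ci*/*co*
    in mM (both >= 0), integer valence *z* (nonzero) and temperature in
    degrees Celsius.  The sign convention is the usual one: positive values
    are outward current.
    """
    if z == 0:
        raise ValidationError("GHK flux requires a nonzero valence")
    if ci < 0 or co < 0:
        raise ValidationError("GHK concentrations must be nonnegative")
    T = ZERO_CELSIUS + celsius
    u = z * FARADAY * (v * 1e-3) / (GAS_CONSTANT * T)
    if abs(u) < _SERIES_THRESHOLD:
        return z * FARADAY * ((ci - co) + u * (ci + co) / 2.0)
    return z * FARADAY * u * (ci - co * exp(-u)) / (1.0 - exp(-u))


def _ghk_builtin(v, ci, co, z, celsius):
    return ghk_flux(v, ci, co, z, celsius)


BUILTIN_FUNCTIONS["ghk"] = (5, _ghk_builtin)
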