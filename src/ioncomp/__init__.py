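"""ioncomp: a layer-oriented declarative language for ionic-current models.

The package compiles hierarchical descriptions of conductance-based membrane
models (Hodgkin-Huxley gates, Markov kinetic schemes, Ohmic and GHK current
laws, calcium pools) into a flat ordered ODE system, and emits executable
code for several targets: a solver-API Python module, an Octave/Matlab
script, and NMODL mechanism files with optional automatic merging.

Typical use::

    from ioncomp import compile_model, fixtures, runtime

    compiled = compile_model(fixtures.hh_fixture())
    result = runtime.simulate(compiled.sys, duration=50.0, stim=15.0)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

from . import ghk as _ghk_module  # noqa: F401  (registers the ghk builtin)
from .components import Model, read_model, validate_structure
from .errors import IoncompError
from .experiments import (ClampProtocol, SimConfig, build_clamp_protocol,
                          build_sim_config)
from .ghk import ghk_flux
from .lower import lower_model
from .odesystem import (ModelInfo, OdeSystem, build_model_info,
                        build_ode_system, order_entities)
from .sexpr import parse_program, parse_sexpr, write_sexpr
from .xmlio import parse_xml, parse_xml_program, write_xml, write_xml_program

__version__ = "0.1.0"

__all__ = ["compile_model", "CompiledModel", "read_model_source",
           "Model", "OdeSystem", "ModelInfo", "SimConfig", "ClampProtocol",
           "ghk_flux", "IoncompError", "__version__"]


@dataclass
class CompiledModel:
    """Everything the pipeline produces for one model source."""
    model: Model
    sys: OdeSystem
    info: ModelInfo
    simulations: List[SimConfig] = field(default_factory=list)
    clamps: List[ClampProtocol] = field(default_factory=list)


def read_model_source(text: str) -> Model:
    """Read a model in either surface dialect (s-expression or XML)."""
    if text.lstrip().startswith("<"):
        forms = parse_xml_program(text)
        text = "\n".join(write_sexpr(f) for f in forms)
    return read_model(text)


def compile_model(text: str) -> CompiledModel:
    """Run the whole pipeline: parse, validate, lower, order, build."""
    model = read_model_source(text)
    validate_structure(model)
    flat = lower_model(model)
    ordered = order_entities(flat)
    sys = build_ode_system(ordered)
    info = build_model_info(sys)
    sims = [build_sim_config(c) for c in model.simulations()]
    clamps = [build_clamp_protocol(c, model) for c in model.voltage_clamps()]
    return CompiledModel(model=model, sys=sys, info=info,
                         simulations=sims, clamps=clamps)
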