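"""Component layer: typed, named, output-declaring model components.

A model is a tree of components.  The structuring rules are those of
conductance-based ionic-current models: a membrane-potential root holds one
membrane-capacitance component and one or more current components; each
ion-specific current holds one or more gating components, exactly one pore
(Ohmic) or permeability (GHK) component and exactly one permeating-ion
component.  Calcium pools (`decaying-pool`) and the experiment components
(`simulation`, `voltage-clamp`) sit beside the currents.

Two widely used shorthands are desugared here into the structured form:

* ``(Membrane-capacitance 1.0 uF/cm*cm)`` becomes a component exporting ``C``;
* ``(Ohmic-current Na (E = 115 mV) (g_max = 120 mS/cm*cm) (gating m ...) ...)``
  becomes a current whose pore/permeating-ion children hold ``g_max``/``E``,
  the ion species being inferred from the current name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .errors import GrammarError, StructuralError
from .expr import Expr, parse_expr_items
from .sexpr import Num, Op, SList, Sym, SyntaxNode, parse_program

__all__ = [
    "KNOWN_IONS", "NON_SPECIFIC", "GateSpec", "InputDecl", "ComponentDecl",
    "Model", "parse_component", "read_model", "validate_structure",
]

# species tokens accepted for permeating/accumulating ions (lowercase);
# anything else must use the explicit non-specific token
KNOWN_IONS = {"na", "k", "ca", "cl", "mg", "zn", "ba", "sr", "li", "cs"}
NON_SPECIFIC = "non-specific"

MEMBRANE_POTENTIAL = "membrane-potential"
MEMBRANE_CAPACITANCE = "membrane-capacitance"
OHMIC_CURRENT = "ohmic-current"
GATING = "gating"
HH_GATING = "hh-gating-dynamics"
PORE = "pore"
PERMEABILITY = "permeability"
PERMEATING_ION = "permeating-ion"
DECAYING_POOL = "decaying-pool"
SIMULATION = "simulation"
VOLTAGE_CLAMP = "voltage-clamp"

COMPONENT_TYPES = {
    MEMBRANE_POTENTIAL, MEMBRANE_CAPACITANCE, OHMIC_CURRENT, GATING,
    HH_GATING, PORE, PERMEABILITY, PERMEATING_ION, DECAYING_POOL,
    SIMULATION, VOLTAGE_CLAMP,
}

_ENTITY_HEADS = {"const", "fun", "d", "reaction"}


@dataclass
class GateSpec:
    """One channel gate: its state name, exponent and rate description."""
    name: str
    power: int = 1
    rate_form: str = "ab"            # "ab" (alpha/beta) or "inftau"
    fwd: Optional[Expr] = None
    rev: Optional[Expr] = None
    inf: Optional[Expr] = None
    tau: Optional[Expr] = None
    initial: Optional[float] = None  # None -> steady state at t=0


@dataclass(frozen=True)
class InputDecl:
    local: str
    source_ctype: str
    source_cname: str
    source_output: Optional[str] = None


@dataclass
class ComponentDecl:
    ctype: str
    cname: Optional[str] = None
    outputs: List[str] = field(default_factory=list)
    entity_decls: List[SyntaxNode] = field(default_factory=list)
    children: List["ComponentDecl"] = field(default_factory=list)
    inputs: List[InputDecl] = field(default_factory=list)
    gates: List[GateSpec] = field(default_factory=list)
    powers: dict = field(default_factory=dict)      # gate name -> power (structured)
    valence: Optional[int] = None                   # permeating-ion
    source_currents: List[str] = field(default_factory=list)  # decaying-pool
    initial: Optional[float] = None

    def children_of_type(self, ctype: str) -> List["ComponentDecl"]:
        return [c for c in self.children if c.ctype == ctype]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def find(self, ctype: str, cname: Optional[str] = None):
        return [c for c in self.walk()
                if c.ctype == ctype and (cname is None or c.cname == cname)]


@dataclass
class Model:
    """A parsed model file: the cell model plus its experiment components."""
    root: ComponentDecl
    experiments: List[ComponentDecl] = field(default_factory=list)

    def simulations(self):
        return [c for c in self.experiments if c.ctype == SIMULATION]

    def voltage_clamps(self):
        return [c for c in self.experiments if c.ctype == VOLTAGE_CLAMP]


def _canonical_ctype(name: str) -> Optional[str]:
    low = name.lower()
    return low if low in COMPONENT_TYPES else None


def _sym_name(item: SyntaxNode, what: str) -> str:
    if not isinstance(item, Sym):
        raise GrammarError(f"expected {what}, got {item!r}")
    return item.name


def _is_assignment_form(clause: SList) -> bool:
    return (len(clause) >= 3 and isinstance(clause[0], Sym)
            and isinstance(clause[1], Op) and clause[1].name == "=")


def _const_decl(name: str, rhs_items) -> SList:
    return SList((Sym("const"), Sym(name), Op("="), *rhs_items))


def _parse_input_clause(clause: SList) -> List[InputDecl]:
    decls = []
    for spec in clause[1:]:
        if not isinstance(spec, SList) or len(spec) < 4:
            raise GrammarError(f"malformed input specification: {spec!r}")
        local = _sym_name(spec[0], "input local name")
        if _sym_name(spec[1], "'from'") != "from":
            raise GrammarError(f"expected 'from' in input specification: {spec!r}")
        sctype = _sym_name(spec[2], "source component type")
        scname = _sym_name(spec[3], "source component name")
        soutput = _sym_name(spec[4], "source output") if len(spec) > 4 else None
        decls.append(InputDecl(local, sctype.lower(), scname, soutput))
    return decls


def _parse_compact_gate(node: SList) -> GateSpec:
    gate = GateSpec(name=_sym_name(node[1], "gate name"))
    have_rate = {}
    for clause in node.items[2:]:
        if not isinstance(clause, SList) or clause.head is None:
            raise GrammarError(f"malformed gating clause: {clause!r}")
        head = clause.head
        if head == "power":
            gate.power = int(clause[1].value)
        elif head in ("forward-rate", "reverse-rate", "inf", "tau"):
            have_rate[head] = parse_expr_items(clause.items[1:])
        elif head == "initial":
            gate.initial = float(clause[1].value)
        else:
            raise GrammarError(f"unknown gating clause {head!r}")
    if "forward-rate" in have_rate or "reverse-rate" in have_rate:
        if set(have_rate) != {"forward-rate", "reverse-rate"}:
            raise GrammarError(
                f"gate {gate.name!r} needs both forward-rate and reverse-rate")
        gate.rate_form = "ab"
        gate.fwd = have_rate["forward-rate"]
        gate.rev = have_rate["reverse-rate"]
    elif "inf" in have_rate or "tau" in have_rate:
        if set(have_rate) != {"inf", "tau"}:
            raise GrammarError(f"gate {gate.name!r} needs both inf and tau")
        gate.rate_form = "inftau"
        gate.inf = have_rate["inf"]
        gate.tau = have_rate["tau"]
    else:
        raise GrammarError(f"gate {gate.name!r} declares no rate form")
    return gate


def _infer_species(cname: Optional[str]) -> str:
    if cname and cname.lower() in KNOWN_IONS:
        return cname.lower()
    return NON_SPECIFIC


def parse_component(node: SyntaxNode) -> ComponentDecl:
    """Parse one component form (recursively) into a :class:`ComponentDecl`."""
    if not isinstance(node, SList) or node.head is None:
        raise GrammarError(f"not a component form: {node!r}")
    ctype = _canonical_ctype(node.head)
    if ctype is None:
        raise GrammarError(f"unknown component or declaration head {node.head!r}")

    comp = ComponentDecl(ctype=ctype)
    items = list(node.items[1:])

    # compact gating: (gating m (power 3) (forward-rate ...) (reverse-rate ...))
    if ctype == GATING and items and isinstance(items[0], Sym):
        gate = _parse_compact_gate(node)
        comp.gates = [gate]
        comp.outputs = [gate.name]
        return comp

    # compact capacitance: (Membrane-capacitance 1.0 uF/cm*cm)
    if ctype == MEMBRANE_CAPACITANCE and items and isinstance(items[0], Num):
        comp.outputs = ["C"]
        comp.entity_decls.append(_const_decl("C", items))
        return comp

    # positional component name (Membrane-potential hh / Ohmic-current Na)
    if items and isinstance(items[0], Sym):
        comp.cname = items.pop(0).name

    for clause in items:
        if not isinstance(clause, SList) or not clause.items:
            raise GrammarError(f"unexpected item {clause!r} in {ctype} component")
        head = clause.head
        if head == "out":
            comp.outputs.extend(_sym_name(s, "output name") for s in clause[1:])
        elif head == "name":
            comp.cname = _sym_name(clause[1], "component name")
        elif head == "input":
            comp.inputs.extend(_parse_input_clause(clause))
        elif head == "valence" and ctype == PERMEATING_ION:
            comp.valence = int(clause[1].value)
        elif head == "current" and ctype == DECAYING_POOL:
            comp.source_currents.extend(_sym_name(s, "current name") for s in clause[1:])
        elif head == "initial":
            comp.initial = float(clause[1].value)
        elif head == "power" and ctype in (GATING, HH_GATING):
            # structured form: (power m 3)
            if len(clause) != 3:
                raise GrammarError(f"malformed power clause: {clause!r}")
            comp.powers[_sym_name(clause[1], "gate name")] = int(clause[2].value)
        elif head == "E" and ctype == OHMIC_CURRENT and _is_assignment_form(clause):
            ion = _infer_species(comp.cname)
            child = ComponentDecl(ctype=PERMEATING_ION, cname=ion, outputs=["e"])
            child.entity_decls.append(_const_decl("e", clause.items[2:]))
            comp.children.append(child)
        elif head == "g_max" and ctype == OHMIC_CURRENT and _is_assignment_form(clause):
            child = ComponentDecl(ctype=PORE, outputs=["gbar"])
            child.entity_decls.append(_const_decl("gbar", clause.items[2:]))
            comp.children.append(child)
        elif head in _ENTITY_HEADS or _is_assignment_form(clause):
            comp.entity_decls.append(clause)
        elif _canonical_ctype(head) is not None:
            comp.children.append(parse_component(clause))
        else:
            raise GrammarError(f"unknown clause {head!r} in {ctype} component")

    if ctype == OHMIC_CURRENT and not comp.children_of_type(PERMEATING_ION):
        # a current with no explicit permeating ion: infer from its name
        ion = _infer_species(comp.cname)
        if comp.children_of_type(PORE) or comp.children_of_type(PERMEABILITY):
            child = ComponentDecl(ctype=PERMEATING_ION, cname=ion, outputs=[])
            comp.children.append(child)
    return comp


def read_model(text: str) -> Model:
    """Parse a model file (one membrane-potential form + experiment forms)."""
    forms = parse_program(text)
    root = None
    experiments = []
    for form in forms:
        comp = parse_component(form)
        if comp.ctype == MEMBRANE_POTENTIAL:
            if root is not None:
                raise StructuralError("more than one membrane-potential component")
            root = comp
        elif comp.ctype in (SIMULATION, VOLTAGE_CLAMP):
            experiments.append(comp)
        else:
            raise StructuralError(
                f"top-level component must be membrane-potential, simulation "
                f"or voltage-clamp, got {comp.ctype}")
    if root is None:
        raise StructuralError("model has no membrane-potential component")
    # experiment components may also be written inside the model form
    for child in list(root.children):
        if child.ctype in (SIMULATION, VOLTAGE_CLAMP):
            root.children.remove(child)
            experiments.append(child)
    return Model(root=root, experiments=experiments)


def validate_structure(model: Model) -> None:
    """Enforce the component structuring rules of ionic-current models."""
    root = model.root
    caps = root.children_of_type(MEMBRANE_CAPACITANCE)
    if len(caps) != 1:
        raise StructuralError(
            f"model must contain exactly one membrane-capacitance component, "
            f"found {len(caps)}")
    currents = root.children_of_type(OHMIC_CURRENT)
    if not currents:
        raise StructuralError("model must contain at least one current component")
    for cur in currents:
        label = cur.cname or "<unnamed>"
        pores = cur.children_of_type(PORE)
        perms = cur.children_of_type(PERMEABILITY)
        if len(pores) + len(perms) != 1:
            raise StructuralError(
                f"current {label}: needs exactly one pore or permeability "
                f"component, found {len(pores) + len(perms)}")
        ions = cur.children_of_type(PERMEATING_ION)
        if len(ions) != 1:
            raise StructuralError(
                f"current {label}: needs exactly one permeating-ion component, "
                f"found {len(ions)}")
        ion = ions[0]
        species = (ion.cname or NON_SPECIFIC).lower()
        if species != NON_SPECIFIC and species not in KNOWN_IONS:
            raise StructuralError(
                f"current {label}: unknown ion species {species!r}")
        gatings = (cur.children_of_type(GATING) + cur.children_of_type(HH_GATING))
        if not gatings and species != NON_SPECIFIC:
            raise StructuralError(
                f"current {label}: ion-specific currents need at least one "
                f"gating component")
        if perms:
            if ion.valence is None:
                raise StructuralError(
                    f"current {label}: GHK currents need a permeating-ion "
                    f"valence")
    for pool in root.children_of_type(DECAYING_POOL):
        label = pool.cname or "<unnamed>"
        if not pool.source_currents:
            raise StructuralError(f"decaying-pool {label}: no source current")
        for cname in pool.source_currents:
            if not any(c.cname == cname for c in currents):
                raise StructuralError(
                    f"decaying-pool {label}: source current {cname!r} not found")
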