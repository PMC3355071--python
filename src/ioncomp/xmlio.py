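"""Canonical XML rendering of the model syntax.

One documented dialect, interchangeable with the s-expression surface form:
``<list>`` elements mirror parenthesized forms and the leaves are ``<sym>``,
``<num>`` (with optional ``unit`` attribute) and ``<op>`` elements.  A file
holding several top-level forms uses a ``<program>`` root.
"""

from __future__ import annotations

from xml.etree import ElementTree as ET

from .errors import GrammarError, SyntaxErrorWithLocation
from .sexpr import Num, Op, SList, Sym, SyntaxNode, format_number

__all__ = ["parse_xml", "write_xml", "parse_xml_program", "write_xml_program"]


def _node_to_element(node: SyntaxNode) -> ET.Element:
    if isinstance(node, SList):
        e = ET.Element("list")
        for item in node.items:
            e.append(_node_to_element(item))
        return e
    if isinstance(node, Sym):
        e = ET.Element("sym")
        e.set("name", node.name)
        return e
    if isinstance(node, Num):
        e = ET.Element("num")
        e.set("value", format_number(node.value))
        if node.unit:
            e.set("unit", node.unit)
        return e
    if isinstance(node, Op):
        e = ET.Element("op")
        e.set("name", node.name)
        return e
    raise TypeError(f"not a syntax node: {node!r}")


def _element_to_node(e: ET.Element) -> SyntaxNode:
    if e.tag == "list":
        return SList(tuple(_element_to_node(c) for c in e))
    if e.tag == "sym":
        return Sym(e.get("name"))
    if e.tag == "num":
        return Num(float(e.get("value")), e.get("unit"))
    if e.tag == "op":
        return Op(e.get("name"))
    raise GrammarError(f"unknown element <{e.tag}> in model XML")


def _indent(elem, level=0):
    pad = "\n" + "  " * level
    if len(elem):
        if not elem.text or not elem.text.strip():
            elem.text = pad + "  "
        for child in elem:
            _indent(child, level + 1)
            child.tail = pad + "  "
        elem[-1].tail = pad


def _serialize(root: ET.Element) -> str:
    _indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def write_xml(node: SyntaxNode) -> str:
    """Byte-stable XML serialization of a single form."""
    return _serialize(_node_to_element(node))


def write_xml_program(forms) -> str:
    root = ET.Element("program")
    for f in forms:
        root.append(_node_to_element(f))
    return _serialize(root)


def _parse_root(text: str) -> ET.Element:
    if not text.strip():
        raise SyntaxErrorWithLocation("empty XML document")
    try:
        return ET.fromstring(text)
    except ET.ParseError as exc:
        raise SyntaxErrorWithLocation(f"malformed XML: {exc}") from exc


def parse_xml(text: str) -> SyntaxNode:
    """Parse a single-form XML document to the common AST."""
    root = _parse_root(text)
    if root.tag == "program":
        forms = [_element_to_node(c) for c in root]
        if len(forms) != 1:
            raise GrammarError("expected a single form, got a program "
                               f"with {len(forms)} forms")
        return forms[0]
    return _element_to_node(root)


def parse_xml_program(text: str) -> list:
    root = _parse_root(text)
    if root.tag == "program":
        return [_element_to_node(c) for c in root]
    return [_element_to_node(root)]
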