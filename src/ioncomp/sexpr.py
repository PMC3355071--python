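"""S-expression reader/writer for the model-description syntax.

The surface syntax is SXML-flavoured: parenthesized forms whose leaves are
symbols, numeric literals (optionally annotated with a unit token such as
``uF/cm*cm``) and infix operator tokens.  Comments run from ``;`` to end of
line.  An equivalent XML dialect is provided by :mod:`ioncomp.xmlio`; the two
serializations are interchangeable.

Lexical conventions (documented because they matter for model authors):

* identifiers may contain ``-`` (e.g. ``holding-duration``); a ``-`` continues
  an identifier when the following character is a letter, otherwise it is the
  minus operator;
* a symbol immediately following a numeric literal is lexed as a unit
  annotation, and ``/``/``*`` joins inside it are kept (``mS/cm*cm`` is one
  token).  Inside arithmetic, division of one bare identifier by another
  therefore needs spaces or parentheses (``a / b``, never ``a/b``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple, Union

from .errors import SyntaxErrorWithLocation

__all__ = [
    "Sym",
    "Num",
    "Op",
    "SList",
    "SyntaxNode",
    "parse_sexpr",
    "parse_program",
    "write_sexpr",
    "format_number",
]

_OPERATOR_CHARS = "+-*/^="


@dataclass(frozen=True)
class Sym:
    name: str

    def __repr__(self):
        return f"Sym({self.name})"


@dataclass(frozen=True)
class Num:
    value: float
    unit: Optional[str] = None

    def __repr__(self):
        return f"Num({self.value}{' ' + self.unit if self.unit else ''})"


@dataclass(frozen=True)
class Op:
    name: str

    def __repr__(self):
        return f"Op({self.name})"


@dataclass(frozen=True)
class SList:
    items: Tuple["SyntaxNode", ...] = field(default_factory=tuple)

    @property
    def head(self) -> Optional[str]:
        """Name of the first item when it is a symbol, else ``None``."""
        if self.items and isinstance(self.items[0], Sym):
            return self.items[0].name
        return None

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __repr__(self):
        return "SList(" + " ".join(map(repr, self.items)) + ")"


SyntaxNode = Union[Sym, Num, Op, SList]


# ---------------------------------------------------------------------------
# Lexer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Token:
    kind: str  # 'lparen' | 'rparen' | 'num' | 'sym' | 'op'
    text: str
    value: Optional[float]
    line: int
    column: int


def _is_ident_start(c: str) -> bool:
    return c.isalpha() or c == "_"


def _is_ident_char(c: str) -> bool:
    return c.isalnum() or c in "_'"


def _tokenize(text: str) -> Iterator[_Token]:
    # Normalize typographic minus signs (they occur in published listings).
    text = text.replace("−", "-").replace("–", "-")
    i, n = 0, len(text)
    line, col = 1, 1
    prev_kind = None

    def tok(kind, s, value=None, l=None, c=None):
        nonlocal prev_kind
        prev_kind = kind
        return _Token(kind, s, value, l if l is not None else line, c if c is not None else col)

    while i < n:
        c = text[i]
        if c == "\n":
            i += 1
            line += 1
            col = 1
            continue
        if c.isspace() or c == ",":  # commas are separators, never tokens
            i += 1
            col += 1
            continue
        if c == ";":
            while i < n and text[i] != "\n":
                i += 1
            continue
        start_line, start_col = line, col
        if c == "(":
            yield tok("lparen", "(", l=start_line, c=start_col)
            i += 1
            col += 1
            continue
        if c == ")":
            yield tok("rparen", ")", l=start_line, c=start_col)
            i += 1
            col += 1
            continue
        if c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()):
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            if j < n and text[j] in "eE":
                k = j + 1
                if k < n and text[k] in "+-":
                    k += 1
                if k < n and text[k].isdigit():
                    j = k
                    while j < n and text[j].isdigit():
                        j += 1
            lexeme = text[i:j]
            try:
                value = float(lexeme)
            except ValueError:
                raise SyntaxErrorWithLocation(f"bad numeric literal {lexeme!r}", start_line, start_col)
            yield tok("num", lexeme, value, start_line, start_col)
            col += j - i
            i = j
            continue
        if _is_ident_start(c):
            after_number = prev_kind == "num"
            j = i
            while j < n:
                cj = text[j]
                if _is_ident_char(cj):
                    j += 1
                elif cj == "-" and j + 1 < n and _is_ident_start(text[j + 1]):
                    j += 1
                elif after_number and cj in "/*" and j + 1 < n and _is_ident_start(text[j + 1]):
                    # unit annotation such as uF/cm*cm, mS/cm*cm
                    j += 1
                else:
                    break
            yield tok("sym", text[i:j], l=start_line, c=start_col)
            col += j - i
            i = j
            continue
        # reaction-transition arrows are symbols, checked before operators
        for arrow in ("<->", "->", "<-"):
            if text.startswith(arrow, i):
                yield tok("sym", arrow, l=start_line, c=start_col)
                i += len(arrow)
                col += len(arrow)
                break
        else:
            if c in _OPERATOR_CHARS:
                yield tok("op", c, l=start_line, c=start_col)
                i += 1
                col += 1
                continue
            raise SyntaxErrorWithLocation(f"unexpected character {c!r}", start_line, start_col)
        continue


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

def _token_to_atom(t: _Token) -> SyntaxNode:
    if t.kind == "num":
        return Num(t.value)
    if t.kind == "sym":
        return Sym(t.text)
    return Op(t.text)


def _parse_datum(tokens, pos):
    t = tokens[pos]
    if t.kind == "lparen":
        items = []
        pos += 1
        while True:
            if pos >= len(tokens):
                raise SyntaxErrorWithLocation("unbalanced parentheses: unexpected end of input",
                                              t.line, t.column)
            if tokens[pos].kind == "rparen":
                return SList(tuple(items)), pos + 1
            node, pos = _parse_datum(tokens, pos)
            items.append(node)
    if t.kind == "rparen":
        raise SyntaxErrorWithLocation("unbalanced parentheses: unexpected ')'", t.line, t.column)
    return _token_to_atom(t), pos + 1


def parse_sexpr(text: str) -> SyntaxNode:
    """Parse exactly one datum; trailing tokens are a syntax error."""
    tokens = list(_tokenize(text))
    if not tokens:
        raise SyntaxErrorWithLocation("empty input", 1, 1)
    node, pos = _parse_datum(tokens, 0)
    if pos != len(tokens):
        t = tokens[pos]
        raise SyntaxErrorWithLocation(f"stray token {t.text!r} after complete form", t.line, t.column)
    return node


def parse_program(text: str) -> list:
    """Parse a sequence of top-level parenthesized forms (a model file)."""
    tokens = list(_tokenize(text))
    if not tokens:
        raise SyntaxErrorWithLocation("empty input", 1, 1)
    forms = []
    pos = 0
    while pos < len(tokens):
        t = tokens[pos]
        if t.kind != "lparen":
            raise SyntaxErrorWithLocation(f"stray token {t.text!r} at top level", t.line, t.column)
        node, pos = _parse_datum(tokens, pos)
        forms.append(node)
    return forms


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

def format_number(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def _write_atom(node: SyntaxNode) -> str:
    if isinstance(node, Num):
        s = format_number(node.value)
        if node.unit:
            s += " " + node.unit
        return s
    if isinstance(node, Sym):
        return node.name
    if isinstance(node, Op):
        return node.name
    raise TypeError(f"not an atom: {node!r}")


def write_sexpr(node: SyntaxNode) -> str:
    """Deterministic canonical serialization; stable under re-parsing."""
    if isinstance(node, SList):
        return "(" + " ".join(write_sexpr(x) for x in node.items) + ")"
    return _write_atom(node)
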