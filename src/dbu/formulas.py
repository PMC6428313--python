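"""The epistemic language L_B.

Core connectives are atoms, negation, conjunction and the belief operator
``B_a``.  Disjunction, implication, the constants and the dual belief
operator ``B̂_a`` ("considers possible") are surface sugar that expands to
the core.  The two complexity measures on formulas — modal depth d(φ) and
size s(φ) — are defined on the expanded core, except that the constants
⊤/⊥ are measured as atoms (depth 0, size 1) rather than via their
propositional definition p ∨ ¬p, which would inflate them arbitrarily.

Concrete syntax (the same one used inside JSON instance documents)::

    atoms        alphanumeric tokens, may contain _ : ' .
    ~ φ          negation
    φ & ψ        conjunction
    φ | ψ        disjunction
    φ -> ψ       implication (right associative)
    B[a] φ       agent a believes φ
    D[a] φ       dual:  ~B[a]~φ
    T, F         verum / falsum

Precedence: ``~``/``B``/``D`` bind tightest, then ``&``, then ``|``,
then ``->``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "Formula", "Atom", "Not", "And", "Believes",
    "Or", "Implies", "Top", "Bot", "Dual",
    "parse", "render", "expand", "depth", "size",
    "FormulaSyntaxError",
]


class Formula:
    """Base class for formula AST nodes.  Nodes are immutable and hashable."""

    __slots__ = ()

    def __invert__(self) -> "Formula":
        return Not(self)

    def __and__(self, other: "Formula") -> "Formula":
        return And(self, other)

    def __or__(self, other: "Formula") -> "Formula":
        return Or(self, other)

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {render(self)!r}>"


@dataclass(frozen=True, repr=False)
class Atom(Formula):
    name: str


@dataclass(frozen=True, repr=False)
class Not(Formula):
    operand: Formula


@dataclass(frozen=True, repr=False)
class And(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True, repr=False)
class Believes(Formula):
    agent: str
    operand: Formula


# --- surface sugar ---------------------------------------------------------

@dataclass(frozen=True, repr=False)
class Or(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True, repr=False)
class Implies(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True, repr=False)
class Top(Formula):
    pass


@dataclass(frozen=True, repr=False)
class Bot(Formula):
    pass


@dataclass(frozen=True, repr=False)
class Dual(Formula):
    """B̂_a φ := ¬B_a¬φ — 'agent a considers φ possible'."""

    agent: str
    operand: Formula


def expand(phi: Formula) -> Formula:
    """Expand ∨, →, B̂ to the core language.

    ⊤ and ⊥ are kept primitive (see module docstring); the evaluator and
    the measures treat them directly.
    """
    if isinstance(phi, (Atom, Top, Bot)):
        return phi
    if isinstance(phi, Not):
        return Not(expand(phi.operand))
    if isinstance(phi, And):
        return And(expand(phi.left), expand(phi.right))
    if isinstance(phi, Believes):
        return Believes(phi.agent, expand(phi.operand))
    if isinstance(phi, Or):
        return Not(And(Not(expand(phi.left)), Not(expand(phi.right))))
    if isinstance(phi, Implies):
        # φ → ψ  :=  ¬φ ∨ ψ
        return expand(Or(Not(phi.left), phi.right))
    if isinstance(phi, Dual):
        return Not(Believes(phi.agent, Not(expand(phi.operand))))
    raise TypeError(f"not a formula: {phi!r}")


def depth(phi: Formula) -> int:
    """Modal depth d(φ): maximum nesting of belief operators."""
    phi = expand(phi)

    def d(f: Formula) -> int:
        if isinstance(f, (Atom, Top, Bot)):
            return 0
        if isinstance(f, Not):
            return d(f.operand)
        if isinstance(f, And):
            return max(d(f.left), d(f.right))
        if isinstance(f, Believes):
            return 1 + d(f.operand)
        raise TypeError(f"not a core formula: {f!r}")

    return d(phi)


def size(phi: Formula) -> int:
    """Size s(φ): number of variable occurrences and connectives."""
    phi = expand(phi)

    def s(f: Formula) -> int:
        if isinstance(f, (Atom, Top, Bot)):
            return 1
        if isinstance(f, Not):
            return 1 + s(f.operand)
        if isinstance(f, And):
            return 1 + s(f.left) + s(f.right)
        if isinstance(f, Believes):
            return 1 + s(f.operand)
        raise TypeError(f"not a core formula: {f!r}")

    return s(phi)


def atoms(phi: Formula) -> frozenset[str]:
    """Propositional variables occurring in φ (constants excluded)."""
    out: set[str] = set()
    _walk(phi, out, None)
    return frozenset(out)


def agents(phi: Formula) -> frozenset[str]:
    """Agents occurring in belief operators of φ."""
    out: set[str] = set()
    _walk(phi, None, out)
    return frozenset(out)


def _walk(phi: Formula, props: set | None, ags: set | None) -> None:
    if isinstance(phi, Atom):
        if props is not None:
            props.add(phi.name)
    elif isinstance(phi, (Top, Bot)):
        pass
    elif isinstance(phi, Not):
        _walk(phi.operand, props, ags)
    elif isinstance(phi, (And, Or, Implies)):
        _walk(phi.left, props, ags)
        _walk(phi.right, props, ags)
    elif isinstance(phi, (Believes, Dual)):
        if ags is not None:
            ags.add(phi.agent)
        _walk(phi.operand, props, ags)
    else:
        raise TypeError(f"not a formula: {phi!r}")


# --- parser ----------------------------------------------------------------

class FormulaSyntaxError(ValueError):
    """Raised on malformed formula text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_ATOM_CHARS = set("abcdefghijklmnopqrstuvwxyz"
                  "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_:'.")


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "~&|()":
            yield (c, c, i)
            i += 1
        elif text.startswith("->", i):
            yield ("->", "->", i)
            i += 2
        elif c in ("B", "D") and i + 1 < n and text[i + 1] == "[":
            j = text.find("]", i + 2)
            if j < 0:
                raise FormulaSyntaxError("unterminated agent bracket", i)
            agent = text[i + 2:j].strip()
            if not agent:
                raise FormulaSyntaxError("empty agent name", i)
            yield ("MODAL", c + ":" + agent, i)
            i = j + 1
        elif c in _ATOM_CHARS:
            j = i
            while j < n and text[j] in _ATOM_CHARS:
                j += 1
            yield ("ATOM", text[i:j], i)
            i = j
        else:
            raise FormulaSyntaxError(f"unexpected character {c!r}", i)
    yield ("EOF", "", n)


class _Parser:
    def __init__(self, text: str):
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.pos]

    def take(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, kind: str) -> tuple[str, str, int]:
        tok = self.take()
        if tok[0] != kind:
            raise FormulaSyntaxError(f"expected {kind!r}, got {tok[1]!r}", tok[2])
        return tok

    def parse(self) -> Formula:
        phi = self.implication()
        tok = self.peek()
        if tok[0] != "EOF":
            raise FormulaSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return phi

    def implication(self) -> Formula:
        left = self.disjunction()
        if self.peek()[0] == "->":
            self.take()
            return Implies(left, self.implication())  # right associative
        return left

    def disjunction(self) -> Formula:
        left = self.conjunction()
        while self.peek()[0] == "|":
            self.take()
            left = Or(left, self.conjunction())
        return left

    def conjunction(self) -> Formula:
        left = self.unary()
        while self.peek()[0] == "&":
            self.take()
            left = And(left, self.unary())
        return left

    def unary(self) -> Formula:
        kind, value, pos = self.peek()
        if kind == "~":
            self.take()
            return Not(self.unary())
        if kind == "MODAL":
            self.take()
            op, agent = value.split(":", 1)
            inner = self.unary()
            return Believes(agent, inner) if op == "B" else Dual(agent, inner)
        if kind == "(":
            self.take()
            phi = self.implication()
            self.expect(")")
            return phi
        if kind == "ATOM":
            self.take()
            if value == "T":
                return Top()
            if value == "F":
                return Bot()
            return Atom(value)
        raise FormulaSyntaxError(f"unexpected token {value!r}", pos)


def parse(text: str, *, agents_declared: frozenset[str] | set[str] | None = None,
          props_declared: frozenset[str] | set[str] | None = None) -> Formula:
    """Parse formula text to an AST.

    When a declaration context is supplied, undeclared agents or atoms
    raise ``ValueError``.
    """
    phi = _Parser(text).parse()
    if agents_declared is not None:
        bad = agents(phi) - frozenset(agents_declared)
        if bad:
            raise ValueError(f"undeclared agent(s) in formula: {sorted(bad)}")
    if props_declared is not None:
        bad = atoms(phi) - frozenset(props_declared)
        if bad:
            raise ValueError(f"undeclared proposition(s) in formula: {sorted(bad)}")
    return phi


def render(phi: Formula) -> str:
    """Canonical text for φ; ``parse(render(φ))`` reparses to the same AST."""
    return _render(phi, 0)


# binding strength of each context: 0 = top, 1 = or-arg, 2 = and-arg, 3 = unary-arg
def _render(phi: Formula, ctx: int) -> str:
    if isinstance(phi, Atom):
        return phi.name
    if isinstance(phi, Top):
        return "T"
    if isinstance(phi, Bot):
        return "F"
    if isinstance(phi, Not):
        return "~" + _render(phi.operand, 3)
    if isinstance(phi, Believes):
        return f"B[{phi.agent}] " + _render(phi.operand, 3)
    if isinstance(phi, Dual):
        return f"D[{phi.agent}] " + _render(phi.operand, 3)
    if isinstance(phi, And):
        text = _render(phi.left, 2) + " & " + _render(phi.right, 3 if _is_and(phi.right) else 2)
        return f"({text})" if ctx >= 3 else text
    if isinstance(phi, Or):
        text = _render(phi.left, 1) + " | " + _render(phi.right, 3 if isinstance(phi.right, Or) else 1)
        return f"({text})" if ctx >= 2 else text
    if isinstance(phi, Implies):
        text = _render(phi.left, 1) + " -> " + _render(phi.right, 0)
        return f"({text})" if ctx >= 1 else text
    raise TypeError(f"not a formula: {phi!r}")


def _is_and(phi: Formula) -> bool:
    return isinstance(phi, And)


def conjoin(parts: list[Formula]) -> Formula:
    """Right-nested conjunction of ``parts``; ⊤ for the empty list."""
    if not parts:
        return Top()
    out = parts[-1]
    for p in reversed(parts[:-1]):
        out = And(p, out)
    return out


def disjoin(parts: list[Formula]) -> Formula:
    """Right-nested disjunction of ``parts``; ⊥ for the empty list."""
    if not parts:
        return Bot()
    out = parts[-1]
    for p in reversed(parts[:-1]):
        out = Or(p, out)
    return out
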