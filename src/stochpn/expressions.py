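"""Mathematical and conditional expressions for rates and constant places.

Expressions may use the names of non-constant places and the variable
``Time`` (simulated seconds) as variables.  The supported surface is the
usual arithmetic one:

* operators ``+  -  *  /  ^  %`` with standard precedence, ``^`` binding
  tightest and right-associative, unary sign, parentheses;
* numeric literals in standard or scientific notation (``3.6e-10``);
* one-argument functions ``abs acos asin atan cbrt ceil cos cosh exp
  floor log sin sinh sqrt tan tanh`` and the two-argument integer
  division ``div(x, y)`` (floor division, so ``div(28, 24) == 1``);
* the predefined constant ``pi``.

Multiplication is always explicit (``2*pi``, never ``2pi``).

Conditional expressions are ordered lists of *cases*.  Each case carries
zero or more comparison conditions and a value expression; evaluation
returns the value of the first case whose conditions all hold, and 0.0
when no case holds.  The concrete text grammar, with ``;`` separating
both conditions and cases::

    cond ; cond ; ... ; cond : value ; <next case> ; ... ; value

A trailing bare expression (no comparison, no ``:``) is an unconditional
case.  Comparison operators are exactly ``=  <  >  <=  >=``; ``=``
compares with absolute tolerance 1e-9 because both sides are real
valued.  Example — 1000 molecules for the first five minutes, 100 for
the next five, none afterwards::

    Time < 5*60 : 1000 ; Time < 10*60 : 100 ; 0
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "Expression",
    "ConditionalExpression",
    "ExpressionError",
    "parse",
    "evaluate",
    "render",
    "parse_conditional",
    "evaluate_conditional",
    "FUNCTIONS",
    "EQ_TOLERANCE",
]

EQ_TOLERANCE = 1e-9

Bindings = Mapping[str, float]


class ExpressionError(ValueError):
    """Syntax or evaluation error; message carries the position or name."""


def _div(x: float, y: float) -> float:
    if y == 0:
        raise ExpressionError("division by zero in div()")
    return float(math.floor(x / y))


FUNCTIONS = {
    "abs": (1, abs),
    "acos": (1, math.acos),
    "asin": (1, math.asin),
    "atan": (1, math.atan),
    "cbrt": (1, lambda x: math.copysign(abs(x) ** (1.0 / 3.0), x)),
    "ceil": (1, lambda x: float(math.ceil(x))),
    "cos": (1, math.cos),
    "cosh": (1, math.cosh),
    "exp": (1, math.exp),
    "floor": (1, lambda x: float(math.floor(x))),
    "log": (1, math.log),
    "sin": (1, math.sin),
    "sinh": (1, math.sinh),
    "sqrt": (1, math.sqrt),
    "tan": (1, math.tan),
    "tanh": (1, math.tanh),
    "div": (2, _div),
}

CONSTANTS = {"pi": math.pi}

_COMPARATORS = ("<=", ">=", "<", ">", "=")


# -- tokenizer -------------------------------------------------------------


@dataclass
class _Token:
    kind: str  # num | name | op | lparen | rparen | comma | cmp
    text: str
    pos: int
    value: float = 0.0


def _tokenize(text: str, allow_cmp: bool = False) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch.isdigit() or (ch == "." and i + 1 < n and text[i + 1].isdigit()):
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
            lit = text[i:j]
            try:
                val = float(lit)
            except ValueError:
                raise ExpressionError(f"bad numeric literal {lit!r} at position {i}")
            tokens.append(_Token("num", lit, i, val))
            i = j
            continue
        if ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(_Token("name", text[i:j], i))
            i = j
            continue
        if allow_cmp and text[i : i + 2] in ("<=", ">="):
            tokens.append(_Token("cmp", text[i : i + 2], i))
            i += 2
            continue
        if allow_cmp and ch in "<>=":
            tokens.append(_Token("cmp", ch, i))
            i += 1
            continue
        if ch in "+-*/^%":
            tokens.append(_Token("op", ch, i))
            i += 1
            continue
        if ch == "(":
            tokens.append(_Token("lparen", ch, i))
            i += 1
            continue
        if ch == ")":
            tokens.append(_Token("rparen", ch, i))
            i += 1
            continue
        if ch == ",":
            tokens.append(_Token("comma", ch, i))
            i += 1
            continue
        raise ExpressionError(f"unexpected character {ch!r} at position {i}")
    return tokens


# -- syntax tree -----------------------------------------------------------


class _Node:
    __slots__ = ()


@dataclass(frozen=True)
class _Num(_Node):
    value: float

    __slots__ = ("value",)


@dataclass(frozen=True)
class _Var(_Node):
    name: str

    __slots__ = ("name",)


@dataclass(frozen=True)
class _Unary(_Node):
    op: str
    operand: _Node

    __slots__ = ("op", "operand")


@dataclass(frozen=True)
class _Binary(_Node):
    op: str
    left: _Node
    right: _Node

    __slots__ = ("op", "left", "right")


@dataclass(frozen=True)
class _Call(_Node):
    func: str
    args: tuple[_Node, ...]

    __slots__ = ("func", "args")


@dataclass(frozen=True)
class Expression:
    """A parsed, immutable mathematical expression."""

    root: _Node
    text: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text

    def variables(self) -> set[str]:
        out: set[str] = set()
        _collect_vars(self.root, out)
        return out


def _collect_vars(node: _Node, out: set[str]) -> None:
    if isinstance(node, _Var):
        out.add(node.name)
    elif isinstance(node, _Unary):
        _collect_vars(node.operand, out)
    elif isinstance(node, _Binary):
        _collect_vars(node.left, out)
        _collect_vars(node.right, out)
    elif isinstance(node, _Call):
        for a in node.args:
            _collect_vars(a, out)


class _Parser:
    """Recursive-descent parser; precedence +,- < *,/,% < unary < ^."""

    def __init__(self, tokens: list[_Token], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise ExpressionError(
                f"unexpected end of expression at position {len(self.text)}"
            )
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.next()
        if tok.kind != kind:
            raise ExpressionError(
                f"expected {kind} but found {tok.text!r} at position {tok.pos}"
            )
        return tok

    def parse_expression(self) -> _Node:
        node = self.parse_term()
        while (tok := self.peek()) is not None and tok.kind == "op" and tok.text in "+-":
            self.next()
            node = _Binary(tok.text, node, self.parse_term())
        return node

    def parse_term(self) -> _Node:
        node = self.parse_unary()
        while (tok := self.peek()) is not None and tok.kind == "op" and tok.text in "*/%":
            self.next()
            node = _Binary(tok.text, node, self.parse_unary())
        return node

    def parse_unary(self) -> _Node:
        tok = self.peek()
        if tok is not None and tok.kind == "op" and tok.text in "+-":
            self.next()
            return _Unary(tok.text, self.parse_unary())
        return self.parse_power()

    def parse_power(self) -> _Node:
        base = self.parse_atom()
        tok = self.peek()
        if tok is not None and tok.kind == "op" and tok.text == "^":
            self.next()
            # right-associative; exponent may carry a sign: 2^-3
            return _Binary("^", base, self.parse_unary())
        return base

    def parse_atom(self) -> _Node:
        tok = self.next()
        if tok.kind == "num":
            return _Num(tok.value)
        if tok.kind == "name":
            nxt = self.peek()
            if nxt is not None and nxt.kind == "lparen":
                if tok.text not in FUNCTIONS:
                    raise ExpressionError(
                        f"unknown function {tok.text!r} at position {tok.pos}"
                    )
                arity = FUNCTIONS[tok.text][0]
                self.next()
                args = [self.parse_expression()]
                while (p := self.peek()) is not None and p.kind == "comma":
                    self.next()
                    args.append(self.parse_expression())
                self.expect("rparen")
                if len(args) != arity:
                    raise ExpressionError(
                        f"function {tok.text!r} takes {arity} argument(s), got {len(args)}"
                    )
                return _Call(tok.text, tuple(args))
            if tok.text in CONSTANTS:
                return _Num(CONSTANTS[tok.text])
            return _Var(tok.text)
        if tok.kind == "lparen":
            node = self.parse_expression()
            self.expect("rparen")
            return node
        raise ExpressionError(f"unexpected {tok.text!r} at position {tok.pos}")


def parse(text: str) -> Expression:
    """Parse an expression string into an :class:`Expression` tree."""
    if not text or not text.strip():
        raise ExpressionError("empty expression")
    tokens = _tokenize(text)
    parser = _Parser(tokens, text)
    root = parser.parse_expression()
    if parser.peek() is not None:
        tok = parser.peek()
        raise ExpressionError(f"trailing input {tok.text!r} at position {tok.pos}")
    return Expression(root, text.strip())


def _eval(node: _Node, b: Bindings) -> float:
    if isinstance(node, _Num):
        return node.value
    if isinstance(node, _Var):
        if node.name not in b:
            raise ExpressionError(f"unbound variable {node.name!r}")
        return float(b[node.name])
    if isinstance(node, _Unary):
        v = _eval(node.operand, b)
        return -v if node.op == "-" else +v
    if isinstance(node, _Binary):
        left = _eval(node.left, b)
        right = _eval(node.right, b)
        op = node.op
        if op == "+":
            return left + right
        if op == "-":
            return left - right
        if op == "*":
            return left * right
        if op == "/":
            if right == 0:
                raise ExpressionError("division by zero")
            return left / right
        if op == "^":
            return left**right
        if op == "%":
            if right == 0:
                raise ExpressionError("modulo by zero")
            # remainder carries the sign of the dividend
            return math.fmod(left, right)
        raise ExpressionError(f"unknown operator {op!r}")
    if isinstance(node, _Call):
        args = [_eval(a, b) for a in node.args]
        try:
            return float(FUNCTIONS[node.func][1](*args))
        except ExpressionError:
            raise
        except ValueError as exc:
            raise ExpressionError(f"domain error in {node.func}(): {exc}") from exc
    raise ExpressionError(f"unknown node {node!r}")  # pragma: no cover


def evaluate(e: Expression, bindings: Bindings | None = None) -> float:
    """Evaluate ``e`` under the given variable bindings; pure, no side effects."""
    return _eval(e.root, bindings or {})


def _render(node: _Node) -> str:
    if isinstance(node, _Num):
        return repr(node.value)
    if isinstance(node, _Var):
        return node.name
    if isinstance(node, _Unary):
        return f"({node.op}{_render(node.operand)})"
    if isinstance(node, _Binary):
        return f"({_render(node.left)} {node.op} {_render(node.right)})"
    if isinstance(node, _Call):
        return f"{node.func}({', '.join(_render(a) for a in node.args)})"
    raise ExpressionError(f"unknown node {node!r}")  # pragma: no cover


def render(e: Expression) -> str:
    """A fully parenthesized textual form that re-parses to the same tree."""
    return _render(e.root)


# -- conditional expressions ----------------------------------------------


@dataclass(frozen=True)
class _Condition:
    left: Expression
    op: str  # one of =, <, >, <=, >=
    right: Expression

    def holds(self, b: Bindings) -> bool:
        lv = evaluate(self.left, b)
        rv = evaluate(self.right, b)
        if self.op == "=":
            return abs(lv - rv) <= EQ_TOLERANCE
        if self.op == "<":
            return lv < rv
        if self.op == ">":
            return lv > rv
        if self.op == "<=":
            return lv <= rv
        return lv >= rv


@dataclass(frozen=True)
class _Case:
    conditions: tuple[_Condition, ...]
    value: Expression


@dataclass(frozen=True)
class ConditionalExpression:
    """Ordered cases; first case whose conditions all hold wins, default 0."""

    cases: tuple[_Case, ...]
    text: str

    def variables(self) -> set[str]:
        out: set[str] = set()
        for case in self.cases:
            for cond in case.conditions:
                out |= cond.left.variables() | cond.right.variables()
            out |= case.value.variables()
        return out


def _split_top_level(text: str, sep: str) -> list[str]:
    parts, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == sep and depth == 0:
            parts.append(text[start:i])
            start = i + 1
    parts.append(text[start:])
    return parts


def _find_comparator(segment: str) -> tuple[int, str] | None:
    depth = 0
    i = 0
    while i < len(segment):
        ch = segment[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif depth == 0 and ch in "<>=":
            if segment[i : i + 2] in ("<=", ">="):
                return i, segment[i : i + 2]
            return i, ch
        i += 1
    return None


def _parse_condition(segment: str, offset: int) -> _Condition:
    found = _find_comparator(segment)
    if found is None:
        raise ExpressionError(
            f"condition missing comparison operator near position {offset}"
        )
    i, op = found
    left, right = segment[:i], segment[i + len(op) :]
    if not left.strip() or not right.strip():
        raise ExpressionError(
            f"condition with dangling comparison operator at position {offset + i}"
        )
    return _Condition(parse(left), op, parse(right))


def parse_conditional(text: str) -> ConditionalExpression:
    """Parse the ``cond ; ... ; cond : value ; ...`` case syntax."""
    if not text or not text.strip():
        raise ExpressionError("empty conditional expression")
    segments = _split_top_level(text, ";")
    cases: list[_Case] = []
    pending: list[_Condition] = []
    offset = 0
    for seg in segments:
        if not seg.strip():
            raise ExpressionError(
                f"empty segment (dangling semicolon) at position {offset}"
            )
        parts = _split_top_level(seg, ":")
        if len(parts) > 2:
            raise ExpressionError(f"more than one ':' in case at position {offset}")
        if len(parts) == 2:
            cond_text, value_text = parts
            pending.append(_parse_condition(cond_text, offset))
            if not value_text.strip():
                raise ExpressionError(
                    f"case with no value after ':' at position {offset}"
                )
            cases.append(_Case(tuple(pending), parse(value_text)))
            pending = []
        elif _find_comparator(seg) is not None:
            pending.append(_parse_condition(seg, offset))
        else:
            if pending:
                raise ExpressionError(
                    f"condition missing comparison operator at position {offset}"
                )
            cases.append(_Case((), parse(seg)))
        offset += len(seg) + 1
    if pending:
        raise ExpressionError("trailing conditions with no ': value'")
    return ConditionalExpression(tuple(cases), text.strip())


def evaluate_conditional(c: ConditionalExpression, bindings: Bindings | None = None) -> float:
    """Value of the first satisfied case; 0.0 when no case is satisfied."""
    b = bindings or {}
    for case in c.cases:
        if all(cond.holds(b) for cond in case.conditions):
            return evaluate(case.value, b)
    return 0.0
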