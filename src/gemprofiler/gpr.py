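"""Gene-protein-reaction (GPR) rule parsing and numeric evaluation.

A GPR rule is a Boolean expression over gene ids: AND joins the subunits of
an enzyme complex (all required), OR joins isozymes (any suffices).  For
reaction activity scoring the operators are evaluated numerically on
expression abundances: AND is the minimum of its children and OR their sum,
so a complex is limited by its scarcest subunit while isozymes contribute
additively.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Union

__all__ = [
    "Gene",
    "And",
    "Or",
    "GPRExpression",
    "GPRParseError",
    "parse_gpr",
    "evaluate_ras",
    "gpr_genes",
]


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple["GPRExpression", ...]

    def __post_init__(self) -> None:
        assert len(self.children) >= 2


@dataclass(frozen=True)
class Or:
    children: tuple["GPRExpression", ...]

    def __post_init__(self) -> None:
        assert len(self.children) >= 2


GPRExpression = Union[Gene, And, Or]


class GPRParseError(ValueError):
    """Malformed GPR rule; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lpar>\() |
        (?P<rpar>\)) |
        (?P<and>&&|&|\band\b|\bAND\b|\bAnd\b) |
        (?P<or>\|\||\||\bor\b|\bOR\b|\bOr\b) |
        (?P<gene>[^\s()&|]+)
    )""",
    re.VERBOSE,
)


def _tokenize(rule: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None or m.end() == pos:
            raise GPRParseError(f"unexpected character {rule[pos]!r}", pos)
        kind = m.lastgroup
        text = m.group(kind)
        start = m.start(kind)
        if kind == "gene" and text.lower() in {"and", "or"}:
            kind = text.lower()
        tokens.append((kind, text, start))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over:  expr := term (OR term)* ;
    term := factor (AND factor)* ;  factor := GENE | '(' expr ')'.
    AND binds tighter than OR; operator chains become n-ary nodes."""

    def __init__(self, rule: str):
        self.rule = rule
        self.tokens = _tokenize(rule)
        self.i = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _offset(self) -> int:
        tok = self.peek()
        return tok[2] if tok else len(self.rule)

    def parse(self) -> GPRExpression:
        if not self.tokens:
            raise GPRParseError("empty rule", 0)
        expr = self.expr()
        if self.peek() is not None:
            raise GPRParseError(f"unexpected token {self.peek()[1]!r}", self._offset())
        return expr

    def expr(self) -> GPRExpression:
        parts = [self.term()]
        while (tok := self.peek()) and tok[0] == "or":
            self.i += 1
            parts.append(self.term())
        # chains become one n-ary node, but parenthesised sub-rules keep
        # their own node so sums associate exactly as written
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def term(self) -> GPRExpression:
        parts = [self.factor()]
        while (tok := self.peek()) and tok[0] == "and":
            self.i += 1
            parts.append(self.factor())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def factor(self) -> GPRExpression:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("dangling operator: expected gene or '('", self._offset())
        kind, text, offset = tok
        if kind == "gene":
            self.i += 1
            return Gene(text)
        if kind == "lpar":
            self.i += 1
            inner = self.expr()
            closing = self.peek()
            if closing is None or closing[0] != "rpar":
                raise GPRParseError("unbalanced parentheses: missing ')'", self._offset())
            self.i += 1
            return inner
        if kind == "rpar":
            raise GPRParseError("unbalanced parentheses: unexpected ')'", offset)
        raise GPRParseError(f"dangling operator {text!r}", offset)


def parse_gpr(rule: str) -> GPRExpression:
    """Parse a GPR rule string into an AST.

    Accepts ``and``/``or`` in any case plus ``&&``, ``||``, ``&``, ``|``,
    and parentheses.  With no parentheses AND binds tighter than OR.
    """
    return _Parser(rule).parse()


def evaluate_ras(
    expr: GPRExpression,
    abundances: Mapping[str, float],
    missing_policy: str = "skip",
) -> Optional[float]:
    """Evaluate a GPR AST on gene abundances: AND -> min, OR -> sum.

    ``missing_policy`` governs genes absent from ``abundances``: under
    ``"skip"`` the gene is dropped from its operator and a node whose
    children are all undefined is itself undefined (returned as None, the
    caller then leaves the reaction unconstrained); under ``"zero"`` an
    absent gene counts as 0.  A score of 0 is a legitimate value (fully
    silent reaction), distinct from undefined.
    """
    if missing_policy not in {"skip", "zero"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if isinstance(expr, Gene):
        if expr.name in abundances:
            return float(abundances[expr.name])
        return 0.0 if missing_policy == "zero" else None
    values = [
        v
        for child in expr.children
        if (v := evaluate_ras(child, abundances, missing_policy)) is not None
    ]
    if not values:
        return None
    return min(values) if isinstance(expr, And) else float(sum(values))


def gpr_genes(expr: GPRExpression) -> set[str]:
    """All gene ids appearing in the AST."""
    if isinstance(expr, Gene):
        return {expr.name}
    out: set[str] = set()
    for child in expr.children:
        out |= gpr_genes(child)
    return out
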