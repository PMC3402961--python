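"""Safe arithmetic expression strings for rate laws and external terms.

Rate laws are declarative strings over metabolite ids, parameter names, the
time symbol ``t`` and a small whitelist of math functions. They are parsed
once with :mod:`ast`, checked against the whitelist and compiled to a code
object, so repeated evaluation during ODE integration is cheap.
"""

from __future__ import annotations

import ast
import math
from typing import Any, Mapping

__all__ = ["CompiledExpression", "ExpressionError", "compile_expression"]

_ALLOWED_FUNCS: dict[str, Any] = {
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "abs": abs,
    "min": min,
    "max": max,
    "pow": pow,
    "tanh": math.tanh,
}

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Num,
    ast.Constant,
    ast.Name,
    ast.Load,
    ast.Call,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.USub,
    ast.UAdd,
    ast.Mod,
)


class ExpressionError(ValueError):
    """Raised when a rate-law string is malformed or uses forbidden syntax."""


class CompiledExpression:
    """A validated, compiled arithmetic expression.

    Parameters
    ----------
    source:
        The expression string, e.g. ``"Vmax * g6p / (Km + g6p)"``.

    Attributes
    ----------
    names:
        Free symbols of the expression (excluding whitelisted functions).
    """

    __slots__ = ("source", "names", "_code")

    def __init__(self, source: str):
        self.source = source
        try:
            tree = ast.parse(source, mode="eval")
        except SyntaxError as exc:  # pragma: no cover - message path
            raise ExpressionError(f"cannot parse expression {source!r}: {exc}") from exc
        names: set[str] = set()
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED_NODES):
                raise ExpressionError(
                    f"forbidden syntax {type(node).__name__!r} in expression {source!r}"
                )
            if isinstance(node, ast.Call):
                if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCS:
                    raise ExpressionError(f"forbidden function call in expression {source!r}")
            if isinstance(node, ast.Name):
                if node.id not in _ALLOWED_FUNCS:
                    names.add(node.id)
        self.names = frozenset(names)
        self._code = compile(tree, "<rate-law>", "eval")

    def evaluate(self, env: Mapping[str, float]) -> float:
        """Evaluate the expression with symbols bound from ``env``."""
        try:
            return float(eval(self._code, {"__builtins__": {}}, {**_ALLOWED_FUNCS, **env}))
        except NameError as exc:
            raise ExpressionError(f"unbound symbol in expression {self.source!r}: {exc}") from exc
        except (ZeroDivisionError, OverflowError, ValueError) as exc:
            raise ExpressionError(f"domain error evaluating {self.source!r}: {exc}") from exc

    def __repr__(self) -> str:  # pragma: no cover
        return f"CompiledExpression({self.source!r})"


def compile_expression(source: str) -> CompiledExpression:
    return CompiledExpression(source)
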