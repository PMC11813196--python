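"""Boolean rule language shared by enabling conditions and diagnosis rules.

An :class:`Expression` is a finite tree whose leaves are either the constant
``true`` or an *atom* — a required ``(item_id, response)`` pair. Internal
nodes are ``and`` / ``or`` / ``not``. Atom truth against a findings map is
strict: an atom holds iff the findings record *exactly* the required
response for the item. An unanswered item therefore makes its atoms false,
which means ``not(atom)`` holds for unanswered items — absence of evidence
is treated as evidence absent, a deliberate modeling convention documented
in the methods note.

JSON dialect (used in knowledge-base files)::

    {"atom": {"item": "buttock_pain", "response": "present"}}
    {"or": [ <expr>, ... ]}
    {"and": [ <expr>, ... ]}
    {"not": <expr>}
    {"true": true}          (also accepted: the bare string "true")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

from .errors import KBFormatError

__all__ = ["Expression", "TRUE", "parse_expression"]

_KINDS = frozenset({"atom", "and", "or", "not", "true"})


@dataclass(frozen=True)
class Expression:
    """Immutable Boolean expression tree node."""

    kind: str
    item_id: str | None = None
    response: str | None = None
    children: tuple["Expression", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise KBFormatError(f"unknown expression kind {self.kind!r}")
        if self.kind == "atom":
            if not self.item_id or self.response is None:
                raise KBFormatError("atom requires an item id and a response")
            if self.children:
                raise KBFormatError("atom nodes take no children")
        elif self.kind == "true":
            if self.children:
                raise KBFormatError("'true' nodes take no children")
        elif self.kind == "not":
            if len(self.children) != 1:
                raise KBFormatError("'not' takes exactly one child")
        else:  # and / or
            if not self.children:
                raise KBFormatError(f"'{self.kind}' requires at least one child")

    # -- constructors -------------------------------------------------
    @staticmethod
    def atom(item_id: str, response: str = "present") -> "Expression":
        return Expression("atom", item_id=item_id, response=response)

    @staticmethod
    def any_of(*children: "Expression") -> "Expression":
        return Expression("or", children=tuple(children))

    @staticmethod
    def all_of(*children: "Expression") -> "Expression":
        return Expression("and", children=tuple(children))

    @staticmethod
    def negate(child: "Expression") -> "Expression":
        return Expression("not", children=(child,))

    # -- queries ------------------------------------------------------
    @property
    def is_always_true(self) -> bool:
        return self.kind == "true"

    def atoms(self) -> set[tuple[str, str]]:
        """The set of distinct ``(item_id, response)`` pairs referenced."""
        return set(self._iter_atoms())

    def _iter_atoms(self) -> Iterator[tuple[str, str]]:
        if self.kind == "atom":
            yield (self.item_id, self.response)  # type: ignore[misc]
        for child in self.children:
            yield from child._iter_atoms()

    def evaluate(self, findings: Mapping[str, str]) -> bool:
        """Standard Boolean semantics; unanswered atoms are false."""
        if self.kind == "true":
            return True
        if self.kind == "atom":
            return findings.get(self.item_id) == self.response
        if self.kind == "not":
            return not self.children[0].evaluate(findings)
        if self.kind == "and":
            return all(c.evaluate(findings) for c in self.children)
        return any(c.evaluate(findings) for c in self.children)

    # -- (de)serialization --------------------------------------------
    def to_json(self) -> Any:
        if self.kind == "true":
            return {"true": True}
        if self.kind == "atom":
            return {"atom": {"item": self.item_id, "response": self.response}}
        if self.kind == "not":
            return {"not": self.children[0].to_json()}
        return {self.kind: [c.to_json() for c in self.children]}


TRUE = Expression("true")


def parse_expression(obj: Any, where: str = "expression") -> Expression:
    """Parse the JSON dialect into an :class:`Expression`.

    ``where`` names the enclosing field in error messages so knowledge-base
    authors can locate the offending rule.
    """
    if obj == "true" or obj is True:
        return TRUE
    if not isinstance(obj, dict) or len(obj) != 1:
        raise KBFormatError(
            f"{where}: expected a single-key expression object, got {obj!r}"
        )
    (key, value), = obj.items()
    if key == "true":
        return TRUE
    if key == "atom":
        if not isinstance(value, dict) or "item" not in value:
            raise KBFormatError(f"{where}: atom requires an 'item' key")
        return Expression.atom(str(value["item"]), str(value.get("response", "present")))
    if key == "not":
        return Expression.negate(parse_expression(value, where))
    if key in ("and", "or"):
        if not isinstance(value, list) or not value:
            raise KBFormatError(f"{where}: '{key}' requires a non-empty list")
        return Expression(key, children=tuple(parse_expression(v, where) for v in value))
    raise KBFormatError(f"{where}: unknown expression kind {key!r}")
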