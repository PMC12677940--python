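"""Cohort filter documents: boolean trees of predicates in the GDC JSON dialect.

A filter is a tree of group nodes (``and`` / ``or`` over a non-empty child
list) and leaf predicates.  Supported leaf operators:

``in``
    ``{"op":"in","content":{"field":"<path>","value":["A","B"]}}`` — the case
    matches when any of its values for the field is listed.
``>=`` / ``<=``
    ``{"op":">=","content":{"field":"<path>","value":20000}}`` — numeric
    comparison; a closed range is an ``and`` of a ``>=`` and a ``<=`` leaf.

Two validation strictness levels are exposed.  *Structural* validation checks
node shapes only (this mirrors what a JSON schema can enforce).  *Strict*
validation additionally closes the language over a data dictionary: every
leaf field must resolve, every ``in`` value must belong to the property's
controlled vocabulary, and every numeric constant must fall inside the
property's [min, max] range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .dictionary import ENUMERATED, NUMERIC, DataDictionary

__all__ = [
    "Leaf",
    "Group",
    "CohortFilter",
    "ValidationReport",
    "FilterParseError",
    "FilterStructureError",
    "GROUP_OPS",
    "LEAF_OPS",
    "parse_filter",
    "serialize_filter",
    "serialize_node",
    "validate_filter",
    "canonicalize",
    "filters_equal",
]

GROUP_OPS = ("and", "or")
LEAF_OPS = ("in", ">=", "<=")


class FilterParseError(ValueError):
    """Input text is not JSON at all."""


class FilterStructureError(ValueError):
    """JSON parsed but does not match the filter node grammar."""

    def __init__(self, path: str, message: str):
        self.path = path
        self.message = message
        super().__init__(f"{path}: {message}")


@dataclass(frozen=True)
class Leaf:
    op: str
    field: str
    value: tuple[str, ...] | int | float


@dataclass(frozen=True)
class Group:
    op: str
    content: tuple


FilterNode = Leaf | Group


@dataclass(frozen=True)
class CohortFilter:
    """A filter document; the serialized root is always an ``and`` group."""

    root: FilterNode


@dataclass
class ValidationReport:
    structural_ok: bool
    strict_ok: bool
    issues: list = field(default_factory=list)  # [(tree path, message)]


# ---------------------------------------------------------------------------
# parse / serialize


def _parse_node(obj, path: str) -> FilterNode:
    if not isinstance(obj, dict):
        raise FilterStructureError(path, f"expected an object, got {type(obj).__name__}")
    op = obj.get("op")
    if op in GROUP_OPS:
        content = obj.get("content")
        if not isinstance(content, list):
            raise FilterStructureError(path, "group content must be a list")
        if not content:
            raise FilterStructureError(path, "group content must be non-empty")
        children = tuple(
            _parse_node(child, f"{path}.content[{i}]") for i, child in enumerate(content)
        )
        return Group(op=op, content=children)
    if op in LEAF_OPS:
        content = obj.get("content")
        if not isinstance(content, dict):
            raise FilterStructureError(path, "leaf content must be an object")
        fld = content.get("field")
        if not isinstance(fld, str) or not fld:
            raise FilterStructureError(path, "leaf field must be a non-empty string")
        value = content.get("value")
        if op == "in":
            if not isinstance(value, list) or not value:
                raise FilterStructureError(
                    path, '"in" value must be a non-empty list'
                )
            for j, v in enumerate(value):
                if not isinstance(v, str):
                    raise FilterStructureError(
                        f"{path}.value[{j}]", "values must be strings"
                    )
            return Leaf(op=op, field=fld, value=tuple(value))
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise FilterStructureError(path, f"{op!r} value must be a number")
        return Leaf(op=op, field=fld, value=value)
    raise FilterStructureError(path, f"unknown op {op!r}")


def parse_filter(text: str) -> CohortFilter:
    """Parse filter JSON text into a :class:`CohortFilter`.

    Clause order is preserved.  Non-JSON input raises
    :class:`FilterParseError`; JSON that does not match the node grammar
    raises :class:`FilterStructureError` carrying the tree path.
    """
    try:
        obj = json.loads(text)
    except (json.JSONDecodeError, TypeError) as exc:
        raise FilterParseError(f"not valid JSON: {exc}") from None
    return CohortFilter(root=_parse_node(obj, "root"))


def _num(value):
    # Integral floats serialize as ints so canonical text is stable.
    if isinstance(value, float) and value.is_integer():
        return int(value)
    return value


def _node_to_obj(node: FilterNode):
    if isinstance(node, Group):
        return {"op": node.op, "content": [_node_to_obj(c) for c in node.content]}
    value = list(node.value) if node.op == "in" else _num(node.value)
    return {"op": node.op, "content": {"field": node.field, "value": value}}


def serialize_node(node: FilterNode) -> str:
    """Compact deterministic JSON for a single node (no root wrapping)."""
    return json.dumps(_node_to_obj(node), separators=(",", ":"))


def serialize_filter(f: CohortFilter) -> str:
    """Deterministic compact JSON; the root is wrapped into an ``and`` group.

    ``parse_filter(serialize_filter(f))`` is tree-equal to ``f`` up to the
    root wrapping.
    """
    root = f.root
    if not (isinstance(root, Group) and root.op == "and"):
        root = Group(op="and", content=(root,))
    return serialize_node(root)


# ---------------------------------------------------------------------------
# validation


def _structural_issues(node: FilterNode, path: str, issues: list) -> None:
    if isinstance(node, Group):
        if node.op not in GROUP_OPS:
            issues.append((path, f"unknown group op {node.op!r}"))
        if not node.content:
            issues.append((path, "group content is empty"))
        for i, child in enumerate(node.content):
            _structural_issues(child, f"{path}.content[{i}]", issues)
    elif isinstance(node, Leaf):
        if node.op not in LEAF_OPS:
            issues.append((path, f"unknown leaf op {node.op!r}"))
        elif node.op == "in":
            if not isinstance(node.value, tuple) or not node.value:
                issues.append((path, '"in" value list is empty'))
            elif not all(isinstance(v, str) and v for v in node.value):
                issues.append((path, '"in" values must be non-empty strings'))
        elif isinstance(node.value, bool) or not isinstance(node.value, (int, float)):
            issues.append((path, f"{node.op!r} value must be a number"))
        if not node.field:
            issues.append((path, "leaf field is empty"))
    else:
        issues.append((path, f"not a filter node: {type(node).__name__}"))


def _strict_issues(node: FilterNode, dd: DataDictionary, path: str, issues: list) -> None:
    if isinstance(node, Group):
        for i, child in enumerate(node.content):
            _strict_issues(child, dd, f"{path}.content[{i}]", issues)
        return
    spec = dd.get(node.field)
    if spec is None:
        issues.append((path, f"field {node.field!r} not in dictionary"))
        return
    if node.op == "in":
        if spec.kind != ENUMERATED:
            issues.append((path, f'"in" targets non-enumerated field {node.field!r}'))
            return
        allowed = set(spec.allowed_values)
        for v in node.value:
            if v not in allowed:
                issues.append(
                    (path, f"value {v!r} not allowed for field {node.field!r}")
                )
    else:
        if spec.kind != NUMERIC:
            issues.append(
                (path, f"numeric comparison targets non-numeric field {node.field!r}")
            )
            return
        if not (spec.min_value <= node.value <= spec.max_value):
            issues.append(
                (
                    path,
                    f"constant {node.value} outside [{spec.min_value}, "
                    f"{spec.max_value}] for field {node.field!r}",
                )
            )


def validate_filter(
    f: CohortFilter, dd: DataDictionary | None = None, level: str = "strict"
) -> ValidationReport:
    """Validate a filter at the requested strictness level.

    Findings are returned in the report, never raised, and the filter is not
    mutated.  ``level="strict"`` requires a dictionary.
    """
    if level not in ("structural", "strict"):
        raise ValueError(f"unknown validation level {level!r}")
    issues: list = []
    _structural_issues(f.root, "root", issues)
    structural_ok = not issues
    strict_ok = structural_ok
    if level == "strict":
        if dd is None:
            raise ValueError("strict validation requires a data dictionary")
        if structural_ok:
            strict_list: list = []
            _strict_issues(f.root, dd, "root", strict_list)
            issues.extend(strict_list)
            strict_ok = not strict_list
        else:
            strict_ok = False
    return ValidationReport(structural_ok=structural_ok, strict_ok=strict_ok, issues=issues)


# ---------------------------------------------------------------------------
# canonical form


def _canonical_node(node: FilterNode) -> FilterNode:
    if isinstance(node, Leaf):
        if node.op == "in":
            return Leaf(op=node.op, field=node.field, value=tuple(sorted(set(node.value))))
        return Leaf(op=node.op, field=node.field, value=_num(node.value))
    children = [_canonical_node(c) for c in node.content]
    children.sort(key=serialize_node)
    return Group(op=node.op, content=tuple(children))


def canonicalize(f: CohortFilter) -> CohortFilter:
    """Canonical form: ``in`` values sorted and deduped, sibling clauses sorted
    by their serialized text, a bare/non-``and`` root wrapped in an ``and``
    group.  Retrieval semantics are unchanged."""
    root = _canonical_node(f.root)
    if not (isinstance(root, Group) and root.op == "and"):
        root = Group(op="and", content=(root,))
    return CohortFilter(root=root)


def filters_equal(a: CohortFilter, b: CohortFilter) -> bool:
    """Equality up to canonical form."""
    return serialize_filter(canonicalize(a)) == serialize_filter(canonicalize(b))
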