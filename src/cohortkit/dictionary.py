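"""Data dictionary: the universe of filterable case properties.

A :class:`DataDictionary` is the single source of truth every other module is
parameterized by: filter validation, synthetic sampling, verbalization labels,
and the constrained-decoding automaton all resolve property names and allowed
values through it.  Each property is either *enumerated* (a controlled
vocabulary of string values, e.g. disease type) or *numeric* (a closed
[min, max] range with units, e.g. age at diagnosis in days).

The canonical on-disk format is a single JSON object::

    {"version": "<label>",
     "properties": [
        {"name": "cases.demographic.gender", "kind": "enumerated",
         "allowed_values": ["female", "male"], "label": "gender"},
        {"name": "cases.diagnoses.age_at_diagnosis", "kind": "numeric",
         "min_value": 0, "max_value": 32872, "units": "days",
         "label": "age at diagnosis"},
     ]}

``label`` and ``units`` are optional; a missing label falls back to the last
dotted path segment with underscores replaced by spaces.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

__all__ = [
    "PropertySpec",
    "DataDictionary",
    "DictionaryError",
    "load_dictionary",
    "serialize_dictionary",
    "dictionary_report",
    "toy_dictionary_path",
    "load_toy_dictionary",
]

ENUMERATED = "enumerated"
NUMERIC = "numeric"

# Characters permitted in property names and enumerated values.  Restricting
# to printable ASCII without JSON metacharacters keeps serialized filters
# escape-free, which the character-level decoding automaton relies on.
_SAFE_CHARS = frozenset(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    " ._,;:()+/%<>=#&'!?@*[]{}|~^$-"
) - frozenset('"\\')


class DictionaryError(ValueError):
    """A dictionary document violated the format or a type invariant."""


def _check_safe(text: str, what: str) -> None:
    bad = set(text) - _SAFE_CHARS
    if bad:
        raise DictionaryError(
            f"{what} {text!r} contains unsupported characters: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class PropertySpec:
    """One filterable property: an enumerated vocabulary or a numeric range."""

    name: str
    kind: str
    allowed_values: tuple[str, ...] = ()
    min_value: float | None = None
    max_value: float | None = None
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise DictionaryError("property name must be non-empty")
        _check_safe(self.name, "property name")
        if self.kind == ENUMERATED:
            if not self.allowed_values:
                raise DictionaryError(
                    f"enumerated property {self.name!r} has no allowed values"
                )
            if len(set(self.allowed_values)) != len(self.allowed_values):
                raise DictionaryError(
                    f"enumerated property {self.name!r} has duplicate values"
                )
            for v in self.allowed_values:
                if not isinstance(v, str) or not v:
                    raise DictionaryError(
                        f"enumerated property {self.name!r} has an empty or "
                        f"non-string value: {v!r}"
                    )
                _check_safe(v, f"value of {self.name!r}")
            if self.min_value is not None or self.max_value is not None:
                raise DictionaryError(
                    f"enumerated property {self.name!r} must not carry bounds"
                )
        elif self.kind == NUMERIC:
            if self.min_value is None or self.max_value is None:
                raise DictionaryError(
                    f"numeric property {self.name!r} needs min_value and max_value"
                )
            if not (self.min_value <= self.max_value):
                raise DictionaryError(
                    f"numeric property {self.name!r}: min_value "
                    f"{self.min_value} > max_value {self.max_value}"
                )
            if self.allowed_values:
                raise DictionaryError(
                    f"numeric property {self.name!r} must not carry allowed_values"
                )
        else:
            raise DictionaryError(
                f"property {self.name!r} has unknown kind {self.kind!r}"
            )

    @property
    def display_label(self) -> str:
        """Human label for verbalization; falls back to the last path segment."""
        if self.label:
            return self.label
        return self.name.rsplit(".", 1)[-1].replace("_", " ")


@dataclass(frozen=True)
class DataDictionary:
    """Immutable collection of :class:`PropertySpec`, keyed by name."""

    properties: dict[str, PropertySpec] = field(default_factory=dict)
    version_label: str = ""

    def __post_init__(self) -> None:
        for name, spec in self.properties.items():
            if name != spec.name:
                raise DictionaryError(
                    f"property keyed {name!r} has mismatched name {spec.name!r}"
                )

    @staticmethod
    def from_specs(specs, version_label: str = "") -> "DataDictionary":
        props: dict[str, PropertySpec] = {}
        for spec in specs:
            if spec.name in props:
                raise DictionaryError(f"duplicate property name {spec.name!r}")
            props[spec.name] = spec
        return DataDictionary(properties=props, version_label=version_label)

    def __contains__(self, name: str) -> bool:
        return name in self.properties

    def __len__(self) -> int:
        return len(self.properties)

    def __iter__(self):
        return iter(self.properties.values())

    def get(self, name: str) -> PropertySpec | None:
        return self.properties.get(name)

    def __getitem__(self, name: str) -> PropertySpec:
        try:
            return self.properties[name]
        except KeyError:
            raise KeyError(f"unknown property {name!r}") from None

    def enumerated(self) -> list[PropertySpec]:
        return [p for p in self if p.kind == ENUMERATED]

    def numeric(self) -> list[PropertySpec]:
        return [p for p in self if p.kind == NUMERIC]


def load_dictionary(source: str | os.PathLike) -> DataDictionary:
    """Load a dictionary from a JSON file path or a JSON text string.

    Raises :class:`DictionaryError` naming the offending property on any
    invariant violation; malformed JSON raises ``json.JSONDecodeError`` with
    line/position information.
    """
    text = source
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    obj = json.loads(text)
    if not isinstance(obj, dict) or "properties" not in obj:
        raise DictionaryError('dictionary JSON must be {"version":…,"properties":[…]}')
    specs = []
    for i, entry in enumerate(obj["properties"]):
        if not isinstance(entry, dict):
            raise DictionaryError(f"properties[{i}] is not an object")
        try:
            specs.append(
                PropertySpec(
                    name=entry.get("name", ""),
                    kind=entry.get("kind", ""),
                    allowed_values=tuple(entry.get("allowed_values", ()) or ()),
                    min_value=entry.get("min_value"),
                    max_value=entry.get("max_value"),
                    units=entry.get("units", "") or "",
                    label=entry.get("label", "") or "",
                )
            )
        except DictionaryError as exc:
            raise DictionaryError(f"properties[{i}]: {exc}") from None
    return DataDictionary.from_specs(specs, version_label=obj.get("version", "") or "")


def serialize_dictionary(dd: DataDictionary) -> str:
    """Canonical JSON text; ``load_dictionary(serialize_dictionary(dd)) == dd``."""
    entries = []
    for spec in dd:
        entry: dict = {"name": spec.name, "kind": spec.kind}
        if spec.kind == ENUMERATED:
            entry["allowed_values"] = list(spec.allowed_values)
        else:
            entry["min_value"] = spec.min_value
            entry["max_value"] = spec.max_value
        if spec.units:
            entry["units"] = spec.units
        if spec.label:
            entry["label"] = spec.label
        entries.append(entry)
    return json.dumps(
        {"version": dd.version_label, "properties": entries}, indent=2
    )


def dictionary_report(dd: DataDictionary) -> dict:
    """Exact counts: properties, per-kind breakdown, distinct enumerated values."""
    enum_props = dd.enumerated()
    return {
        "version": dd.version_label,
        "n_properties": len(dd),
        "n_enumerated": len(enum_props),
        "n_numeric": len(dd.numeric()),
        "n_enumerated_values": sum(len(p.allowed_values) for p in enum_props),
    }


def toy_dictionary_path() -> str:
    """Path of the bundled toy dictionary (6 properties, GDC-flavored)."""
    return os.path.join(os.path.dirname(__file__), "data", "toy_dictionary.json")


def load_toy_dictionary() -> DataDictionary:
    return load_dictionary(toy_dictionary_path())
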