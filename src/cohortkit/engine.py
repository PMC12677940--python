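"""Local case retrieval: apply a cohort filter to an offline case store.

The store maps case IDs to multi-valued property assignments and stands in
for a remote case index.  Matching semantics:

* ``in`` leaf — existential: the case matches when *any* of its values for
  the field is in the filter's value list (cases can carry multiple
  diagnoses/samples, and a case is retrieved when any nested record matches).
* ``>=`` / ``<=`` leaf — existential over the case's numeric values.
* ``and`` group — intersection of child results; ``or`` — union.
* A missing property never matches (partially annotated cases are silently
  excluded, not errors), and an unknown field or value simply matches
  nothing — imprecise machine-generated names degrade retrieval rather than
  raising.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd

from .dictionary import NUMERIC, DataDictionary
from .filters import CohortFilter, FilterNode, Group, Leaf

__all__ = [
    "CaseRecord",
    "CaseStore",
    "apply_filter",
    "export_case_ids",
    "save_store_jsonl",
    "load_store_jsonl",
    "load_store_csv",
]


@dataclass(frozen=True)
class CaseRecord:
    """One case: an opaque ID plus property path → value-list assignments."""

    case_id: str
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        for path, vals in self.values.items():
            if len(set(vals)) != len(vals):
                raise ValueError(
                    f"case {self.case_id!r}: duplicate values for {path!r}"
                )


@dataclass
class CaseStore:
    """Collection of cases with unique IDs."""

    records: list[CaseRecord] = field(default_factory=list)
    dictionary_version: str = ""

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for cid in ids:
                if cid in seen:
                    dup = cid
                    break
                seen.add(cid)
            raise ValueError(f"duplicate case_id {dup!r} in store")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _leaf_matches(leaf: Leaf, record: CaseRecord) -> bool:
    vals = record.values.get(leaf.field, ())
    if leaf.op == "in":
        wanted = set(leaf.value)
        return any(v in wanted for v in vals)
    for v in vals:
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            continue
        if leaf.op == ">=" and v >= leaf.value:
            return True
        if leaf.op == "<=" and v <= leaf.value:
            return True
    return False


def _eval_node(node: FilterNode, store: CaseStore) -> set[str]:
    # Set-algebra evaluation: leaves scan the store once, groups combine
    # child sets.  (The per-case recursive oracle in the test suite is the
    # independent route.)
    if isinstance(node, Leaf):
        return {r.case_id for r in store if _leaf_matches(node, r)}
    sets = [_eval_node(child, store) for child in node.content]
    if node.op == "and":
        result = sets[0]
        for s in sets[1:]:
            result = result & s
        return result
    return set().union(*sets)


def apply_filter(f: CohortFilter, store: CaseStore) -> set[str]:
    """Return the set of case IDs retrieved by the filter."""
    return _eval_node(f.root, store)


def export_case_ids(ids, destination: str | os.PathLike) -> None:
    """Write one case ID per line, lexicographically sorted, UTF-8.

    Matches the portal-style export of a retrieved cohort as a plain text
    file of case identifiers.
    """
    with open(destination, "w", encoding="utf-8") as fh:
        for cid in sorted(ids):
            fh.write(cid + "\n")


# ---------------------------------------------------------------------------
# store I/O: JSONL (canonical, preserves multi-values) and flat CSV (for
# hand-made fixtures: columns case_id, property, value).


def save_store_jsonl(store: CaseStore, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if store.dictionary_version:
            fh.write(json.dumps({"dictionary_version": store.dictionary_version}) + "\n")
        for record in store:
            fh.write(
                json.dumps(
                    {"case_id": record.case_id,
                     "values": {k: list(v) for k, v in record.values.items()}},
                    sort_keys=True,
                )
                + "\n"
            )


def load_store_jsonl(path: str | os.PathLike) -> CaseStore:
    records = []
    version = ""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "case_id" not in obj:
                version = obj.get("dictionary_version", version)
                continue
            records.append(
                CaseRecord(
                    case_id=obj["case_id"],
                    values={k: tuple(v) for k, v in obj.get("values", {}).items()},
                )
            )
    return CaseStore(records=records, dictionary_version=version)


def load_store_csv(
    path: str | os.PathLike, dd: DataDictionary | None = None
) -> CaseStore:
    """Read a flat (case_id, property, value) CSV.

    CSV values are strings; when a dictionary is supplied, values of numeric
    properties are converted to numbers.
    """
    df = pd.read_csv(path, dtype=str)
    expected = {"case_id", "property", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"store CSV needs columns {sorted(expected)}")
    numeric_fields = (
        {p.name for p in dd.numeric()} if dd is not None else set()
    )
    by_case: dict[str, dict[str, list]] = {}
    for case_id, prop, value in df[["case_id", "property", "value"]].itertuples(
        index=False
    ):
        if prop in numeric_fields:
            value = float(value)
            if value.is_integer():
                value = int(value)
        bucket = by_case.setdefault(case_id, {}).setdefault(prop, [])
        if value not in bucket:
            bucket.append(value)
    records = [
        CaseRecord(case_id=cid, values={k: tuple(v) for k, v in props.items()})
        for cid, props in by_case.items()
    ]
    return CaseStore(
        records=records,
        dictionary_version=dd.version_label if dd is not None else "",
    )
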