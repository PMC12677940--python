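"""Synthetic corpora: random cohort filters, case stores, and paired queries.

The sampler draws fields and values uniformly from the data dictionary to
build strict-valid conjunctive filters; each filter is then *reverse
translated* into a natural-language query.  The default reverse translation
is a deterministic template renderer (so corpora are byte-reproducible); an
instruction-tuned chat model can be plugged in through
:func:`build_reverse_translation_prompt` + a caller-supplied completion
function.

Two verbalization styles are provided:

* ``verbose`` — enumerates every selected value in canonical clause order,
  e.g. ``cases where gender is female and project is TCGA-LUAD or TCGA-BRCA``.
* ``concise`` — collapses a leaf selecting *all* allowed values of a property
  into "any <label>" (the way a human would say "any lung lobe"), and merges
  a paired lower/upper bound into "between A and B".
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .dictionary import DataDictionary, PropertySpec
from .engine import CaseRecord, CaseStore, apply_filter
from .filters import CohortFilter, Group, Leaf, canonicalize, parse_filter, \
    serialize_filter, validate_filter

__all__ = [
    "SamplerConfig",
    "QueryFilterPair",
    "sample_filter",
    "sample_case_store",
    "verbalize",
    "build_reverse_translation_prompt",
    "reverse_translate",
    "make_corpus",
    "filter_eval_pairs",
    "write_corpus",
    "read_corpus",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Distributional knobs of the filter sampler.

    Defaults: uniform 1–4 clauses per filter, uniform 1–3 values per ``in``
    leaf, and a 0.2 probability that a clause is a numeric range (rendered as
    a ``>=``/``<=`` leaf pair with bounds drawn uniformly from the property's
    [min, max]).
    """

    seed: int = 0
    n_clauses_weights: dict = field(
        default_factory=lambda: {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}
    )
    n_values_weights: dict = field(default_factory=lambda: {1: 1.0, 2: 1.0, 3: 1.0})
    p_numeric: float = 0.2

    def __post_init__(self) -> None:
        for name, weights in (
            ("n_clauses_weights", self.n_clauses_weights),
            ("n_values_weights", self.n_values_weights),
        ):
            vals = list(weights.values())
            if any(w < 0 for w in vals) or sum(vals) <= 0:
                raise ValueError(f"{name} must be non-negative with positive sum")
        if not 0.0 <= self.p_numeric <= 1.0:
            raise ValueError("p_numeric must be in [0, 1]")


@dataclass(frozen=True)
class QueryFilterPair:
    """A natural-language query paired with its ground-truth filter."""

    query: str
    filter: CohortFilter
    origin: str = "synthetic"  # synthetic | user | manual
    style: str = "verbose"  # verbose | concise


def _weighted_choice(rng: np.random.Generator, weights: dict):
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def sample_filter(
    dd: DataDictionary, cfg: SamplerConfig, rng: np.random.Generator
) -> CohortFilter:
    """Draw one strict-valid conjunctive filter with distinct clause fields."""
    enum_pool = dd.enumerated()
    num_pool = dd.numeric()
    if not enum_pool and (cfg.p_numeric == 0 or not num_pool):
        raise ValueError(
            "dictionary has no enumerated properties and numeric clauses are "
            "disabled; nothing to sample"
        )
    n_clauses = min(_weighted_choice(rng, cfg.n_clauses_weights), len(dd))
    enum_avail = list(enum_pool)
    num_avail = list(num_pool)
    leaves: list[Leaf] = []
    for _ in range(n_clauses):
        use_numeric = num_avail and (
            not enum_avail or rng.random() < cfg.p_numeric
        )
        if use_numeric:
            spec = num_avail.pop(rng.integers(len(num_avail)))
            lo_bound = int(np.ceil(spec.min_value))
            hi_bound = int(np.floor(spec.max_value))
            a = int(rng.integers(lo_bound, hi_bound + 1))
            b = int(rng.integers(lo_bound, hi_bound + 1))
            lo, hi = min(a, b), max(a, b)
            leaves.append(Leaf(op=">=", field=spec.name, value=lo))
            leaves.append(Leaf(op="<=", field=spec.name, value=hi))
        else:
            spec = enum_avail.pop(rng.integers(len(enum_avail)))
            k = min(_weighted_choice(rng, cfg.n_values_weights), len(spec.allowed_values))
            idx = rng.choice(len(spec.allowed_values), size=k, replace=False)
            values = tuple(spec.allowed_values[i] for i in sorted(idx))
            leaves.append(Leaf(op="in", field=spec.name, value=values))
    return canonicalize(CohortFilter(root=Group(op="and", content=tuple(leaves))))


def sample_case_store(
    dd: DataDictionary,
    n_cases: int,
    missing_rate: float = 0.05,
    rng: np.random.Generator | None = None,
    derive: dict | None = None,
    case_id_prefix: str = "case",
) -> CaseStore:
    """Draw a synthetic store: each case assigns each property one value drawn
    uniformly from its allowed set/range, dropped with ``missing_rate``.

    ``derive`` maps a field to a function of the sampled record values,
    letting callers impose semantic links that independent sampling cannot
    express (e.g. program determined by project).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    records = []
    width = max(4, len(str(max(n_cases, 1))))
    for i in range(n_cases):
        values: dict = {}
        for spec in dd:
            if rng.random() < missing_rate:
                continue
            if spec.kind == "enumerated":
                values[spec.name] = (
                    spec.allowed_values[rng.integers(len(spec.allowed_values))],
                )
            else:
                lo = int(np.ceil(spec.min_value))
                hi = int(np.floor(spec.max_value))
                values[spec.name] = (int(rng.integers(lo, hi + 1)),)
        if derive:
            for fld, fn in derive.items():
                derived = fn(values)
                if derived is None:
                    values.pop(fld, None)
                else:
                    values[fld] = tuple(derived)
        records.append(CaseRecord(case_id=f"{case_id_prefix}-{i:0{width}d}", values=values))
    return CaseStore(records=records, dictionary_version=dd.version_label)


# ---------------------------------------------------------------------------
# verbalization (template reverse translation)


def _value_list_phrase(values) -> str:
    values = list(values)
    if len(values) == 1:
        return values[0]
    if len(values) == 2:
        return f"{values[0]} or {values[1]}"
    return ", ".join(values[:-1]) + ", or " + values[-1]


def _numeric_phrase(spec: PropertySpec, op: str, value) -> str:
    word = "at least" if op == ">=" else "at most"
    units = f" {spec.units}" if spec.units else ""
    return f"{spec.display_label} is {word} {value}{units}"


def _leaf_phrase(leaf: Leaf, dd: DataDictionary, style: str) -> str:
    spec = dd[leaf.field]
    if leaf.op == "in":
        if style == "concise" and set(leaf.value) == set(spec.allowed_values):
            return f"any {spec.display_label}"
        return f"{spec.display_label} is {_value_list_phrase(leaf.value)}"
    return _numeric_phrase(spec, leaf.op, leaf.value)


def _render_group(node: Group, dd: DataDictionary, style: str) -> str:
    phrases: list[str] = []
    skip: set[int] = set()
    children = node.content
    for i, child in enumerate(children):
        if i in skip:
            continue
        if isinstance(child, Group):
            inner = _render_group(child, dd, style)
            phrases.append(f"({inner})" if len(child.content) > 1 else inner)
            continue
        if (
            style == "concise"
            and child.op == "<="
            and node.op == "and"
        ):
            # Pair a <= bound with a matching >= sibling into "between L and H".
            for j, other in enumerate(children):
                if (
                    j != i
                    and isinstance(other, Leaf)
                    and other.op == ">="
                    and other.field == child.field
                ):
                    spec = dd[child.field]
                    units = f" {spec.units}" if spec.units else ""
                    phrases.append(
                        f"{spec.display_label} is between {other.value} and "
                        f"{child.value}{units}"
                    )
                    skip.add(j)
                    break
            else:
                phrases.append(_leaf_phrase(child, dd, style))
            continue
        phrases.append(_leaf_phrase(child, dd, style))
    joiner = " and " if node.op == "and" else " or "
    return joiner.join(phrases)


def verbalize(f: CohortFilter, dd: DataDictionary, style: str = "verbose") -> str:
    """Deterministic template rendering of a strict-valid filter.

    Verbose style enumerates every value in canonical clause order; concise
    style applies the "any <label>" and "between A and B" collapses.
    """
    if style not in ("verbose", "concise"):
        raise ValueError(f"unknown style {style!r}")
    report = validate_filter(f, dd, level="strict")
    if not report.strict_ok:
        raise ValueError(f"verbalize requires a strict-valid filter: {report.issues}")
    canonical = canonicalize(f)
    return "cases where " + _render_group(canonical.root, dd, style)


_PROMPT_TEMPLATE = (
    "You are helping translate structured cohort filters into natural "
    "language. Write one short natural-language query a researcher would "
    "type to request the cohort selected by this filter JSON. Mention every "
    "constraint; do not add constraints that are not present.\n\n"
    "Filter JSON:\n{filter_json}\n\nQuery:"
)


def build_reverse_translation_prompt(f: CohortFilter, dd: DataDictionary) -> str:
    """Chat-style prompt embedding the exact serialized filter, for use with a
    caller-supplied completion function (deterministic per filter)."""
    report = validate_filter(f, dd, level="strict")
    if not report.strict_ok:
        raise ValueError("prompt construction requires a strict-valid filter")
    return _PROMPT_TEMPLATE.format(filter_json=serialize_filter(canonicalize(f)))


def reverse_translate(
    f: CohortFilter,
    dd: DataDictionary,
    style: str = "verbose",
    completion=None,
) -> QueryFilterPair:
    """Build a query/filter pair: templates by default, or an external
    completion function applied to the reverse-translation prompt."""
    if completion is not None:
        query = completion(build_reverse_translation_prompt(f, dd)).strip()
    else:
        query = verbalize(f, dd, style=style)
    return QueryFilterPair(query=query, filter=canonicalize(f), origin="synthetic", style=style)


def make_corpus(
    dd: DataDictionary,
    cfg: SamplerConfig,
    n_synthetic: int,
    user_pairs=None,
    rng: np.random.Generator | None = None,
    style: str = "verbose",
    completion=None,
) -> list[QueryFilterPair]:
    """Sample filters, reverse translate each, append any user pairs, and
    deduplicate on (canonical filter JSON, query text), keeping first."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pairs: list[QueryFilterPair] = []
    for _ in range(n_synthetic):
        f = sample_filter(dd, cfg, rng)
        pairs.append(reverse_translate(f, dd, style=style, completion=completion))
    for p in user_pairs or ():
        pairs.append(p)
    seen = set()
    unique: list[QueryFilterPair] = []
    for p in pairs:
        key = (serialize_filter(canonicalize(p.filter)), p.query)
        if key in seen:
            continue
        seen.add(key)
        unique.append(p)
    return unique


def filter_eval_pairs(
    pairs,
    store: CaseStore,
    token_budget: float = 1024,
    length_fn=len,
    separator: str = "\n",
) -> list[QueryFilterPair]:
    """Keep pairs whose filter retrieves at least one case from the store and
    whose combined query+filter text fits within the token budget under the
    supplied length function (cohorts of 0 cases and over-length samples are
    unusable for evaluation)."""
    kept = []
    for p in pairs:
        if not apply_filter(p.filter, store):
            continue
        combined = p.query + separator + serialize_filter(canonicalize(p.filter))
        if length_fn(combined) > token_budget:
            continue
        kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# corpus I/O (JSONL: {"query":…, "filter":…, "origin":…, "style":…})


def write_corpus(pairs, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(
                json.dumps(
                    {
                        "query": p.query,
                        "filter": json.loads(serialize_filter(canonicalize(p.filter))),
                        "origin": p.origin,
                        "style": p.style,
                    },
                    separators=(",", ":"),
                )
                + "\n"
            )


def read_corpus(path: str | os.PathLike) -> list[QueryFilterPair]:
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            pairs.append(
                QueryFilterPair(
                    query=obj["query"],
                    filter=parse_filter(json.dumps(obj["filter"])),
                    origin=obj.get("origin", "synthetic"),
                    style=obj.get("style", "verbose"),
                )
            )
    return pairs
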