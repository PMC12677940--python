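import itertools

import numpy as np
import pytest

from cohortkit.dictionary import DataDictionary, PropertySpec, load_toy_dictionary
from cohortkit.engine import CaseRecord, CaseStore
from cohortkit.filters import CohortFilter, Group, Leaf, canonicalize


@pytest.fixture(scope="session")
def toy_dd():
    return load_toy_dictionary()


@pytest.fixture(scope="session")
def micro_dd():
    """Tiny dictionary with a small numeric range so exhaustive language
    enumeration over the decoding automaton stays exhaustive."""
    return DataDictionary.from_specs(
        [
            PropertySpec(
                name="cases.project.program.name",
                kind="enumerated",
                allowed_values=("TCGA", "CPTAC"),
                label="program",
            ),
            PropertySpec(
                name="cases.demographic.gender",
                kind="enumerated",
                allowed_values=("female", "male"),
                label="gender",
            ),
            PropertySpec(
                name="cases.diagnoses.age_at_diagnosis",
                kind="numeric",
                min_value=0,
                max_value=12,
                units="days",
                label="age at diagnosis",
            ),
        ],
        version_label="micro",
    )


PROJECT = "cases.project.project_id"
PROGRAM = "cases.project.program.name"
AGE = "cases.diagnoses.age_at_diagnosis"

PROJECT_TO_PROGRAM = {
    "TCGA-LUAD": "TCGA",
    "TCGA-BRCA": "TCGA",
    "CPTAC-3": "CPTAC",
    "TARGET-AML": "TARGET",
}


@pytest.fixture
def four_case_store():
    """c1/c4 TCGA-LUAD (ages 25000/10000), c2 TCGA-BRCA, c3 CPTAC-3."""
    return CaseStore(
        records=[
            CaseRecord("c1", {PROJECT: ("TCGA-LUAD",), PROGRAM: ("TCGA",), AGE: (25000,)}),
            CaseRecord("c2", {PROJECT: ("TCGA-BRCA",), PROGRAM: ("TCGA",)}),
            CaseRecord("c3", {PROJECT: ("CPTAC-3",), PROGRAM: ("CPTAC",)}),
            CaseRecord("c4", {PROJECT: ("TCGA-LUAD",), PROGRAM: ("TCGA",), AGE: (10000,)}),
        ]
    )


def leaf_in(field, *values):
    return Leaf(op="in", field=field, value=tuple(values))


def wrap(*nodes):
    return CohortFilter(root=Group(op="and", content=tuple(nodes)))


def random_structural_filter(rng: np.random.Generator, dd, max_depth=2,
                             p_bogus=0.0):
    """Random possibly-nested filter over a dictionary; with probability
    ``p_bogus`` a leaf uses an unknown field or value (still structurally
    valid)."""
    specs = list(dd)

    def leaf():
        if p_bogus and rng.random() < p_bogus:
            return Leaf(op="in", field="cases.unknown_field", value=("mystery",))
        spec = specs[rng.integers(len(specs))]
        if spec.kind == "numeric":
            op = ">=" if rng.random() < 0.5 else "<="
            lo, hi = int(spec.min_value), int(spec.max_value)
            return Leaf(op=op, field=spec.name, value=int(rng.integers(lo, hi + 1)))
        k = int(rng.integers(1, len(spec.allowed_values) + 1))
        idx = rng.choice(len(spec.allowed_values), size=k, replace=False)
        return Leaf(
            op="in",
            field=spec.name,
            value=tuple(spec.allowed_values[i] for i in sorted(idx)),
        )

    def node(depth):
        if depth >= max_depth or rng.random() < 0.4:
            return leaf()
        op = "and" if rng.random() < 0.5 else "or"
        children = tuple(node(depth + 1) for _ in range(int(rng.integers(1, 4))))
        return Group(op=op, content=children)

    return CohortFilter(root=Group(op="and", content=(node(0),)))


def enumerate_flat_filters(dd, max_clauses=2, numeric_values=None):
    """Every canonical strict-valid flat conjunctive filter with at most
    ``max_clauses`` leaf clauses and distinct (op, field) per clause —
    the decoding dialect, enumerated independently of the automaton."""
    leaves = []
    for spec in dd:
        if spec.kind == "enumerated":
            values = sorted(spec.allowed_values)
            options = []
            for r in range(1, len(values) + 1):
                options.extend(itertools.combinations(values, r))
            leaves.append([Leaf(op="in", field=spec.name, value=v) for v in options])
        else:
            lo, hi = int(spec.min_value), int(spec.max_value)
            numbers = (
                list(range(lo, hi + 1)) if numeric_values is None else numeric_values
            )
            for op in (">=", "<="):
                leaves.append(
                    [Leaf(op=op, field=spec.name, value=n) for n in numbers]
                )
    filters = []
    for r in range(1, max_clauses + 1):
        for groups in itertools.combinations(range(len(leaves)), r):
            for combo in itertools.product(*[leaves[g] for g in groups]):
                filters.append(
                    canonicalize(CohortFilter(root=Group(op="and", content=combo)))
                )
    return filters
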