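"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately written from the definitions (per-case
recursion, binomial tail sums, closed-form t) rather than reusing the
package's own code paths.
"""

from math import comb, sqrt

from cohortkit.filters import CohortFilter, Group, Leaf


def record_matches(node, record) -> bool:
    """Per-case recursive predicate evaluation (the brute-force route)."""
    if isinstance(node, Group):
        results = (record_matches(child, record) for child in node.content)
        return all(results) if node.op == "and" else any(results)
    assert isinstance(node, Leaf)
    values = record.values.get(node.field, ())
    if node.op == "in":
        return any(v in node.value for v in values)
    numeric = [v for v in values if isinstance(v, (int, float)) and not isinstance(v, bool)]
    if node.op == ">=":
        return any(v >= node.value for v in numeric)
    return any(v <= node.value for v in numeric)


def brute_force_apply(f: CohortFilter, store) -> set:
    return {r.case_id for r in store if record_matches(f.root, r)}


def binomial_mcnemar_p(b: int, c: int) -> float:
    """Exact two-sided McNemar p: doubled binomial(n=b+c, 1/2) tail of the
    smaller discordant count, capped at 1."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(comb(n, i) for i in range(k + 1)) * 0.5**n
    return min(1.0, 2.0 * tail)


def paired_t_statistic(diff) -> float:
    """Closed-form paired t on a difference vector."""
    n = len(diff)
    mean = sum(diff) / n
    var = sum((d - mean) ** 2 for d in diff) / (n - 1)
    return mean / sqrt(var / n)
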