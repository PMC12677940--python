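"""Case-set evaluation and system comparison.

Predicted filters are scored against ground truth by the *cases they
retrieve*, not by filter text, because many filters denote the same cohort
(selecting a program is equivalent to selecting all of its projects).  Per
sample:

* TPR (sensitivity)  = |predicted ∩ actual| / |actual|
* IoU (Jaccard)      = |predicted ∩ actual| / |predicted ∪ actual|
* Exact              = [predicted == actual]
* semantic           = similarity between the original query and the reverse
  translation of the predicted filter (token-F1 by default; an
  embedding-based F1 BERTScore-style scorer plugs in through the same
  ``scorer(a, b) -> float`` contract)

A prediction that cannot be used to retrieve cases — truncated generation,
unparseable output, a raised predictor — scores as the empty set (all case
metrics 0, semantic 0).  Systems are compared pairwise with paired t-tests
(TPR / IoU / semantic) or McNemar's test (Exact), Bonferroni-corrected.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .dictionary import DataDictionary
from .engine import CaseStore, apply_filter
from .filters import CohortFilter, canonicalize, parse_filter, serialize_filter
from .synth import QueryFilterPair, verbalize

__all__ = [
    "EvalRecord",
    "MetricSummary",
    "SystemComparison",
    "case_metrics",
    "token_f1",
    "semantic_similarity",
    "evaluate_system",
    "compare_systems",
    "summarize",
    "write_records",
    "read_records",
]

# Discordant-pair count below which McNemar uses the exact binomial form.
MCNEMAR_EXACT_THRESHOLD = 25

METRICS = ("tpr", "iou", "exact", "semantic")


def case_metrics(predicted: set, actual: set) -> tuple[float, float, bool]:
    """(TPR, IoU, Exact) for a pair of retrieved case-ID sets.

    ``actual`` must be non-empty (empty true cohorts are excluded upstream);
    an empty prediction scores (0, 0, False).
    """
    predicted = set(predicted)
    actual = set(actual)
    if not actual:
        raise ValueError("actual case set must be non-empty")
    inter = len(predicted & actual)
    tpr = inter / len(actual)
    iou = inter / len(predicted | actual)
    return tpr, iou, predicted == actual


_PUNCT_RE = re.compile(r"[^\w\s-]")
# Function words ignored by the default scorer so that word-order and
# phrasing variants of the same constraint set score 1.0.
_STOPWORDS = frozenset(
    ("a an and are as at be by for from in is of on or the to was were "
     "where with any all who whose which that have has").split()
)


def _content_tokens(text: str) -> list[str]:
    tokens = _PUNCT_RE.sub(" ", text.lower()).split()
    content = [t for t in tokens if t not in _STOPWORDS]
    return content or tokens


def token_f1(a: str, b: str) -> float:
    """Multiset F1 over lowercased, punctuation-stripped content tokens."""
    ta, tb = _content_tokens(a), _content_tokens(b)
    counts_a: dict[str, int] = {}
    for t in ta:
        counts_a[t] = counts_a.get(t, 0) + 1
    overlap = 0
    for t in tb:
        if counts_a.get(t, 0) > 0:
            counts_a[t] -= 1
            overlap += 1
    if overlap == 0:
        return 0.0
    precision = overlap / len(tb)
    recall = overlap / len(ta)
    return 2 * precision * recall / (precision + recall)


def semantic_similarity(query_a: str, query_b: str, scorer=None) -> float:
    """Similarity of two queries under a pluggable scorer (default: token F1,
    symmetric and deterministic)."""
    if not query_a or not query_b:
        raise ValueError("semantic similarity requires non-empty texts")
    scorer = scorer or token_f1
    return float(scorer(query_a, query_b))


@dataclass
class EvalRecord:
    """Per-sample outcome of one system on one query/filter pair."""

    query: str
    true_filter: CohortFilter
    predicted_filter: CohortFilter | None  # None marks an unusable prediction
    true_cases: set
    predicted_cases: set
    tpr: float
    iou: float
    exact: bool
    semantic: float
    invalid: bool = False
    style: str = "verbose"


@dataclass
class SystemComparison:
    metric: str
    system_a: str
    system_b: str
    mean_a: float
    mean_b: float
    test: str  # "paired t" | "mcnemar exact" | "mcnemar chi2"
    statistic: float
    p_raw: float
    p_adjusted: float
    degenerate: bool = False


@dataclass
class MetricSummary:
    means: dict
    n: int
    comparisons: list = field(default_factory=list)
    scorer: str = "token_f1"
    bonferroni_family: int = 0


def evaluate_system(
    pairs,
    predictor,
    store: CaseStore,
    dd: DataDictionary,
    scorer=None,
) -> list[EvalRecord]:
    """Run a predictor over pre-filtered pairs and score every sample.

    ``predictor(query)`` may return filter JSON text, a
    :class:`CohortFilter`, or raise; unusable outputs (exceptions,
    unparseable text) are mapped to the empty case set rather than crashing
    the run.  Deterministic given a deterministic predictor.
    """
    records = []
    for pair in pairs:
        true_cases = apply_filter(pair.filter, store)
        if not true_cases:
            raise ValueError(
                "pair with an empty true cohort reached evaluation; filter "
                "eval pairs upstream"
            )
        predicted_filter: CohortFilter | None = None
        try:
            out = predictor(pair.query)
            if isinstance(out, CohortFilter):
                predicted_filter = out
            elif isinstance(out, str):
                predicted_filter = parse_filter(out)
        except Exception:
            predicted_filter = None
        if predicted_filter is None:
            predicted_cases: set = set()
        else:
            predicted_cases = apply_filter(predicted_filter, store)
        tpr, iou, exact = case_metrics(predicted_cases, true_cases)
        if predicted_filter is None:
            semantic = 0.0
        else:
            try:
                reverse = verbalize(predicted_filter, dd, style=pair.style)
                semantic = semantic_similarity(pair.query, reverse, scorer=scorer)
            except ValueError:
                semantic = 0.0  # strict-invalid prediction has no verbalization
        records.append(
            EvalRecord(
                query=pair.query,
                true_filter=canonicalize(pair.filter),
                predicted_filter=predicted_filter,
                true_cases=true_cases,
                predicted_cases=predicted_cases,
                tpr=tpr,
                iou=iou,
                exact=exact,
                semantic=semantic,
                invalid=predicted_filter is None,
                style=pair.style,
            )
        )
    return records


def _check_aligned(records_a, records_b) -> None:
    if len(records_a) != len(records_b):
        raise ValueError("record lists differ in length")
    if len(records_a) < 2:
        raise ValueError("need at least 2 paired records to compare")
    for i, (ra, rb) in enumerate(zip(records_a, records_b)):
        if ra.query != rb.query or serialize_filter(ra.true_filter) != serialize_filter(
            rb.true_filter
        ):
            raise ValueError(f"records misaligned at index {i}")


def _paired_t(diff: np.ndarray) -> tuple[float, float, bool]:
    if np.allclose(diff.std(ddof=1), 0.0):
        return 0.0, 1.0, True  # zero-variance differences: no evidence either way
    t_stat, p = stats.ttest_rel(diff, np.zeros_like(diff))
    return float(t_stat), float(p), False


def mcnemar_test(b: int, c: int) -> tuple[float, float, str]:
    """McNemar on a discordance table: exact binomial when b + c is small,
    continuity-corrected chi-square otherwise.  Returns (statistic, p, name).
    """
    if b + c == 0:
        return 0.0, 1.0, "mcnemar exact"
    exact = (b + c) < MCNEMAR_EXACT_THRESHOLD
    table = [[0, b], [c, 0]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    name = "mcnemar exact" if exact else "mcnemar chi2"
    return float(res.statistic), float(min(res.pvalue, 1.0)), name


def compare_systems(
    records_a,
    records_b,
    label_a: str = "A",
    label_b: str = "B",
    metrics=METRICS,
) -> list[SystemComparison]:
    """Pairwise significance tests between two aligned evaluation runs.

    Paired two-sided t-tests for the continuous metrics, McNemar for Exact,
    Bonferroni correction over the comparisons performed in this call.
    """
    _check_aligned(records_a, records_b)
    comparisons = []
    family = len(metrics)
    for metric in metrics:
        va = np.array([float(getattr(r, metric)) for r in records_a])
        vb = np.array([float(getattr(r, metric)) for r in records_b])
        if metric == "exact":
            b = int(np.sum((va == 1) & (vb == 0)))  # A right, B wrong
            c = int(np.sum((va == 0) & (vb == 1)))
            statistic, p_raw, test = mcnemar_test(b, c)
            degenerate = (b + c) == 0
        else:
            statistic, p_raw, degenerate = _paired_t(va - vb)
            test = "paired t"
        comparisons.append(
            SystemComparison(
                metric=metric,
                system_a=label_a,
                system_b=label_b,
                mean_a=float(va.mean()),
                mean_b=float(vb.mean()),
                test=test,
                statistic=statistic,
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * family),
                degenerate=degenerate,
            )
        )
    return comparisons


def summarize(records, comparisons=None, scorer: str = "token_f1") -> MetricSummary:
    """Aggregate per-sample records into metric means plus any comparisons."""
    n = len(records)
    if n == 0:
        return MetricSummary(means={}, n=0, comparisons=list(comparisons or ()))
    means = {
        metric: float(np.mean([float(getattr(r, metric)) for r in records]))
        for metric in METRICS
    }
    means["invalid_rate"] = float(np.mean([r.invalid for r in records]))
    return MetricSummary(
        means=means,
        n=n,
        comparisons=list(comparisons or ()),
        scorer=scorer,
        bonferroni_family=len(comparisons) if comparisons else 0,
    )


def render_table(summary: MetricSummary) -> str:
    """Plain-text table in TPR / IoU / Exact / BERT column order."""
    lines = [f"n = {summary.n}   (semantic scorer: {summary.scorer})"]
    lines.append(f"{'TPR':>7} {'IoU':>7} {'Exact':>7} {'BERT':>7}")
    if summary.means:
        lines.append(
            f"{summary.means['tpr']:7.3f} {summary.means['iou']:7.3f} "
            f"{summary.means['exact']:7.3f} {summary.means['semantic']:7.3f}"
        )
    for cmp_ in summary.comparisons:
        flag = " (degenerate)" if cmp_.degenerate else ""
        lines.append(
            f"{cmp_.metric:>8}: {cmp_.system_a} {cmp_.mean_a:.3f} vs "
            f"{cmp_.system_b} {cmp_.mean_b:.3f}  [{cmp_.test}] "
            f"p={cmp_.p_raw:.3g} adj={cmp_.p_adjusted:.3g}{flag}"
        )
    return "\n".join(lines)


def summary_to_json(summary: MetricSummary) -> dict:
    return {
        "n": summary.n,
        "means": summary.means,
        "scorer": summary.scorer,
        "bonferroni_family": summary.bonferroni_family,
        "comparisons": [
            {
                "metric": c.metric,
                "system_a": c.system_a,
                "system_b": c.system_b,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "test": c.test,
                "statistic": c.statistic,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
                "degenerate": c.degenerate,
            }
            for c in summary.comparisons
        ],
    }


def write_records(records, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "query": r.query,
                        "true_filter": json.loads(serialize_filter(r.true_filter)),
                        "predicted_filter": (
                            None
                            if r.predicted_filter is None
                            else json.loads(serialize_filter(r.predicted_filter))
                        ),
                        "true_cases": sorted(r.true_cases),
                        "predicted_cases": sorted(r.predicted_cases),
                        "tpr": r.tpr,
                        "iou": r.iou,
                        "exact": r.exact,
                        "semantic": r.semantic,
                        "invalid": r.invalid,
                        "style": r.style,
                    },
                    separators=(",", ":"),
                )
                + "\n"
            )


def read_records(path: str | os.PathLike) -> list[EvalRecord]:
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            records.append(
                EvalRecord(
                    query=obj["query"],
                    true_filter=parse_filter(json.dumps(obj["true_filter"])),
                    predicted_filter=(
                        None
                        if obj["predicted_filter"] is None
                        else parse_filter(json.dumps(obj["predicted_filter"]))
                    ),
                    true_cases=set(obj["true_cases"]),
                    predicted_cases=set(obj["predicted_cases"]),
                    tpr=obj["tpr"],
                    iou=obj["iou"],
                    exact=obj["exact"],
                    semantic=obj["semantic"],
                    invalid=obj.get("invalid", False),
                    style=obj.get("style", "verbose"),
                )
            )
    return records
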