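import numpy as np
import pytest

from cohortkit.engine import apply_filter
from cohortkit.evaluation import (
    case_metrics,
    compare_systems,
    evaluate_system,
    mcnemar_test,
    read_records,
    render_table,
    semantic_similarity,
    summarize,
    summary_to_json,
    token_f1,
    write_records,
)
from cohortkit.filters import CohortFilter, Group, Leaf, serialize_filter
from cohortkit.synth import QueryFilterPair, SamplerConfig, sample_case_store, \
    sample_filter, verbalize
from cohortkit.nl2filter import TruncationError

from conftest import PROGRAM, leaf_in, wrap
from _oracles import binomial_mcnemar_p, paired_t_statistic


@pytest.mark.parametrize(
    "predicted, actual, expected",
    [
        ({"a", "b", "c"}, {"a", "b", "c"}, (1.0, 1.0, True)),
        ({"a", "b"}, {"a", "c"}, (0.5, 1 / 3, False)),
        (set(), {"a"}, (0.0, 0.0, False)),  # empty-prediction rule
        ({"x"}, {"a", "b"}, (0.0, 0.0, False)),
    ],
)
def test_case_metrics_hand_computed_values(predicted, actual, expected):
    tpr, iou, exact = case_metrics(predicted, actual)
    assert (round(tpr, 12), round(iou, 12), exact) == (
        round(expected[0], 12), round(expected[1], 12), expected[2]
    )


def test_case_metrics_requires_non_empty_actual():
    with pytest.raises(ValueError):
        case_metrics({"a"}, set())


def test_case_metric_invariants_on_random_set_pairs():
    rng = np.random.default_rng(0)
    universe = [f"id{i}" for i in range(30)]
    for _ in range(10_000):
        predicted = {u for u in universe if rng.random() < 0.3}
        actual = {u for u in universe if rng.random() < 0.3} or {"id0"}
        tpr, iou, exact = case_metrics(predicted, actual)
        assert 0.0 <= iou <= tpr <= 1.0
        assert exact == (tpr == 1.0 and iou == 1.0)
        relabel = {u: f"R{u}" for u in universe}
        tpr2, iou2, exact2 = case_metrics(
            {relabel[p] for p in predicted}, {relabel[a] for a in actual}
        )
        assert (tpr2, iou2, exact2) == (tpr, iou, exact)


def test_token_f1_examples():
    assert semantic_similarity("same text", "same text") == 1.0
    assert semantic_similarity("alpha beta", "gamma delta") == 0.0
    assert semantic_similarity(
        "cases with lung adenocarcinoma", "lung adenocarcinoma cases"
    ) == 1.0  # bag-of-content-tokens is order- and function-word-insensitive
    assert token_f1("lung lung cancer", "lung cancer") == pytest.approx(4 / 5)
    with pytest.raises(ValueError):
        semantic_similarity("", "x")


def _eval_setup(toy_dd, n_pairs=20, n_cases=120, seed=5):
    rng = np.random.default_rng(seed)
    store = sample_case_store(toy_dd, n_cases, missing_rate=0.05, rng=rng)
    cfg = SamplerConfig(seed=seed)
    pairs = []
    while len(pairs) < n_pairs:
        f = sample_filter(toy_dd, cfg, rng)
        if apply_filter(f, store):
            pairs.append(QueryFilterPair(query=verbalize(f, toy_dd), filter=f))
    return pairs, store


def test_oracle_predictor_scores_perfectly(toy_dd):
    pairs, store = _eval_setup(toy_dd)
    truth = {p.query: p.filter for p in pairs}
    records = evaluate_system(pairs, lambda q: truth[q], store, toy_dd)
    assert all(r.tpr == r.iou == r.semantic == 1.0 and r.exact for r in records)
    summary = summarize(records)
    assert summary.means["tpr"] == summary.means["iou"] == 1.0
    assert summary.means["exact"] == summary.means["semantic"] == 1.0


def test_failing_predictors_score_zero_without_crashing(toy_dd):
    pairs, store = _eval_setup(toy_dd)
    nothing = wrap(leaf_in(PROGRAM, "TCGA", "CPTAC", "TARGET"))

    def raising(_q):
        raise TruncationError("ran out of budget")

    for predictor in (raising, lambda _q: "not json at all"):
        records = evaluate_system(pairs, predictor, store, toy_dd)
        assert all(r.invalid and r.tpr == r.iou == r.semantic == 0.0
                   and not r.exact for r in records)

    constant = evaluate_system(pairs, lambda _q: nothing, store, toy_dd)
    assert all(not r.invalid for r in constant)
    assert all(r.tpr == 1.0 or r.tpr < 1.0 for r in constant)  # defined everywhere


def test_dropping_a_clause_retrieves_a_superset(toy_dd):
    pairs, store = _eval_setup(toy_dd, n_pairs=50, seed=8)
    truth = {p.query: p.filter for p in pairs}

    def drop_one(query):
        f = truth[query]
        content = f.root.content
        if len(content) > 1:
            f = CohortFilter(Group("and", content[1:]))
        return f

    records = evaluate_system(pairs, drop_one, store, toy_dd)
    for r in records:
        assert r.tpr == 1.0  # superset retrieval never misses a true case
        assert r.iou <= 1.0
        assert r.predicted_cases >= r.true_cases


def test_compare_identical_runs_never_significant(toy_dd):
    pairs, store = _eval_setup(toy_dd)
    truth = {p.query: p.filter for p in pairs}
    records = evaluate_system(pairs, lambda q: truth[q], store, toy_dd)
    comparisons = compare_systems(records, records)
    for c in comparisons:
        assert c.p_raw == 1.0 and c.p_adjusted == 1.0
        if c.metric != "exact":
            assert c.degenerate


def test_mcnemar_exact_matches_binomial_tail_enumeration():
    for b in range(0, 13):
        for c in range(0, 13 - b):
            _stat, p, name = mcnemar_test(b, c)
            assert name == "mcnemar exact"
            assert p == pytest.approx(binomial_mcnemar_p(b, c), abs=1e-12)
    assert mcnemar_test(1, 1)[1] == 1.0
    _stat, _p, name = mcnemar_test(20, 10)
    assert name == "mcnemar chi2"


def test_paired_t_matches_closed_form_to_1e10(toy_dd):
    rng = np.random.default_rng(3)
    noise = rng.normal(scale=0.02, size=10)
    diffs = np.array([0.1] * 10) + noise
    pairs, store = _eval_setup(toy_dd, n_pairs=10, seed=2)
    truth = {p.query: p.filter for p in pairs}
    rec_a = evaluate_system(pairs, lambda q: truth[q], store, toy_dd)
    rec_b = evaluate_system(pairs, lambda q: truth[q], store, toy_dd)
    for r, d in zip(rec_b, diffs):
        r.tpr = r.tpr - d
    comparison = [c for c in compare_systems(rec_a, rec_b) if c.metric == "tpr"][0]
    assert comparison.statistic == pytest.approx(paired_t_statistic(diffs), abs=1e-10)
    assert not comparison.degenerate


def test_bonferroni_adjustment_bounds(toy_dd):
    pairs, store = _eval_setup(toy_dd)
    truth = {p.query: p.filter for p in pairs}
    rec_a = evaluate_system(pairs, lambda q: truth[q], store, toy_dd)
    rec_b = evaluate_system(
        pairs, lambda q: wrap(leaf_in(PROGRAM, "TCGA")), store, toy_dd
    )
    for c in compare_systems(rec_a, rec_b):
        assert c.p_adjusted >= c.p_raw
        assert c.p_adjusted <= 1.0


def test_misaligned_records_rejected(toy_dd):
    pairs, store = _eval_setup(toy_dd)
    truth = {p.query: p.filter for p in pairs}
    records = evaluate_system(pairs, lambda q: truth[q], store, toy_dd)
    with pytest.raises(ValueError, match="misaligned"):
        compare_systems(records, list(reversed(records)))
    with pytest.raises(ValueError, match="length"):
        compare_systems(records, records[:-1])


def test_summary_serialization_and_empty_case(tmp_path, toy_dd):
    assert summarize([]).n == 0
    pairs, store = _eval_setup(toy_dd)
    truth = {p.query: p.filter for p in pairs}
    records = evaluate_system(pairs, lambda q: truth[q], store, toy_dd)
    path = tmp_path / "records.jsonl"
    write_records(records, path)
    loaded = read_records(path)
    assert [serialize_filter(r.true_filter) for r in loaded] == [
        serialize_filter(r.true_filter) for r in records
    ]
    assert [r.tpr for r in loaded] == [r.tpr for r in records]
    summary = summarize(records, comparisons=compare_systems(records, records))
    payload = summary_to_json(summary)
    assert payload["n"] == len(records) and len(payload["comparisons"]) == 4
    table = render_table(summary)
    assert "TPR" in table and "BERT" in table
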