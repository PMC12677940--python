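import numpy as np
import pytest

from cohortkit.filters import canonicalize, parse_filter, serialize_filter, \
    validate_filter
from cohortkit.nl2filter import (
    EOS,
    SEPARATOR,
    ConstraintError,
    TrainConfig,
    TrainingInstance,
    TruncationError,
    build_automaton,
    generate,
    load_model,
    make_training_instances,
    save_model,
    train,
)
from cohortkit.synth import SamplerConfig, make_corpus

from conftest import enumerate_flat_filters


class _RandomScoreModel:
    """Backbone mock: finite random scores over the vocabulary, no training.
    Used to show that constrained validity is independent of model quality."""

    def __init__(self, automaton, seed=0, max_len=2048):
        self.char_vocab = ["\x00", "\x02", EOS] + sorted(automaton.vocabulary)
        self.char_index = {c: i for i, c in enumerate(self.char_vocab)}
        self.max_len = max_len
        self._rng = np.random.default_rng(seed)

    def next_scores(self, prefix):
        return self._rng.normal(size=len(self.char_vocab))


# ---------------------------------------------------------------------------
# automaton language


def test_bounded_language_equals_canonical_strict_valid_filters(micro_dd):
    """Soundness and bounded completeness: the automaton's ≤2-clause language
    is exactly the canonical serializations of strict-valid flat filters."""
    automaton = build_automaton(micro_dd)
    accepted = set(automaton.enumerate_accepted(max_clauses=2))
    for text in accepted:
        f = parse_filter(text)
        assert validate_filter(f, micro_dd).strict_ok
        assert serialize_filter(canonicalize(f)) == text
    expected = {
        serialize_filter(f) for f in enumerate_flat_filters(micro_dd, max_clauses=2)
    }
    assert accepted == expected


def test_every_single_clause_canonical_filter_is_accepted(toy_dd):
    automaton = build_automaton(toy_dd)
    for f in enumerate_flat_filters(toy_dd, max_clauses=1,
                                    numeric_values=[0, 7, 308, 32872]):
        assert automaton.accepts(serialize_filter(f))


def test_unknown_field_rejected_before_closing_quote(toy_dd):
    automaton = build_automaton(toy_dd)
    good = '{"op":"and","content":[{"op":"in","content":{"field":"cases.zzz","value":["TCGA"]}}]}'
    state = automaton.start_state
    consumed = 0
    for ch in good:
        state = automaton.try_step(state, ch)
        if state is None:
            break
        consumed += 1
    field_close = good.index('zzz"') + 3
    assert consumed < field_close


def test_allowed_next_agrees_with_per_character_stepping(toy_dd):
    """Brute-force oracle: the advertised alphabet of each visited state is
    exactly the set of characters try_step accepts."""
    automaton = build_automaton(toy_dd)
    probe = sorted(automaton.vocabulary | set("aZ9 !.\t"))
    rng = np.random.default_rng(0)
    checked = 0
    while checked < 1000:
        state = automaton.start_state
        while not automaton.is_accepting(state):
            allowed = automaton.allowed_next(state)
            stepped = {c for c in probe if automaton.try_step(state, c) is not None}
            assert stepped == set(allowed) & set(probe)
            assert allowed  # no dead ends off the accepting state
            checked += 1
            state = automaton.step(state, sorted(allowed)[rng.integers(len(allowed))])
    assert automaton.allowed_next(("accept",)) == frozenset()


def test_start_state_opens_the_root_object(toy_dd):
    automaton = build_automaton(toy_dd)
    assert automaton.allowed_next(automaton.start_state) == frozenset("{")


def test_vocabulary_gap_raises_listing_missing_symbols(toy_dd):
    with pytest.raises(ConstraintError, match="missing required symbols"):
        build_automaton(toy_dd, vocabulary="abc123")


def test_unknown_state_raises(toy_dd):
    automaton = build_automaton(toy_dd)
    with pytest.raises(ConstraintError, match="unknown automaton state"):
        automaton.allowed_next(("warp", 3))


def test_constrained_generation_from_random_model_is_strict_valid(toy_dd):
    automaton = build_automaton(toy_dd)
    model = _RandomScoreModel(automaton, seed=1)
    rng = np.random.default_rng(2)
    for i in range(200):
        text = generate(model, f"probe query {i}", automaton=automaton,
                        decode="sampled", rng=rng, max_len=2048)
        assert validate_filter(parse_filter(text), toy_dd).strict_ok


# ---------------------------------------------------------------------------
# training


@pytest.fixture(scope="module")
def small_corpus(toy_dd):
    rng = np.random.default_rng(20)
    return make_corpus(toy_dd, SamplerConfig(seed=20), 160, rng=rng)


def test_training_reduces_heldout_loss_and_is_seed_deterministic(toy_dd, small_corpus):
    config = TrainConfig(dictionary=toy_dd, seed=9, epochs=6)
    model_a = train(small_corpus, config)
    assert model_a.metadata["holdout_loss_final"] < model_a.metadata["holdout_loss_initial"]
    assert model_a.metadata["train_loss_final"] < model_a.metadata["train_loss_initial"]
    model_b = train(small_corpus, TrainConfig(dictionary=toy_dd, seed=9, epochs=6))
    assert np.array_equal(model_a.W, model_b.W) and np.array_equal(model_a.u, model_b.u)
    automaton = build_automaton(toy_dd)
    for pair in small_corpus[:5]:
        assert generate(model_a, pair.query, automaton=automaton) == generate(
            model_b, pair.query, automaton=automaton
        )


def test_memorization_probe_reproduces_training_targets(toy_dd, small_corpus):
    probe = small_corpus[:50]
    model = train(probe, TrainConfig(dictionary=toy_dd, seed=1, epochs=40,
                                     holdout_fraction=0.0))
    hits = 0
    for pair in probe:
        target = serialize_filter(canonicalize(pair.filter))
        if generate(model, pair.query) == target:
            hits += 1
    assert hits >= 45


def test_greedy_decoding_is_deterministic_and_mask_is_noop_when_valid(
    toy_dd, small_corpus
):
    model = train(small_corpus, TrainConfig(dictionary=toy_dd, seed=9, epochs=6))
    automaton = build_automaton(toy_dd)
    for pair in small_corpus[:8]:
        free = generate(model, pair.query)
        assert free == generate(model, pair.query)
        if automaton.accepts(free):
            assert generate(model, pair.query, automaton=automaton) == free


def test_untrained_model_with_automaton_still_emits_strict_valid(toy_dd, small_corpus):
    config = TrainConfig(dictionary=toy_dd, seed=0, epochs=6)
    trained = train(small_corpus, config)
    trained.W[:] = 0.0
    trained.u[:] = 0.0
    automaton = build_automaton(toy_dd)
    text = generate(trained, "anything at all", automaton=automaton, max_len=4096)
    assert validate_filter(parse_filter(text), toy_dd).strict_ok


def test_training_rejects_empty_or_overlong_input(toy_dd, small_corpus):
    with pytest.raises(ValueError, match="empty"):
        train([], TrainConfig(dictionary=toy_dd))
    with pytest.raises(ValueError, match="budget"):
        make_training_instances(small_corpus[:1], max_len=10)
    long_inst = TrainingInstance(prompt="q" * 50, target="t" * 100)
    with pytest.raises(ValueError, match="budget"):
        train([long_inst], TrainConfig(dictionary=toy_dd, max_len=64))


def test_generation_truncation_signal(toy_dd, small_corpus):
    model = train(small_corpus[:30], TrainConfig(dictionary=toy_dd, seed=0, epochs=2))
    automaton = build_automaton(toy_dd)
    with pytest.raises(TruncationError):
        generate(model, small_corpus[0].query, automaton=automaton, max_len=60)


def test_model_round_trips_through_artifact_directory(tmp_path, toy_dd, small_corpus):
    model = train(small_corpus, TrainConfig(dictionary=toy_dd, seed=9, epochs=6))
    save_model(model, tmp_path / "model")
    loaded = load_model(tmp_path / "model")
    assert np.array_equal(loaded.W, model.W)
    assert loaded.metadata["dictionary_sha256"] == model.metadata["dictionary_sha256"]
    automaton = build_automaton(toy_dd)
    for pair in small_corpus[:5]:
        assert generate(loaded, pair.query, automaton=automaton) == generate(
            model, pair.query, automaton=automaton
        )
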