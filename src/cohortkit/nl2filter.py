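"""Query→filter translation with grammar-constrained decoding.

Two cooperating pieces:

* :class:`ConstraintAutomaton` — a character-level finite-state acceptor for
  the canonical serialization of strict-valid conjunctive filters, compiled
  from a data dictionary.  Field names and enumerated values are trie-encoded
  verbatim; numeric literals are digit sequences interval-checked against the
  property's [min, max] bounds.  During decoding the automaton masks the
  model's next-character scores, so *any* model — trained or random — can
  only emit strict-valid filter JSON.

* :class:`MaxentCharModel` — the reference translator backbone: an
  autoregressive character-level maxent (multinomial logistic) language model
  trained with a causal LM objective on ``query + "\\n" + filter_json``
  concatenations.  Its features combine a character n-gram window over the
  generated text, a bag-of-words encoding of the query, and a pointer/copy
  feature set that lets it transcribe values and numeric bounds mentioned in
  the query.  It is deterministic, CPU-trainable in about a minute at the
  default corpus scale, and exposes the next-token-scores contract any other
  backbone can implement.

The decoding language is the flat canonical dialect the synthetic sampler
emits: a root ``and`` group of leaf clauses in strictly increasing
(op, field) order, ``in`` value lists sorted and deduplicated, integer
numeric literals.  Arbitrary nested filters parse and validate fine
elsewhere in the package; they are simply not targets of constrained
generation, which is trained and masked toward the canonical form.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dictionary import ENUMERATED, DataDictionary, load_dictionary, \
    serialize_dictionary
from .filters import CohortFilter, canonicalize, serialize_filter

__all__ = [
    "SEPARATOR",
    "EOS",
    "DEFAULT_MAX_LEN",
    "ConstraintError",
    "TruncationError",
    "ConstraintAutomaton",
    "build_automaton",
    "allowed_next",
    "TrainingInstance",
    "make_training_instances",
    "TrainConfig",
    "MaxentCharModel",
    "train",
    "generate",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

SEPARATOR = "\n"  # between query and filter JSON in the concatenated format
EOS = "\x03"
_BOS = "\x02"
_PAD = "\x00"
DEFAULT_MAX_LEN = 1024  # sequence-unit budget for query + separator + filter

_ROOT_OPEN = '{"op":"and","content":['


class ConstraintError(ValueError):
    """Automaton construction or stepping failed."""


class TruncationError(RuntimeError):
    """The length budget ran out before generation reached an accepting state."""


# ---------------------------------------------------------------------------
# numeric literal helpers: integer decimal strings, no leading zeros,
# interval-checked against closed bounds.


def _numeral_complete(lo: int, hi: int, prefix: str) -> bool:
    if not prefix or (prefix[0] == "0" and len(prefix) > 1):
        return False
    return lo <= int(prefix) <= hi


def _numeral_extendable(lo: int, hi: int, prefix: str) -> bool:
    """True when some strictly longer in-range numeral starts with prefix."""
    if prefix == "" :
        return hi >= 1  # any first digit of a positive number
    if prefix == "0" or (prefix[0] == "0" and len(prefix) > 1):
        return False
    base = int(prefix)
    for extra in range(1, len(str(hi)) - len(prefix) + 1):
        low = base * 10**extra
        high = low + 10**extra - 1
        if low <= hi and high >= lo:
            return True
    return False


def _numeral_next_digits(lo: int, hi: int, prefix: str) -> set[str]:
    out = set()
    for d in "0123456789":
        q = prefix + d
        if q[0] == "0" and len(q) > 1:
            continue
        if _numeral_complete(lo, hi, q) or _numeral_extendable(lo, hi, q):
            out.add(d)
    return out


# ---------------------------------------------------------------------------
# the automaton


@dataclass(frozen=True)
class _LeafKey:
    op: str
    fld: str
    head: str  # '{"op":"<op>","content":{"field":"<field>","value":'
    values: tuple[str, ...] = ()  # sorted allowed values (enumerated keys)
    lo: int = 0
    hi: int = 0


class ConstraintAutomaton:
    """Lazy DFA over the canonical flat filter serialization.

    States are hashable tuples; :meth:`allowed_next` computes the outgoing
    alphabet and :meth:`try_step` performs an independent per-character
    check, so the two can be cross-validated.  The start state is
    ``("lit_root", 0)`` and the unique accepting state is ``("accept",)``.
    """

    def __init__(self, dd: DataDictionary):
        keys = []
        for spec in dd:
            if spec.kind == ENUMERATED:
                ops = ("in",)
            else:
                lo = math.ceil(spec.min_value)
                hi = math.floor(spec.max_value)
                if lo < 0:
                    raise ConstraintError(
                        f"numeric property {spec.name!r} has negative bounds; "
                        "the decoding dialect covers non-negative integers"
                    )
                if lo > hi:
                    raise ConstraintError(
                        f"numeric property {spec.name!r} has no integer in "
                        f"[{spec.min_value}, {spec.max_value}]"
                    )
                ops = (">=", "<=")
            for op in ops:
                head = (
                    '{"op":"' + op + '","content":{"field":"' + spec.name
                    + '","value":'
                )
                if spec.kind == ENUMERATED:
                    keys.append(
                        _LeafKey(op=op, fld=spec.name, head=head,
                                 values=tuple(sorted(spec.allowed_values)))
                    )
                else:
                    keys.append(
                        _LeafKey(op=op, fld=spec.name, head=head,
                                 lo=math.ceil(spec.min_value),
                                 hi=math.floor(spec.max_value))
                    )
        if not keys:
            raise ConstraintError("dictionary has no properties to decode over")
        keys.sort(key=lambda k: k.head)
        self.keys: tuple[_LeafKey, ...] = tuple(keys)
        self.dictionary = dd
        chars = set(_ROOT_OPEN) | set('[]{},"') | set("0123456789")
        for k in self.keys:
            chars |= set(k.head)
            for v in k.values:
                chars |= set(v)
        self.vocabulary = frozenset(chars)

    # -- state space -------------------------------------------------------

    @property
    def start_state(self):
        return ("lit_root", 0)

    def is_accepting(self, state) -> bool:
        return state == ("accept",)

    def _head_candidates(self, last: int, prefix: str) -> list[int]:
        return [
            k
            for k in range(last + 1, len(self.keys))
            if self.keys[k].head.startswith(prefix)
        ]

    def allowed_next(self, state) -> frozenset:
        """The exact set of characters with outgoing transitions.

        Empty only at the accepting state; every other reachable state can
        make progress, so masked decoding never dead-ends.
        """
        kind = state[0]
        if kind == "lit_root":
            return frozenset(_ROOT_OPEN[state[1]])
        if kind == "clause":
            _, last, prefix = state
            chars = set()
            for k in self._head_candidates(last, prefix):
                head = self.keys[k].head
                if len(head) > len(prefix):
                    chars.add(head[len(prefix)])
            return frozenset(chars)
        if kind == "vopen":
            return frozenset("[")
        if kind == "val":
            _, k, last_vi, vprefix = state
            if vprefix is None:
                return frozenset('"')
            key = self.keys[k]
            chars = set()
            for vi in range(last_vi + 1, len(key.values)):
                v = key.values[vi]
                if not v.startswith(vprefix):
                    continue
                if len(v) > len(vprefix):
                    chars.add(v[len(vprefix)])
                else:
                    chars.add('"')
            return frozenset(chars)
        if kind == "vdone":
            _, k, vi = state
            chars = {"]"}
            if vi < len(self.keys[k].values) - 1:
                chars.add(",")
            return frozenset(chars)
        if kind == "num":
            _, k, digits = state
            key = self.keys[k]
            chars = _numeral_next_digits(key.lo, key.hi, digits)
            if _numeral_complete(key.lo, key.hi, digits):
                chars.add("}")
            return frozenset(chars)
        if kind == "endlit":
            return frozenset("}")
        if kind == "after":
            _, k = state
            chars = {"]"}
            if k < len(self.keys) - 1:
                chars.add(",")
            return frozenset(chars)
        if kind == "close":
            return frozenset("}")
        if kind == "accept":
            return frozenset()
        raise ConstraintError(f"unknown automaton state {state!r}")

    def try_step(self, state, char: str):
        """Transition on one character, or ``None`` when not allowed.

        Implemented as an independent per-character check rather than via
        :meth:`allowed_next`, so the two routes can be tested against each
        other.
        """
        kind = state[0]
        if kind == "lit_root":
            i = state[1]
            if _ROOT_OPEN[i] != char:
                return None
            if i + 1 == len(_ROOT_OPEN):
                return ("clause", -1, "")
            return ("lit_root", i + 1)
        if kind == "clause":
            _, last, prefix = state
            new = prefix + char
            cands = self._head_candidates(last, new)
            if not cands:
                return None
            k = cands[0]
            if self.keys[k].head == new:
                if self.keys[k].op == "in":
                    return ("vopen", k)
                return ("num", k, "")
            return ("clause", last, new)
        if kind == "vopen":
            return ("val", state[1], -1, None) if char == "[" else None
        if kind == "val":
            _, k, last_vi, vprefix = state
            if vprefix is None:
                return ("val", k, last_vi, "") if char == '"' else None
            key = self.keys[k]
            if char == '"':
                for vi in range(last_vi + 1, len(key.values)):
                    if key.values[vi] == vprefix:
                        return ("vdone", k, vi)
                return None
            new = vprefix + char
            for vi in range(last_vi + 1, len(key.values)):
                if key.values[vi].startswith(new):
                    return ("val", k, last_vi, new)
            return None
        if kind == "vdone":
            _, k, vi = state
            if char == "]":
                return ("endlit", k, 0)
            if char == "," and vi < len(self.keys[k].values) - 1:
                return ("val", k, vi, None)
            return None
        if kind == "num":
            _, k, digits = state
            key = self.keys[k]
            if char == "}" and _numeral_complete(key.lo, key.hi, digits):
                return ("endlit", k, 1)
            if char.isdigit():
                q = digits + char
                if _numeral_complete(key.lo, key.hi, q) or _numeral_extendable(
                    key.lo, key.hi, q
                ):
                    return ("num", k, q)
            return None
        if kind == "endlit":
            _, k, n = state
            if char != "}":
                return None
            if n + 1 == 2:
                return ("after", k)
            return ("endlit", k, n + 1)
        if kind == "after":
            _, k = state
            if char == "]":
                return ("close",)
            if char == "," and k < len(self.keys) - 1:
                return ("clause", k, "")
            return None
        if kind == "close":
            return ("accept",) if char == "}" else None
        if kind == "accept":
            return None
        raise ConstraintError(f"unknown automaton state {state!r}")

    def step(self, state, char: str):
        nxt = self.try_step(state, char)
        if nxt is None:
            raise ConstraintError(
                f"character {char!r} not allowed in state {state!r}"
            )
        return nxt

    def accepts(self, text: str) -> bool:
        state = self.start_state
        for ch in text:
            state = self.try_step(state, ch)
            if state is None:
                return False
        return self.is_accepting(state)

    def run(self, text: str):
        """State after consuming ``text``, or ``None`` once off-language."""
        state = self.start_state
        for ch in text:
            state = self.try_step(state, ch)
            if state is None:
                return None
        return state

    def enumerate_accepted(self, max_clauses: int = 2):
        """Yield every accepted string with at most ``max_clauses`` clauses.

        Exhaustive bounded search; intended for small dictionaries with small
        numeric ranges.
        """
        stack = [(self.start_state, "", 1)]
        while stack:
            state, text, n_clauses = stack.pop()
            if self.is_accepting(state):
                yield text
                continue
            for ch in sorted(self.allowed_next(state)):
                if state[0] == "after" and ch == ",":
                    if n_clauses + 1 > max_clauses:
                        continue
                    stack.append((self.step(state, ch), text + ch, n_clauses + 1))
                else:
                    stack.append((self.step(state, ch), text + ch, n_clauses))


def build_automaton(dd: DataDictionary, vocabulary=None) -> ConstraintAutomaton:
    """Compile the constraint automaton for a dictionary.

    When an explicit ``vocabulary`` (iterable of characters) is supplied, it
    must cover every character that can appear in serialized filters;
    missing symbols raise :class:`ConstraintError` listing them.
    """
    automaton = ConstraintAutomaton(dd)
    if vocabulary is not None:
        missing = sorted(automaton.vocabulary - set(vocabulary))
        if missing:
            raise ConstraintError(
                f"vocabulary is missing required symbols: {missing!r}"
            )
    return automaton


def allowed_next(automaton: ConstraintAutomaton, state) -> frozenset:
    """Module-level alias of :meth:`ConstraintAutomaton.allowed_next`."""
    return automaton.allowed_next(state)


# ---------------------------------------------------------------------------
# training data


@dataclass(frozen=True)
class TrainingInstance:
    """One seq2seq unit: query prompt, canonical filter target, and their
    decoder-only concatenation ``prompt + SEPARATOR + target``."""

    prompt: str
    target: str

    @property
    def concatenated(self) -> str:
        return self.prompt + SEPARATOR + self.target


def make_training_instances(pairs, max_len: int = DEFAULT_MAX_LEN):
    """Convert query/filter pairs to instances, enforcing the length budget."""
    instances = []
    for p in pairs:
        target = serialize_filter(canonicalize(p.filter))
        prompt = p.query.replace(SEPARATOR, " ").strip()
        inst = TrainingInstance(prompt=prompt, target=target)
        if len(inst.concatenated) + len(EOS) > max_len:
            raise ValueError(
                f"instance exceeds the {max_len}-unit budget: {prompt[:60]!r}…"
            )
        instances.append(inst)
    return instances


# ---------------------------------------------------------------------------
# feature extraction

_WORD_RE = re.compile(r"[a-z0-9][a-z0-9.\-]*")
_NUM_TOKEN_RE = re.compile(r"(?<![0-9A-Za-z.\-])(\d+)(?![0-9A-Za-z\-])")
_VALUE_DONE_RE = re.compile(r'"value":(\d+)\}')
_COPY_CLASS = frozenset(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789 .,-"
)

# pairwise feature templates
_T_COPY = 0            # character continues a query substring match
_T_HEAD_ANY = 1        # next char of any mentioned candidate clause head
_T_HEAD_MIN = 2        # next char of the first mentioned candidate clause head
_T_VAL_ANY = 3         # next char of any mentioned candidate value
_T_VAL_MIN = 4         # next char of the first mentioned candidate value
_T_LIST_MORE = 5       # ',' while a mentioned value remains unemitted
_T_LIST_DONE = 6       # ']' when no mentioned value remains
_T_CLAUSE_MORE = 7     # ',' while a mentioned clause remains unemitted
_T_CLAUSE_DONE = 8     # ']' when no mentioned clause remains
_T_NUM_CLOSE = 9       # '}' when the emitted digits equal a query number
_T_DIGIT_BASE = 10     # 4x4 grid: next digit of query number i at slot j
N_PAIR_TEMPLATES = _T_DIGIT_BASE + 16


def _tokenize(text: str) -> list[str]:
    return ["<num>" if t.isdigit() else t for t in _WORD_RE.findall(text.lower())]


class _QueryContext:
    """Per-query precomputation shared across decoding positions."""

    def __init__(self, query: str, automaton: ConstraintAutomaton):
        self.query = query
        self.tokens = set(_tokenize(query))
        self.numbers = _NUM_TOKEN_RE.findall(query)
        self.number_set = set(self.numbers)
        lowered = query.lower()
        self.mentioned_key = []
        self.mentioned_values = []
        for key in automaton.keys:
            spec = automaton.dictionary[key.fld]
            label_tokens = set(_tokenize(spec.display_label))
            self.mentioned_key.append(
                bool(label_tokens) and label_tokens <= self.tokens
            )
            mentioned = set()
            for vi, v in enumerate(key.values):
                # Hyphens count as token-internal so "TCGA" does not match
                # inside "TCGA-LUAD".
                pattern = (
                    r"(?<![a-z0-9-])" + re.escape(v.lower()) + r"(?![a-z0-9-])"
                )
                if re.search(pattern, lowered):
                    mentioned.add(vi)
            self.mentioned_values.append(mentioned)


def _copy_next_chars(query: str, output: str) -> set[str]:
    """Characters that continue the longest suffix of the output found
    verbatim in the query (the pointer/copy signal)."""
    tail_chars = []
    for ch in reversed(output):
        if ch not in _COPY_CLASS:
            break
        tail_chars.append(ch)
        if len(tail_chars) == 10:
            break
    tail = "".join(reversed(tail_chars))
    if not tail:
        return set()
    min_len = 1 if tail[-1].isdigit() else 2
    for length in range(len(tail), min_len - 1, -1):
        suffix = tail[-length:]
        found = set()
        start = query.find(suffix)
        while start != -1:
            end = start + length
            if end < len(query):
                found.add(query[end])
            start = query.find(suffix, start + 1)
        if found:
            return found
    return set()


def _pairwise_features(
    automaton: ConstraintAutomaton, ctx: _QueryContext, state, output: str
):
    """List of (template, character) features active at this position."""
    feats = []
    for ch in _copy_next_chars(ctx.query, output):
        feats.append((_T_COPY, ch))
    if state is None:
        return feats
    kind = state[0]
    if kind == "clause":
        _, last, prefix = state
        first = True
        for k in automaton._head_candidates(last, prefix):
            if not ctx.mentioned_key[k]:
                continue
            head = automaton.keys[k].head
            if len(head) > len(prefix):
                feats.append((_T_HEAD_ANY, head[len(prefix)]))
                if first:
                    feats.append((_T_HEAD_MIN, head[len(prefix)]))
            first = False
    elif kind == "val" and state[3] is not None:
        _, k, last_vi, vprefix = state
        key = automaton.keys[k]
        mentioned = ctx.mentioned_values[k]
        first = True
        for vi in range(last_vi + 1, len(key.values)):
            v = key.values[vi]
            if not v.startswith(vprefix) or vi not in mentioned:
                continue
            nxt = v[len(vprefix)] if len(v) > len(vprefix) else '"'
            feats.append((_T_VAL_ANY, nxt))
            if first:
                feats.append((_T_VAL_MIN, nxt))
            first = False
    elif kind == "vdone":
        _, k, vi = state
        remaining = any(
            v2 > vi for v2 in ctx.mentioned_values[k]
        )
        feats.append((_T_LIST_MORE, ",") if remaining else (_T_LIST_DONE, "]"))
    elif kind == "num":
        _, k, digits = state
        slot = min(len(_VALUE_DONE_RE.findall(output)), 3)
        for i, number in enumerate(ctx.numbers[:4]):
            if number.startswith(digits) and len(number) > len(digits):
                feats.append((_T_DIGIT_BASE + 4 * slot + i, number[len(digits)]))
        if digits and digits in ctx.number_set:
            feats.append((_T_NUM_CLOSE, "}"))
    elif kind == "after":
        _, k = state
        remaining = any(
            ctx.mentioned_key[k2] for k2 in range(k + 1, len(automaton.keys))
        )
        feats.append((_T_CLAUSE_MORE, ",") if remaining else (_T_CLAUSE_DONE, "]"))
    return feats


# ---------------------------------------------------------------------------
# the maxent character model


@dataclass
class TrainConfig:
    """Optimization and architecture settings for the reference backbone."""

    dictionary: DataDictionary | None = None
    seed: int = 0
    epochs: int = 14
    batch_size: int = 2048
    learning_rate: float = 0.08
    l2: float = 1e-6
    window: int = 16
    max_len: int = DEFAULT_MAX_LEN
    holdout_fraction: float = 0.1


class MaxentCharModel:
    """Autoregressive character LM: linear softmax over window n-gram,
    query bag-of-words, and pairwise pointer/copy features.

    Exposes :meth:`next_scores` (finite scores over the full character
    vocabulary for any prefix within the length budget), which is the only
    contract :func:`generate` relies on.
    """

    def __init__(self, char_vocab, word_vocab, window, max_len, dd, metadata=None):
        self.char_vocab = list(char_vocab)
        self.char_index = {c: i for i, c in enumerate(self.char_vocab)}
        self.word_vocab = dict(word_vocab)
        self.window = window
        self.max_len = max_len
        self.dictionary = dd
        self.automaton = ConstraintAutomaton(dd)
        C = len(self.char_vocab)
        self.n_features = window * C + len(self.word_vocab) + 1
        self.W = np.zeros((self.n_features, C))
        self.u = np.zeros(N_PAIR_TEMPLATES)
        self.metadata = metadata or {}
        self._ctx_cache: tuple[str, _QueryContext] | None = None
        self._state_cache: tuple[str, object] | None = None

    # -- feature assembly --------------------------------------------------

    def _window_indices(self, output: str) -> list[int]:
        C = len(self.char_vocab)
        padded = _BOS + output
        rows = []
        for pos in range(self.window):
            j = len(padded) - 1 - pos
            ch = padded[j] if j >= 0 else _PAD
            rows.append(pos * C + self.char_index.get(ch, self.char_index[_PAD]))
        return rows

    def _word_indices(self, query: str) -> list[int]:
        base = self.window * len(self.char_vocab)
        idx = {
            base + self.word_vocab[t]
            for t in _tokenize(query)
            if t in self.word_vocab
        }
        return sorted(idx)

    def _query_context(self, query: str) -> _QueryContext:
        if self._ctx_cache is not None and self._ctx_cache[0] == query:
            return self._ctx_cache[1]
        ctx = _QueryContext(query, self.automaton)
        self._ctx_cache = (query, ctx)
        return ctx

    def _tracker_state(self, output: str):
        if self._state_cache is not None:
            prev_out, prev_state = self._state_cache
            if output == prev_out:
                return prev_state
            if output.startswith(prev_out) and len(output) == len(prev_out) + 1:
                state = (
                    None
                    if prev_state is None
                    else self.automaton.try_step(prev_state, output[-1])
                )
                self._state_cache = (output, state)
                return state
        state = self.automaton.run(output)
        self._state_cache = (output, state)
        return state

    def next_scores(self, prefix: str) -> np.ndarray:
        """Scores over the character vocabulary for the next unit."""
        if len(prefix) >= self.max_len:
            raise TruncationError(
                f"prefix length {len(prefix)} reaches the {self.max_len} budget"
            )
        if SEPARATOR in prefix:
            query, output = prefix.split(SEPARATOR, 1)
        else:
            query, output = prefix, ""
        rows = self._window_indices(output) + self._word_indices(query)
        rows.append(self.n_features - 1)
        scores = self.W[rows].sum(axis=0)
        ctx = self._query_context(query)
        state = self._tracker_state(output)
        for t, ch in _pairwise_features(self.automaton, ctx, state, output):
            ci = self.char_index.get(ch)
            if ci is not None:
                scores[ci] += self.u[t]
        return scores


def _build_design(model: MaxentCharModel, instances):
    """Sparse design matrices and targets for all next-char positions of the
    target (+EOS) region of every instance."""
    C = len(model.char_vocab)
    indptr = [0]
    indices: list[int] = []
    targets: list[int] = []
    pair_rows = [[] for _ in range(N_PAIR_TEMPLATES)]
    pair_cols = [[] for _ in range(N_PAIR_TEMPLATES)]
    automaton = model.automaton
    row = 0
    for inst in instances:
        word_idx = model._word_indices(inst.prompt)
        ctx = _QueryContext(inst.prompt, automaton)
        seq = inst.target + EOS
        state = automaton.start_state
        output = ""
        for ch in seq:
            indices.extend(model._window_indices(output))
            indices.extend(word_idx)
            indices.append(model.n_features - 1)
            indptr.append(len(indices))
            targets.append(model.char_index[ch])
            for t, pch in _pairwise_features(automaton, ctx, state, output):
                ci = model.char_index.get(pch)
                if ci is not None:
                    pair_rows[t].append(row)
                    pair_cols[t].append(ci)
            row += 1
            if ch != EOS and state is not None:
                state = automaton.try_step(state, ch)
            output += ch if ch != EOS else ""
    n = row
    X = sp.csr_matrix(
        (np.ones(len(indices)), np.array(indices), np.array(indptr)),
        shape=(n, model.n_features),
    )
    G = []
    for t in range(N_PAIR_TEMPLATES):
        G.append(
            sp.csr_matrix(
                (
                    np.ones(len(pair_rows[t])),
                    (np.array(pair_rows[t], dtype=int), np.array(pair_cols[t], dtype=int)),
                ),
                shape=(n, C),
            )
        )
    y = np.array(targets, dtype=int)
    return X, G, y


def _mean_ce(model, X, G, y, W, u, batch=8192):
    n = X.shape[0]
    total = 0.0
    for start in range(0, n, batch):
        idx = slice(start, min(start + batch, n))
        logits = np.asarray(X[idx] @ W)
        for t in range(N_PAIR_TEMPLATES):
            if u[t] != 0.0 and G[t].nnz:
                logits += u[t] * G[t][idx].toarray()
        logits -= logits.max(axis=1, keepdims=True)
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        total += -logp[np.arange(logp.shape[0]), y[idx]].sum()
    return total / max(n, 1)


def train(corpus, config: TrainConfig) -> MaxentCharModel:
    """Fit the maxent backbone with a causal LM objective (Adam, seeded).

    ``corpus`` is a list of query/filter pairs or prebuilt
    :class:`TrainingInstance` objects.  Raises on an empty corpus or an
    over-length instance.  Held-out cross-entropy before and after training
    is logged and stored in the model metadata.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    if config.dictionary is None:
        raise ValueError("TrainConfig.dictionary is required")
    dd = config.dictionary
    if isinstance(corpus[0], TrainingInstance):
        instances = list(corpus)
        for inst in instances:
            if len(inst.concatenated) + len(EOS) > config.max_len:
                raise ValueError(
                    f"instance exceeds the {config.max_len}-unit budget: "
                    f"{inst.prompt[:60]!r}…"
                )
    else:
        instances = make_training_instances(corpus, max_len=config.max_len)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(instances))
    n_holdout = int(round(config.holdout_fraction * len(instances)))
    holdout = [instances[i] for i in order[: n_holdout]]
    training = [instances[i] for i in order[n_holdout:]] or instances

    automaton = ConstraintAutomaton(dd)
    chars = set(automaton.vocabulary)
    for inst in instances:
        chars |= set(inst.target)
    char_vocab = [_PAD, _BOS, EOS] + sorted(chars)
    word_counts: dict[str, int] = {}
    for inst in instances:
        for tok in set(_tokenize(inst.prompt)):
            word_counts[tok] = word_counts.get(tok, 0) + 1
    word_vocab = {w: i for i, w in enumerate(sorted(word_counts))}

    model = MaxentCharModel(
        char_vocab=char_vocab,
        word_vocab=word_vocab,
        window=config.window,
        max_len=config.max_len,
        dd=dd,
        metadata={
            "seed": config.seed,
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "learning_rate": config.learning_rate,
            "l2": config.l2,
            "window": config.window,
            "max_len": config.max_len,
            "separator": SEPARATOR,
            "n_training_instances": len(training),
            "n_holdout_instances": len(holdout),
            "dictionary_sha256": hashlib.sha256(
                serialize_dictionary(dd).encode()
            ).hexdigest(),
        },
    )

    X, G, y = _build_design(model, training)
    if holdout:
        Xh, Gh, yh = _build_design(model, holdout)
        initial_holdout = _mean_ce(model, Xh, Gh, yh, model.W, model.u)
    n, C = X.shape[0], len(char_vocab)
    W = model.W
    u = model.u
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mu = np.zeros_like(u); vu = np.zeros_like(u)
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            B = len(idx)
            Xb = X[idx]
            logits = np.asarray(Xb @ W)
            Gb = []
            for t in range(N_PAIR_TEMPLATES):
                gt = G[t][idx]
                Gb.append(gt)
                if gt.nnz:
                    logits += u[t] * gt.toarray()
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(B), y[idx]] -= 1.0
            p /= B
            gW = np.asarray(Xb.T @ p) + config.l2 * W
            gu = np.array(
                [Gb[t].multiply(p).sum() if Gb[t].nnz else 0.0
                 for t in range(N_PAIR_TEMPLATES)]
            )
            step += 1
            mW = b1 * mW + (1 - b1) * gW
            vW = b2 * vW + (1 - b2) * gW * gW
            mu = b1 * mu + (1 - b1) * gu
            vu = b2 * vu + (1 - b2) * gu * gu
            corr1 = 1 - b1**step
            corr2 = 1 - b2**step
            W -= config.learning_rate * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
            u -= config.learning_rate * (mu / corr1) / (np.sqrt(vu / corr2) + eps)
    model.W = W
    model.u = u
    final_train = _mean_ce(model, X, G, y, W, u)
    model.metadata["train_loss_initial"] = float(np.log(C))
    model.metadata["train_loss_final"] = float(final_train)
    if holdout:
        final_holdout = _mean_ce(model, Xh, Gh, yh, W, u)
        model.metadata["holdout_loss_initial"] = float(initial_holdout)
        model.metadata["holdout_loss_final"] = float(final_holdout)
        logger.info(
            "train: held-out CE %.4f -> %.4f (train %.4f, n=%d)",
            initial_holdout, final_holdout, final_train, n,
        )
    return model


# ---------------------------------------------------------------------------
# decoding


def generate(
    model: MaxentCharModel,
    query: str,
    automaton: ConstraintAutomaton | None = None,
    decode: str = "greedy",
    rng: np.random.Generator | None = None,
    max_len: int | None = None,
) -> str:
    """Decode filter JSON text for a query.

    With an automaton, next-character scores are masked to the allowed set,
    so the output is guaranteed to be strict-valid regardless of the model;
    decoding stops at the accepting state.  Without one, decoding is free
    and stops at the end-of-sequence unit.  Greedy decoding is deterministic
    (ties broken by vocabulary order); ``decode="sampled"`` needs ``rng``.
    Raises :class:`TruncationError` when the length budget runs out first.
    """
    if decode not in ("greedy", "sampled"):
        raise ValueError(f"unknown decode mode {decode!r}")
    if decode == "sampled" and rng is None:
        raise ValueError("sampled decoding requires an rng")
    budget = max_len if max_len is not None else model.max_len
    prompt = query.replace(SEPARATOR, " ").strip()
    base = prompt + SEPARATOR
    if len(base) >= budget:
        raise TruncationError("query alone exceeds the length budget")
    out = ""
    state = automaton.start_state if automaton is not None else None
    specials = {model.char_index[_PAD], model.char_index[_BOS]}
    while True:
        if automaton is not None:
            allowed = automaton.allowed_next(state)
            if not allowed:
                if automaton.is_accepting(state):
                    return out
                raise ConstraintError(f"dead end at state {state!r}")
        if len(base) + len(out) >= budget:
            raise TruncationError(
                "length budget reached before generation completed"
            )
        scores = model.next_scores(base + out)
        if automaton is not None:
            mask_idx = [
                model.char_index[c] for c in allowed if c in model.char_index
            ]
            if not mask_idx:
                raise ConstraintError(
                    "model vocabulary covers no allowed character; rebuild the "
                    "model with this dictionary"
                )
        else:
            mask_idx = [
                i for i in range(len(model.char_vocab)) if i not in specials
            ]
        sub = scores[mask_idx]
        if decode == "greedy":
            choice = mask_idx[int(np.argmax(sub))]
        else:
            p = np.exp(sub - sub.max())
            p /= p.sum()
            choice = mask_idx[int(rng.choice(len(mask_idx), p=p))]
        ch = model.char_vocab[choice]
        if automaton is None and ch == EOS:
            return out
        if automaton is not None:
            state = automaton.step(state, ch)
        out += ch


# ---------------------------------------------------------------------------
# persistence (runtime artifacts: metadata JSON + npz weights)


def save_model(model: MaxentCharModel, directory: str | os.PathLike) -> None:
    os.makedirs(directory, exist_ok=True)
    meta = dict(model.metadata)
    meta.update(
        {
            "char_vocab": model.char_vocab,
            "word_vocab": model.word_vocab,
            "window": model.window,
            "max_len": model.max_len,
            "dictionary_json": serialize_dictionary(model.dictionary),
        }
    )
    with open(os.path.join(directory, "metadata.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh)
    np.savez(os.path.join(directory, "weights.npz"), W=model.W, u=model.u)


def load_model(directory: str | os.PathLike) -> MaxentCharModel:
    with open(os.path.join(directory, "metadata.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    dd = load_dictionary(meta.pop("dictionary_json"))
    model = MaxentCharModel(
        char_vocab=meta.pop("char_vocab"),
        word_vocab=meta.pop("word_vocab"),
        window=meta.pop("window"),
        max_len=meta.pop("max_len"),
        dd=dd,
        metadata=meta,
    )
    weights = np.load(os.path.join(directory, "weights.npz"))
    model.W = weights["W"]
    model.u = weights["u"]
    return model
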