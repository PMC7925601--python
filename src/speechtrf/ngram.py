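"""Interpolated modified Kneser--Ney n-gram language model and surprisal.

The model is trained on tokenized sentences and provides smoothed conditional
probabilities ``P(w | history)`` for any history built from in-vocabulary
words, with an ``<unk>`` symbol absorbing out-of-vocabulary tokens.  The
implementation follows the standard modified Kneser--Ney recursion: three
discounts ``D1, D2, D3+`` per order estimated from count-of-count statistics,
raw counts at the entry order, continuation counts at the backed-off orders,
and full interpolation down to a discounted unigram distribution mixed with a
uniform distribution over the vocabulary.  Probabilities are strictly
positive for every in-vocabulary word and sum to one over the vocabulary for
any history.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from .tokens import WordToken, normalize_word

__all__ = ["NGramModel", "train_kneser_ney", "surprisal", "UNK"]

UNK = "<unk>"

_FALLBACK_DISCOUNT = 0.75


def _estimate_discounts(counts: Iterable[int]) -> tuple[float, float, float]:
    """Modified KN discounts (D1, D2, D3+) from count-of-counts.

    Falls back to a fixed discount of 0.75 (with a warning) when the
    count-of-count statistics needed by the closed-form estimates are missing,
    as happens on very small corpora.
    """
    n = Counter()
    for c in counts:
        if 1 <= c <= 4:
            n[c] += 1
    n1, n2, n3, n4 = n[1], n[2], n[3], n[4]
    if min(n1, n2, n3, n4) == 0:
        warnings.warn(
            "count-of-counts too sparse for modified-KN discount estimation; "
            f"falling back to fixed discount {_FALLBACK_DISCOUNT}",
            stacklevel=2,
        )
        d = _FALLBACK_DISCOUNT
        return d, d, d
    y = n1 / (n1 + 2.0 * n2)
    d1 = 1.0 - 2.0 * y * n2 / n1
    d2 = 2.0 - 3.0 * y * n3 / n2
    d3 = 3.0 - 4.0 * y * n4 / n3
    # Negative estimates can occur on unusual corpora; clamping keeps the
    # discounted mass non-negative without breaking normalization.
    return max(d1, 0.0), max(d2, 0.0), max(d3, 0.0)


class _Distribution:
    """One order's count table, indexed history -> {word: count}."""

    __slots__ = ("followers", "discounts", "_stats")

    def __init__(self, followers: dict[tuple, dict[str, int]]):
        self.followers = followers
        all_counts = [c for d in followers.values() for c in d.values()]
        self.discounts = _estimate_discounts(all_counts)
        self._stats: dict[tuple, tuple[float, float]] = {}

    def history_stats(self, h: tuple) -> tuple[float, float]:
        """(total count of h·, discounted mass to redistribute)."""
        cached = self._stats.get(h)
        if cached is not None:
            return cached
        d1, d2, d3 = self.discounts
        fol = self.followers.get(h)
        if not fol:
            out = (0.0, 0.0)
        else:
            total = 0
            n1 = n2 = n3p = 0
            for c in fol.values():
                total += c
                if c == 1:
                    n1 += 1
                elif c == 2:
                    n2 += 1
                else:
                    n3p += 1
            out = (float(total), d1 * n1 + d2 * n2 + d3 * n3p)
        self._stats[h] = out
        return out

    def count(self, h: tuple, w: str) -> int:
        fol = self.followers.get(h)
        return fol.get(w, 0) if fol else 0

    def discount_for(self, c: int) -> float:
        d1, d2, d3 = self.discounts
        if c == 1:
            return d1
        if c == 2:
            return d2
        return d3


class NGramModel:
    """Modified interpolated Kneser--Ney model of a fixed maximum order.

    Use :func:`train_kneser_ney` to construct one from a corpus.
    """

    def __init__(
        self,
        order: int,
        vocab: frozenset[str],
        raw: dict[int, _Distribution],
        cont: dict[int, _Distribution],
    ):
        self.order = order
        self.vocab = vocab
        self._raw = raw
        self._cont = cont

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    def _map(self, word: str) -> str:
        return word if word in self.vocab else UNK

    def prob(self, word: str, history: Sequence[str] = ()) -> float:
        """Smoothed P(word | history).

        ``history`` is the ordered sequence of preceding words (oldest first);
        only the last ``order - 1`` entries are used.  Out-of-vocabulary words
        (in the target or the history) are mapped to ``<unk>``.
        """
        w = self._map(word)
        h = tuple(self._map(x) for x in history[-(self.order - 1):])
        return self._prob(w, h, top=True)

    def _prob(self, w: str, h: tuple, top: bool) -> float:
        k = len(h) + 1
        dist = (self._raw if top else self._cont)[k]
        lower = (
            1.0 / self.vocab_size
            if k == 1
            else self._prob(w, h[1:], top=False)
        )
        total, discounted = dist.history_stats(h)
        if total == 0.0:
            return lower  # unseen history: pure backoff
        c = dist.count(h, w)
        num = max(c - dist.discount_for(c), 0.0) if c > 0 else 0.0
        return num / total + (discounted / total) * lower

    def logprob(self, word: str, history: Sequence[str] = ()) -> float:
        return math.log(self.prob(word, history))


def _build_followers(
    counts: Counter,
) -> dict[tuple, dict[str, int]]:
    followers: dict[tuple, dict[str, int]] = defaultdict(dict)
    for gram, c in counts.items():
        followers[gram[:-1]][gram[-1]] = c
    return dict(followers)


def train_kneser_ney(
    sentences: Iterable[Sequence[str]], order: int = 5
) -> NGramModel:
    """Train a modified interpolated Kneser--Ney model.

    Parameters
    ----------
    sentences : iterable of tokenized sentences (lists of word strings);
        n-gram windows never cross sentence boundaries.
    order : maximum n-gram order (default 5).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    sents = [list(s) for s in sentences]
    if not any(sents):
        raise ValueError("corpus is empty")

    raw_counts: dict[int, Counter] = {k: Counter() for k in range(1, order + 1)}
    for sent in sents:
        n = len(sent)
        for k in range(1, order + 1):
            for i in range(n - k + 1):
                raw_counts[k][tuple(sent[i : i + k])] += 1

    vocab = frozenset(w for (w,) in raw_counts[1]) | {UNK}

    # Continuation counts: number of distinct single-word left extensions.
    cont_counts: dict[int, Counter] = {k: Counter() for k in range(1, order)}
    for k in range(1, order):
        for gram in raw_counts[k + 1]:
            cont_counts[k][gram[1:]] += 1

    raw = {k: _Distribution(_build_followers(raw_counts[k])) for k in raw_counts}
    cont = {
        k: _Distribution(_build_followers(cont_counts[k])) for k in cont_counts
    }
    # The full order is never backed off into; alias it so both tables exist.
    cont[order] = raw[order]
    return NGramModel(order, vocab, raw, cont)


def surprisal(
    model: NGramModel, tokens: Sequence[WordToken | str]
) -> list[float]:
    """Per-token surprisal ``-ln P(w | up to order-1 preceding words)``.

    Histories are built from all words (content and function alike) and are
    truncated at sentence starts: a word never conditions on words from the
    previous sentence.  Tokens may be :class:`WordToken` (sentence boundaries
    from ``sentence_id``) or bare strings (treated as a single sentence).
    Words are normalized (lower-cased, punctuation-stripped) before lookup;
    out-of-vocabulary words map to ``<unk>``.
    """
    out: list[float] = []
    history: list[str] = []
    prev_sentence: int | None = None
    for tok in tokens:
        if isinstance(tok, WordToken):
            word, sent = tok.word, tok.sentence_id
        else:
            word, sent = tok, 0
        if sent != prev_sentence:
            history = []
            prev_sentence = sent
        norm = normalize_word(word)
        out.append(-model.logprob(norm, history[-(model.order - 1):]))
        history.append(norm)
    return out
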