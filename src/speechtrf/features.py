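"""Word-level regressors: semantic dissimilarity, surprisal alignment and
impulse-series construction.

Semantic dissimilarity for a content word is ``1 - r`` where ``r`` is the
Pearson correlation between the word's embedding vector and the average of the
embedding vectors of its preceding context words.  In ``"sentence"`` mode the
context is every preceding content word of the same sentence; in window mode
(``context=k``) it is the ``k`` most recent preceding content words regardless
of sentence boundary.  Words without an embedding are unscored and excluded
from context averages; a word with an empty context is unscored.  Scored
features are reduced to the impulses common to both dissimilarity and
surprisal before regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ngram import NGramModel, surprisal
from .tokens import EmbeddingTable, WordToken, normalize_word

__all__ = [
    "FeatureImpulseSeries",
    "ScoredFeatures",
    "semantic_dissimilarity",
    "normalize_match",
    "build_impulse_series",
    "build_onset_regressor",
    "score_transcript",
]


@dataclass
class FeatureImpulseSeries:
    """A sample-rate regressor: zeros except at content-word onset samples.

    ``word_index_map`` maps sample index -> tuple of token indices whose
    impulses landed on that sample (tuples of length > 1 only on collisions).
    """

    name: str
    values: np.ndarray
    fs: float
    word_index_map: dict[int, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def nonzero_samples(self) -> np.ndarray:
        return np.flatnonzero(self.values)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def semantic_dissimilarity(
    tokens: Sequence[WordToken],
    embeddings: EmbeddingTable,
    context: str | int = "sentence",
) -> np.ndarray:
    """Per-token dissimilarity; NaN for unscored tokens.

    A token is scored iff it is a content word with an embedding and a
    non-empty context. Context words are the preceding embeddable content
    words — of the same sentence (``context="sentence"``) or the last ``k``
    across sentence boundaries (``context=k``).
    """
    if isinstance(context, str):
        if context != "sentence":
            raise ValueError(f"unknown context mode {context!r}")
        k = None
    else:
        k = int(context)
        if k < 1:
            raise ValueError("window size must be >= 1")

    out = np.full(len(tokens), np.nan)
    ctx: list[np.ndarray] = []
    prev_sentence: int | None = None
    for i, tok in enumerate(tokens):
        if k is None and tok.sentence_id != prev_sentence:
            ctx = []
            prev_sentence = tok.sentence_id
        if not tok.is_content:
            continue
        norm = normalize_word(tok.word)
        if norm not in embeddings:
            warnings.warn(f"no embedding for {tok.word!r}; token unscored")
            continue
        vec = embeddings.get(norm)
        window = ctx if k is None else ctx[-k:]
        if window:
            r = _pearson(vec, np.mean(window, axis=0))
            if np.isnan(r):
                warnings.warn(
                    f"degenerate (constant) vector for {tok.word!r}; unscored"
                )
            else:
                out[i] = 1.0 - r
        ctx.append(vec)
    return out


def normalize_match(
    values: np.ndarray, reference_values: np.ndarray | tuple[float, float]
) -> np.ndarray:
    """Affinely rescale ``values`` to the mean/sd of a reference distribution.

    ``reference_values`` may be a sample or an explicit ``(mean, sd)`` pair.
    Raises on constant input (sd = 0), which cannot be matched.
    """
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values))
    if sd == 0.0:
        raise ValueError("cannot normalize constant values (sd = 0)")
    if isinstance(reference_values, tuple):
        ref_mean, ref_sd = map(float, reference_values)
    else:
        ref = np.asarray(reference_values, dtype=float)
        ref_mean, ref_sd = float(np.mean(ref)), float(np.std(ref))
    if ref_sd <= 0.0:
        raise ValueError("reference sd must be > 0")
    return (values - values.mean()) / sd * ref_sd + ref_mean


def build_impulse_series(
    tokens: Sequence[WordToken],
    values: Sequence[float],
    fs: float,
    n_samples: int,
    token_indices: Sequence[int] | None = None,
    name: str = "feature",
) -> FeatureImpulseSeries:
    """Place ``values`` as impulses at ``round(onset_s * fs)``.

    ``token_indices`` selects which tokens carry the values (defaults to all
    tokens, in which case NaN values are skipped). Collisions — two words
    rounding to the same sample — are summed with a warning. Onsets beyond
    the trial raise an error naming the token.
    """
    if token_indices is None:
        token_indices = range(len(tokens))
    series = np.zeros(n_samples)
    index_map: dict[int, tuple[int, ...]] = {}
    for ti, val in zip(token_indices, values):
        if np.isnan(val):
            continue
        tok = tokens[ti]
        s = int(round(tok.onset_s * fs))
        if not 0 <= s < n_samples:
            raise ValueError(
                f"token {tok.word!r} at onset {tok.onset_s}s maps to sample "
                f"{s}, outside trial of {n_samples} samples at {fs} Hz"
            )
        if s in index_map:
            warnings.warn(
                f"impulse collision at sample {s} (tokens "
                f"{index_map[s] + (ti,)}); heights summed"
            )
            index_map[s] = index_map[s] + (ti,)
        else:
            index_map[s] = (ti,)
        series[s] += val
    return FeatureImpulseSeries(name, series, fs, index_map)


def build_onset_regressor(
    tokens: Sequence[WordToken],
    dissimilarity_values: Sequence[float],
    surprisal_values: Sequence[float],
    fs: float,
    n_samples: int,
    token_indices: Sequence[int] | None = None,
    name: str = "onset",
) -> FeatureImpulseSeries:
    """Acoustic-onset nuisance regressor.

    A single constant impulse height — the mean of the trial's concatenated
    dissimilarity and surprisal values — placed at every scored onset.
    """
    dis = np.asarray(dissimilarity_values, dtype=float)
    sur = np.asarray(surprisal_values, dtype=float)
    both = np.concatenate([dis[~np.isnan(dis)], sur[~np.isnan(sur)]])
    if both.size == 0:
        warnings.warn("no scored words in trial; onset regressor is all-zero")
        return FeatureImpulseSeries(name, np.zeros(n_samples), fs, {})
    height = float(both.mean())
    if token_indices is None:
        token_indices = [i for i, v in enumerate(dis) if not np.isnan(v)]
        heights = [height] * len(token_indices)
    else:
        heights = [height] * len(token_indices)
    return build_impulse_series(
        tokens, heights, fs, n_samples, token_indices=token_indices, name=name
    )


def score_transcript(
    tokens: Sequence[WordToken],
    embeddings: EmbeddingTable,
    model: NGramModel,
    context: str | int = "sentence",
) -> "ScoredFeatures":
    """Dissimilarity + surprisal for one trial, reduced to common impulses."""
    dis = semantic_dissimilarity(tokens, embeddings, context=context)
    sur = np.asarray(surprisal(model, tokens), dtype=float)
    # Common-impulse rule: keep only content words with a dissimilarity score;
    # surprisal is defined everywhere so this is the binding constraint.
    scored = np.flatnonzero(~np.isnan(dis))
    return ScoredFeatures(
        token_indices=scored,
        onsets_s=np.array([tokens[i].onset_s for i in scored]),
        words=[tokens[i].word for i in scored],
        dissimilarity=dis[scored],
        surprisal=sur[scored],
    )


@dataclass
class ScoredFeatures:
    """Aligned per-word feature values for the scored content words of a trial."""

    token_indices: np.ndarray
    onsets_s: np.ndarray
    words: list[str]
    dissimilarity: np.ndarray
    surprisal: np.ndarray

    def __len__(self) -> int:
        return len(self.token_indices)

    def normalized_surprisal(
        self, reference: np.ndarray | tuple[float, float] | None = None
    ) -> np.ndarray:
        """Surprisal matched to the dissimilarity distribution (or explicit moments)."""
        ref = self.dissimilarity if reference is None else reference
        return normalize_match(self.surprisal, ref)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "token_index": self.token_indices,
                "word": self.words,
                "onset_s": self.onsets_s,
                "dissimilarity": self.dissimilarity,
                "surprisal": self.surprisal,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
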