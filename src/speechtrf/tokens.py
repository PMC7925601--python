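"""Word tokens, embedding tables and content-word flagging."""

from __future__ import annotations

import string
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WordToken",
    "EmbeddingTable",
    "normalize_word",
    "flag_content_words",
    "DEFAULT_FUNCTION_WORDS",
    "read_transcript_tsv",
    "write_transcript_tsv",
]

_PUNCT = string.punctuation + "‘’“”–—"


def normalize_word(word: str) -> str:
    """Lower-case and strip surrounding punctuation."""
    return word.strip(_PUNCT).lower()


@dataclass(frozen=True)
class WordToken:
    """One word of a time-aligned transcript.

    Attributes
    ----------
    word : surface form as transcribed.
    onset_s, offset_s : word boundaries in seconds; ``onset_s < offset_s``.
    sentence_id : running sentence index, non-decreasing within a trial.
    is_content : True for open-class (content) words.
    """

    word: str
    onset_s: float
    offset_s: float
    sentence_id: int
    is_content: bool = True

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError(
                f"token {self.word!r}: onset_s ({self.onset_s}) must be < "
                f"offset_s ({self.offset_s})"
            )


class EmbeddingTable:
    """Vocabulary -> d-dimensional real vectors (GloVe-style).

    Parameters
    ----------
    words : vocabulary, one entry per row of ``vectors``.
    vectors : array of shape (n_words, dim); must be finite.
    """

    def __init__(self, words: Sequence[str], vectors: np.ndarray):
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2 or len(words) != vectors.shape[0]:
            raise ValueError("words and vectors must align (n_words, dim)")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("embedding vectors must be finite")
        self.words = list(words)
        self.vectors = vectors
        self._index = {w: i for i, w in enumerate(self.words)}
        if len(self._index) != len(self.words):
            raise ValueError("duplicate words in embedding table")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def get(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    # -- GloVe text format: "word v1 v2 ... vd" per line, space-delimited --

    @classmethod
    def read_text(cls, path: str | Path) -> "EmbeddingTable":
        words: list[str] = []
        rows: list[list[float]] = []
        with open(path, "r", encoding="utf8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) < 2:
                    continue
                words.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(words, np.asarray(rows))

    def write_text(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf8") as fh:
            for w, vec in zip(self.words, self.vectors):
                fh.write(w + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")


#: Minimal English closed-class lexicon used when none is supplied. The
#: content/function decision for the synthetic vocabulary is made by the
#: generator itself; this set exists for real transcripts.
DEFAULT_FUNCTION_WORDS: frozenset[str] = frozenset(
    """a an the this that these those my your his her its our their
    i you he she it we they me him us them
    am is are was were be been being do does did have has had
    will would shall should can could may might must
    and or but nor so yet if then than because although while whereas
    of in on at by for with from to into onto over under between through
    about against during before after above below up down out off
    as not no nor none any some all both each every either neither
    there here when where why how what which who whom whose
    take""".split()
)


def flag_content_words(
    tokens: Iterable[WordToken],
    function_word_lexicon: Iterable[str] = DEFAULT_FUNCTION_WORDS,
) -> list[WordToken]:
    """Return tokens with ``is_content`` set from a function-word lexicon.

    A token is a content word iff its normalized form (lower-cased, surrounding
    punctuation stripped) is not in the lexicon. Empty normalized forms are
    flagged as function words.
    """
    lex = {normalize_word(w) for w in function_word_lexicon}
    out = []
    for tok in tokens:
        norm = normalize_word(tok.word)
        out.append(replace(tok, is_content=bool(norm) and norm not in lex))
    return out


_TRANSCRIPT_COLUMNS = ["word", "onset_s", "offset_s", "sentence_id", "is_content"]


def write_transcript_tsv(tokens: Sequence[WordToken], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (t.word, t.onset_s, t.offset_s, t.sentence_id, int(t.is_content))
            for t in tokens
        ],
        columns=_TRANSCRIPT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_transcript_tsv(path: str | Path) -> list[WordToken]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TRANSCRIPT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transcript TSV missing columns: {sorted(missing)}")
    return [
        WordToken(
            word=str(r.word),
            onset_s=float(r.onset_s),
            offset_s=float(r.offset_s),
            sentence_id=int(r.sentence_id),
            is_content=bool(r.is_content),
        )
        for r in df.itertuples(index=False)
    ]
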