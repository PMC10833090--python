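"""TF-IDF featurization over document sets, emitting a sparse document-term matrix.

The weighting follows the classic definition with the one-smoothed document
frequency: tf(w, d) = C(w, d) / |d| with |d| the token count of d, and
idf(w) = log(D / (1 + df(w))) with D the number of documents and df(w) the
number of documents containing w.  As printed, idf goes negative when a word
occurs in every document; it is clamped at 0 so weights stay non-negative.
Natural logarithm throughout.  No row normalization by default (an optional
L2 flag exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import Corpus, Document

__all__ = [
    "Vocabulary",
    "DocTermMatrix",
    "build_vocabulary",
    "term_frequency",
    "inverse_document_frequency",
    "tfidf_matrix",
    "save_matrix",
    "load_matrix",
]


@dataclass(frozen=True)
class Vocabulary:
    """Stable, lexicographically ordered word list with index lookup."""

    words: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.index:
            object.__setattr__(self, "index", {w: i for i, w in enumerate(self.words)})

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index


@dataclass
class DocTermMatrix:
    """Sparse TF-IDF (or count) matrix with document-id and vocabulary sidecars."""

    matrix: sp.csr_matrix
    row_ids: list[str]
    vocabulary: Vocabulary

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length does not match matrix rows")
        if self.matrix.shape[1] != len(self.vocabulary):
            raise ValueError("vocabulary size does not match matrix columns")
        if not np.all(np.isfinite(self.matrix.data)):
            raise ValueError("matrix contains non-finite values")


def build_vocabulary(corpus: Corpus, min_count: int = 1) -> Vocabulary:
    """Words with corpus frequency >= min_count, sorted lexicographically."""
    counts = corpus.vocabulary_counts()
    words = sorted(w for w, c in counts.items() if c >= min_count)
    if not words:
        raise ValueError("vocabulary is empty after frequency filtering")
    return Vocabulary(words=tuple(words))


def term_frequency(word: str, document: Document | Sequence[str]) -> float:
    """C(w, d) / |d| with |d| the token count (multiplicity included)."""
    tokens = document.tokens if isinstance(document, Document) else list(document)
    if len(tokens) == 0:
        raise ValueError("term frequency undefined for an empty document")
    return tokens.count(word) / len(tokens)


def inverse_document_frequency(
    word: str, documents: Sequence[Document | Sequence[str]], clamp: bool = True
) -> float:
    """log(D / (1 + df(w))), clamped at 0 when the word occurs in every document."""
    if len(documents) == 0:
        raise ValueError("idf undefined for an empty document set")
    df = 0
    for d in documents:
        tokens = d.tokens if isinstance(d, Document) else d
        if word in tokens:
            df += 1
    value = math.log(len(documents) / (1 + df))
    return max(value, 0.0) if clamp else value


def tfidf_matrix(
    documents: Sequence[Document],
    vocabulary: Vocabulary,
    l2_normalize: bool = False,
) -> DocTermMatrix:
    """Sparse tf x idf matrix over a document set for a fixed vocabulary.

    Documents with no in-vocabulary token are dropped with a warning (their
    tf row would be undefined).  Zero entries are not stored.
    """
    import warnings

    n_docs = len(documents)
    vocab_index = vocabulary.index

    kept_docs: list[Document] = []
    for d in documents:
        if any(t in vocab_index for t in d.tokens):
            kept_docs.append(d)
        else:
            warnings.warn(
                f"document {d.doc_id!r} has no in-vocabulary token; dropped",
                stacklevel=2,
            )

    # document frequency over the full (pre-drop) document set
    df = np.zeros(len(vocabulary), dtype=np.int64)
    for d in documents:
        for j in {vocab_index[t] for t in d.tokens if t in vocab_index}:
            df[j] += 1
    idf = np.log(n_docs / (1.0 + df))
    np.clip(idf, 0.0, None, out=idf)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i, d in enumerate(kept_docs):
        n_tok = len(d.tokens)
        counts: dict[int, int] = {}
        for t in d.tokens:
            j = vocab_index.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            w = (c / n_tok) * idf[j]
            if w != 0.0:
                rows.append(i)
                cols.append(j)
                vals.append(w)

    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(kept_docs), len(vocabulary)), dtype=np.float64
    )
    if l2_normalize:
        norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
        norms[norms == 0] = 1.0
        mat = sp.diags(1.0 / norms) @ mat
        mat = sp.csr_matrix(mat)
    return DocTermMatrix(
        matrix=mat, row_ids=[d.doc_id for d in kept_docs], vocabulary=vocabulary
    )


def save_matrix(dtm: DocTermMatrix, prefix: str | Path) -> None:
    """Write MatrixMarket .mtx plus vocabulary and doc-id sidecar text files."""
    prefix = Path(prefix)
    from scipy.io import mmwrite

    mmwrite(str(prefix.with_suffix(".mtx")), dtm.matrix)
    prefix.with_suffix(".vocab.txt").write_text(
        "\n".join(dtm.vocabulary.words) + "\n", encoding="utf-8"
    )
    prefix.with_suffix(".docs.txt").write_text(
        "\n".join(dtm.row_ids) + "\n", encoding="utf-8"
    )


def load_matrix(prefix: str | Path) -> DocTermMatrix:
    prefix = Path(prefix)
    from scipy.io import mmread

    mat = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    words = tuple(
        prefix.with_suffix(".vocab.txt").read_text(encoding="utf-8").splitlines()
    )
    row_ids = prefix.with_suffix(".docs.txt").read_text(encoding="utf-8").splitlines()
    return DocTermMatrix(matrix=mat, row_ids=row_ids, vocabulary=Vocabulary(words=words))
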