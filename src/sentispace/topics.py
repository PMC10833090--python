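"""Topic models for short texts: biterm topic model (BTM), LDA, perplexity,
topic-count selection, and embedding-based vocabulary reduction.

The BTM models the corpus-wide distribution of biterms — unordered word pairs
co-occurring in the same short document — instead of per-document mixtures,
which suits microblog comments of 5–30 tokens.  Inference is collapsed Gibbs
sampling; estimates are read off the final-iteration counts:

    theta_k   = (n_k + alpha) / (|B| + K*alpha)
    phi_{k,w} = (n_{w|k} + beta) / (2*n_k + M*beta)

LDA uses the standard collapsed sampler with symmetric priors alpha = 50/K
and beta = 0.01 and 1000 iterations by default.  The topic count is chosen by
minimum held-out perplexity, exp(-mean log p(w)).  A deterministic PPMI/SVD
embedding plus k-means supports representative-word vocabulary reduction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from . import _gibbs
from .corpus import Corpus
from .features import Vocabulary, build_vocabulary

__all__ = [
    "BtmState",
    "LdaState",
    "EmbeddingProvider",
    "PpmiSvdEmbedding",
    "WordClusterMap",
    "extract_biterms",
    "corpus_biterms",
    "fit_btm",
    "biterm_probability",
    "fit_lda",
    "infer_doc_topics_lda",
    "infer_doc_topics_btm",
    "perplexity",
    "select_k",
    "cluster_vocabulary",
    "reduce_corpus",
    "topic_weights_chisq",
]


@dataclass
class BtmState:
    """Fitted biterm topic model."""

    K: int
    theta: np.ndarray  # (K,) corpus-level topic distribution
    phi: np.ndarray  # (K, M) topic-word distributions
    vocabulary: Vocabulary
    biterms: np.ndarray  # (|B|, 2) word-index pairs
    assignments: np.ndarray  # (|B|,) topic index per biterm
    alpha: float
    beta: float
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        if abs(self.theta.sum() - 1.0) > 1e-9:
            raise ValueError("theta does not sum to 1")
        if np.abs(self.phi.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("phi rows do not sum to 1")


@dataclass
class LdaState:
    """Fitted LDA model (collapsed Gibbs, symmetric priors)."""

    K: int
    doc_topic: np.ndarray  # (n_docs, K)
    phi: np.ndarray  # (K, M)
    vocabulary: Vocabulary
    doc_ids: list[str]
    alpha: float
    beta: float
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        if np.abs(self.doc_topic.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("doc_topic rows do not sum to 1")
        if np.abs(self.phi.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("phi rows do not sum to 1")


def extract_biterms(tokens: Sequence[str], window: int | None = None) -> list[tuple[str, str]]:
    """All unordered token-position pairs of one document.

    With the short-text convention (``window=None``) every pair of positions
    contributes one biterm, so an n-token document yields n(n-1)/2 biterms;
    pairs of identical words are kept.  A window restricts pairs to positions
    at most ``window`` apart for longer texts.  Each pair is returned in
    sorted word order.
    """
    out: list[tuple[str, str]] = []
    n = len(tokens)
    for i in range(n):
        jmax = n if window is None else min(n, i + window + 1)
        for j in range(i + 1, jmax):
            a, b = tokens[i], tokens[j]
            out.append((a, b) if a <= b else (b, a))
    return out


def corpus_biterms(
    corpus: Corpus, vocabulary: Vocabulary, window: int | None = None
) -> tuple[np.ndarray, list[int]]:
    """Stack all in-vocabulary biterms; returns (pairs array, per-doc offsets).

    ``offsets[i]:offsets[i+1]`` slices document i's biterms.
    """
    idx = vocabulary.index
    pairs: list[tuple[int, int]] = []
    offsets = [0]
    for doc in corpus:
        toks = [t for t in doc.tokens if t in idx]
        for a, b in extract_biterms(toks, window):
            ia, ib = idx[a], idx[b]
            pairs.append((ia, ib) if ia <= ib else (ib, ia))
        offsets.append(len(pairs))
    arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return arr, offsets


def fit_btm(
    corpus: Corpus,
    K: int,
    alpha: float = 1.0,
    beta: float = 0.01,
    iterations: int = 500,
    seed: int = 0,
    vocabulary: Vocabulary | None = None,
    window: int | None = None,
) -> BtmState:
    """Fit a biterm topic model by collapsed Gibbs sampling.

    Reproducible bit-for-bit for a fixed seed.  ``alpha`` defaults to 1.0
    (a mild symmetric prior on the corpus topic distribution) and ``beta``
    to 0.01.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    vocab = vocabulary if vocabulary is not None else build_vocabulary(corpus)
    pairs, _ = corpus_biterms(corpus, vocab, window)
    if pairs.shape[0] == 0:
        raise ValueError("corpus contains no biterms (all documents < 2 tokens?)")
    M = len(vocab)
    z, n_k, n_wk = _gibbs.btm_gibbs(
        np.ascontiguousarray(pairs[:, 0]),
        np.ascontiguousarray(pairs[:, 1]),
        K,
        M,
        float(alpha),
        float(beta),
        int(iterations),
        _gibbs.seed_state(seed),
    )
    B = pairs.shape[0]
    theta = (n_k + alpha) / (B + K * alpha)
    phi = (n_wk.T + beta) / (2.0 * n_k[:, None] + M * beta)
    return BtmState(
        K=K,
        theta=theta,
        phi=phi,
        vocabulary=vocab,
        biterms=pairs,
        assignments=z,
        alpha=alpha,
        beta=beta,
        iterations=iterations,
        seed=seed,
    )


def biterm_probability(state: BtmState, biterm: tuple[str, str]) -> float:
    """p(b) = sum_k theta_k phi_{k,w1} phi_{k,w2}; symmetric in the pair."""
    idx = state.vocabulary.index
    try:
        i, j = idx[biterm[0]], idx[biterm[1]]
    except KeyError as exc:
        raise KeyError(f"word {exc.args[0]!r} not in model vocabulary") from None
    return float(np.sum(state.theta * state.phi[:, i] * state.phi[:, j]))


def fit_lda(
    corpus: Corpus,
    K: int,
    seed: int = 0,
    alpha: float | None = None,
    beta: float = 0.01,
    iterations: int = 1000,
    vocabulary: Vocabulary | None = None,
) -> LdaState:
    """Fit LDA by collapsed Gibbs with symmetric priors alpha=50/K, beta=0.01."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if alpha is None:
        alpha = 50.0 / K
    vocab = vocabulary if vocabulary is not None else build_vocabulary(corpus)
    idx = vocab.index

    doc_ids: list[int] = []
    words: list[int] = []
    kept: list[str] = []
    d = 0
    for doc in corpus:
        toks = [idx[t] for t in doc.tokens if t in idx]
        if not toks:
            continue
        doc_ids.extend([d] * len(toks))
        words.extend(toks)
        kept.append(doc.doc_id)
        d += 1
    if not words:
        raise ValueError("no in-vocabulary tokens")

    M = len(vocab)
    z, n_dk, n_wk, n_k = _gibbs.lda_gibbs(
        np.asarray(doc_ids, dtype=np.int64),
        np.asarray(words, dtype=np.int64),
        d,
        K,
        M,
        float(alpha),
        float(beta),
        int(iterations),
        _gibbs.seed_state(seed),
    )
    doc_topic = (n_dk + alpha) / (n_dk.sum(axis=1, keepdims=True) + K * alpha)
    phi = (n_wk.T + beta) / (n_k[:, None] + M * beta)
    return LdaState(
        K=K,
        doc_topic=doc_topic,
        phi=phi,
        vocabulary=vocab,
        doc_ids=kept,
        alpha=alpha,
        beta=beta,
        iterations=iterations,
        seed=seed,
    )


def infer_doc_topics_lda(
    state: LdaState, tokens: Sequence[str], n_iter: int = 50
) -> np.ndarray:
    """Fold in one unseen document: EM for its topic mixture with phi fixed."""
    idx = state.vocabulary.index
    wids = [idx[t] for t in tokens if t in idx]
    K = state.K
    theta = np.full(K, 1.0 / K)
    if not wids:
        return theta
    phi_w = state.phi[:, wids]  # (K, n)
    for _ in range(n_iter):
        r = phi_w * theta[:, None]  # (K, n)
        r /= r.sum(axis=0, keepdims=True)
        theta = (r.sum(axis=1) + state.alpha) / (len(wids) + K * state.alpha)
    return theta


def infer_doc_topics_btm(state: BtmState, tokens: Sequence[str]) -> np.ndarray:
    """p(k|doc) ∝ sum over the document's biterms of p(k|biterm).

    Documents with no in-vocabulary biterm fall back to the corpus-level
    topic distribution theta.
    """
    idx = state.vocabulary.index
    toks = [t for t in tokens if t in idx]
    pairs = extract_biterms(toks)
    if not pairs:
        return state.theta.copy()
    acc = np.zeros(state.K)
    for a, b in pairs:
        p = state.theta * state.phi[:, idx[a]] * state.phi[:, idx[b]]
        s = p.sum()
        if s > 0:
            acc += p / s
    if acc.sum() == 0:
        return state.theta.copy()
    return acc / acc.sum()


def perplexity(
    model: BtmState | LdaState, heldout: Corpus, method: str = "completion"
) -> float:
    """Held-out perplexity exp(-sum log p(w) / N) over in-vocabulary tokens.

    p(w) mixes the per-document topic weights with the topic-word
    distributions.  With ``method="completion"`` (the default) each held-out
    document is split in two: the topic mixture is inferred from the tokens
    at even positions and the log-likelihood is scored on the tokens at odd
    positions.  This document-completion scheme keeps the scored words out
    of the mixture inference; the naive alternative (``method="fold-in"``,
    mixture inferred from the whole document) lets larger topic counts fit
    the scored words themselves and biases topic-count selection upward.
    Out-of-vocabulary tokens are skipped; the fraction of tokens covered is
    available via :func:`vocabulary_coverage`.
    """
    if method not in {"completion", "fold-in"}:
        raise ValueError(f"unknown perplexity method {method!r}")
    idx = model.vocabulary.index
    total_logp = 0.0
    n_tokens = 0
    for doc in heldout:
        toks = [t for t in doc.tokens if t in idx]
        if not toks:
            continue
        if method == "completion":
            infer_toks = toks[0::2]
            eval_toks = toks[1::2]
        else:
            infer_toks = toks
            eval_toks = toks
        if not eval_toks:
            continue
        if isinstance(model, LdaState):
            theta_d = infer_doc_topics_lda(model, infer_toks)
        else:
            theta_d = infer_doc_topics_btm(model, infer_toks)
        wids = [idx[t] for t in eval_toks]
        p_w = theta_d @ model.phi[:, wids]  # (n,)
        total_logp += float(np.log(p_w).sum())
        n_tokens += len(wids)
    if n_tokens == 0:
        raise ValueError("held-out corpus has no in-vocabulary tokens to score")
    return math.exp(-total_logp / n_tokens)


def vocabulary_coverage(model: BtmState | LdaState, corpus: Corpus) -> float:
    """Fraction of corpus tokens covered by the model vocabulary."""
    idx = model.vocabulary.index
    n_in = n_all = 0
    for doc in corpus:
        n_all += len(doc.tokens)
        n_in += sum(1 for t in doc.tokens if t in idx)
    return n_in / n_all if n_all else 0.0


def select_k(
    corpus: Corpus,
    k_grid: Sequence[int],
    seed: int = 0,
    model: str = "lda",
    test_fraction: float = 0.25,
    **fit_kwargs,
) -> int:
    """Choose the topic count with minimum held-out perplexity.

    The corpus is split into train/test by a seeded shuffle; one model per
    candidate K is fitted on the training part and scored on the held-out
    part.  Ties resolve toward the smaller K.
    """
    if not k_grid:
        raise ValueError("k_grid is empty")
    docs = list(corpus.documents)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    n_test = max(1, int(round(test_fraction * len(docs))))
    test_idx = set(order[:n_test].tolist())
    train = Corpus([docs[i] for i in range(len(docs)) if i not in test_idx])
    test = Corpus([docs[i] for i in test_idx])

    best_k = None
    best_perp = math.inf
    for K in sorted(k_grid):
        if model == "lda":
            m = fit_lda(train, K, seed=seed, **fit_kwargs)
        elif model == "btm":
            m = fit_btm(train, K, seed=seed, **fit_kwargs)
        else:
            raise ValueError(f"unknown model {model!r}")
        perp = perplexity(m, test)
        if perp < best_perp:  # strict: ties keep the smaller K
            best_perp = perp
            best_k = K
    return best_k


class EmbeddingProvider(Protocol):
    """Deterministic word -> vector map of fixed dimension."""

    name: str
    dimension: int

    def embed(self, word: str) -> np.ndarray: ...


class PpmiSvdEmbedding:
    """Deterministic corpus-derived embedding: PPMI co-occurrence + truncated SVD.

    Co-occurrence is counted at the document level (suits short texts);
    positive pointwise mutual information is factorized with a dense SVD and
    each singular vector's sign is fixed so the largest-magnitude component
    is positive.  Requires no external assets.
    """

    def __init__(self, corpus: Corpus, vocabulary: Vocabulary, dimension: int = 50):
        self.name = "ppmi-svd"
        self.vocabulary = vocabulary
        idx = vocabulary.index
        M = len(vocabulary)
        cooc = np.zeros((M, M))
        for doc in corpus:
            wids = sorted({idx[t] for t in doc.tokens if t in idx})
            for i, j in itertools.combinations(wids, 2):
                cooc[i, j] += 1
                cooc[j, i] += 1
            for i in wids:
                cooc[i, i] += 1
        total = cooc.sum()
        if total == 0:
            raise ValueError("no co-occurrence mass; corpus/vocabulary mismatch")
        row = cooc.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            pmi = np.log((cooc * total) / (row * row.T))
        pmi[~np.isfinite(pmi)] = 0.0
        ppmi = np.clip(pmi, 0.0, None)
        u, s, _ = np.linalg.svd(ppmi, hermitian=True)
        dim = min(dimension, M)
        self.dimension = dim
        vecs = u[:, :dim] * np.sqrt(s[:dim])
        # deterministic sign: largest-|component| of each column positive
        for j in range(dim):
            col = vecs[:, j]
            if col[np.argmax(np.abs(col))] < 0:
                vecs[:, j] = -col
        self._vectors = vecs

    def embed(self, word: str) -> np.ndarray:
        return self._vectors[self.vocabulary.index[word]]


@dataclass
class WordClusterMap:
    """word -> representative-word substitution map from embedding clusters."""

    mapping: dict[str, str]
    n_clusters: int

    def __post_init__(self) -> None:
        reps = set(self.mapping.values())
        for r in reps:
            if self.mapping.get(r) != r:
                raise ValueError(f"representative {r!r} does not map to itself")

    @property
    def representatives(self) -> set[str]:
        return set(self.mapping.values())

    def __getitem__(self, word: str) -> str:
        return self.mapping[word]


def cluster_vocabulary(
    vocabulary: Vocabulary,
    provider: EmbeddingProvider,
    n_clusters: int,
    frequencies: dict[str, int],
    seed: int = 0,
) -> WordClusterMap:
    """k-means on word vectors; each cluster keeps its highest-frequency word.

    Every vocabulary word maps to its cluster's representative (ties broken
    lexicographically), so substituting through the map shrinks the
    vocabulary to at most ``n_clusters`` words.
    """
    from sklearn.cluster import KMeans

    words = list(vocabulary.words)
    if n_clusters > len(words):
        raise ValueError("n_clusters exceeds vocabulary size")
    X = np.vstack([provider.embed(w) for w in words])
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    mapping: dict[str, str] = {}
    for c in range(n_clusters):
        members = [w for w, l in zip(words, labels) if l == c]
        if not members:
            continue
        rep = min(members, key=lambda w: (-frequencies.get(w, 0), w))
        for w in members:
            mapping[w] = rep
    return WordClusterMap(mapping=mapping, n_clusters=n_clusters)


def reduce_corpus(corpus: Corpus, cluster_map: WordClusterMap) -> Corpus:
    """Replace every token by its cluster representative; counts preserved."""
    uncovered = sorted(
        {t for doc in corpus for t in doc.tokens if t not in cluster_map.mapping}
    )
    if uncovered:
        raise KeyError(f"tokens not covered by the cluster map: {uncovered[:10]}")
    out = corpus.copy()
    for doc in out:
        doc.tokens = [cluster_map.mapping[t] for t in doc.tokens]
    return out


def topic_weights_chisq(
    dominant_topics: Sequence[int], strata: Sequence[str], K: int | None = None
) -> np.ndarray:
    """Topic weights from a chi-square decomposition over time strata.

    Builds the topic x stratum (e.g. month) contingency table of
    dominant-topic counts; topic k's raw weight is its contribution
    sum_strata (O-E)^2 / E under independence, normalized to sum to 1.  A
    perfectly uniform table (all O == E) yields uniform weights.
    """
    if len(dominant_topics) != len(strata):
        raise ValueError("dominant_topics and strata must have equal length")
    topics = np.asarray(dominant_topics)
    if K is None:
        K = int(topics.max()) + 1
    labels = sorted(set(strata))
    table = np.zeros((K, len(labels)))
    col = {s: j for j, s in enumerate(labels)}
    for t, s in zip(topics, strata):
        table[t, col[s]] += 1
    row_tot = table.sum(axis=1, keepdims=True)
    col_tot = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row_tot * col_tot / total
    if np.any(expected == 0):
        raise ValueError(
            "zero expected cell in the topic/stratum table; use coarser strata"
        )
    contrib = ((table - expected) ** 2 / expected).sum(axis=1)
    if contrib.sum() < 1e-12:
        return np.full(K, 1.0 / K)
    return contrib / contrib.sum()


def save_model(state: BtmState | LdaState, prefix: str | Path) -> None:
    """Plain-text model files: header plus phi matrix and theta/doc-topic."""
    prefix = Path(prefix)
    kind = "btm" if isinstance(state, BtmState) else "lda"
    header = (
        f"kind={kind}\nK={state.K}\nalpha={state.alpha}\nbeta={state.beta}\n"
        f"iterations={state.iterations}\nseed={state.seed}\n"
    )
    prefix.with_suffix(".header.txt").write_text(header, encoding="utf-8")
    np.savetxt(prefix.with_suffix(".phi.txt"), state.phi)
    if isinstance(state, BtmState):
        np.savetxt(prefix.with_suffix(".theta.txt"), state.theta)
    else:
        np.savetxt(prefix.with_suffix(".doc_topic.txt"), state.doc_topic)
    prefix.with_suffix(".vocab.txt").write_text(
        "\n".join(state.vocabulary.words) + "\n", encoding="utf-8"
    )


def top_words(state: BtmState | LdaState, n: int = 10) -> list[list[str]]:
    """Per-topic top-n words by probability."""
    words = state.vocabulary.words
    out = []
    for k in range(state.K):
        order = np.argsort(-state.phi[k])[:n]
        out.append([words[j] for j in order])
    return out
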