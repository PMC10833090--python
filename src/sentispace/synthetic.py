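"""Synthetic microblog-corpus generator with known ground truth.

Emulates the structure of a crawled pandemic-era comment corpus: short
documents (5-30 tokens), a handful of latent topics, emotion-bearing words
injected at a per-stage rate whose negative share falls across the three
study stages (public mood moving from negative to positive), province-like
region labels whose negativity shares are smooth over an adjacency graph,
and dates spanning July 2020 - June 2021.  Token strings are synthetic
identifiers (w0001, eNI000, ...) so no language resources are needed; the
generator records everything it planted so pipeline estimates can be checked
against the truth.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .corpus import (
    Corpus,
    Document,
    LexiconEntry,
    MAIN_CATEGORIES,
    NEGATIVE_CATEGORIES,
    SentimentLexicon,
    default_taxonomy,
)
from .spatiotemporal import StagePartition, default_stage_partition

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "make_lexicon",
    "make_corpus",
    "make_adjacency",
    "expected_negative_fraction",
]

_DEFAULT_REGIONS = tuple(f"R{i:02d}" for i in range(1, 9))


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the emulated study: 2000 screened comments of 5-30
    tokens, a three-stage window from July 2020 to June 2021, emotion words
    injected at rate 0.3 with per-stage negative shares (0.8, 0.5, 0.2)
    tracing the negative-to-positive mood trend, and 8 regions on a chain
    with smooth regional negativity shifts.
    """

    seed: int = 0
    n_documents: int = 2000
    doc_length_range: tuple[int, int] = (5, 30)
    K_true: int = 12
    vocab_size: int = 600
    topic_concentration: float = 0.05
    disjoint_topics: bool = False
    emotion_word_rate: tuple[float, ...] = (0.3, 0.3, 0.3)
    stage_negativity: tuple[float, ...] = (0.8, 0.5, 0.2)
    regions: tuple[str, ...] = _DEFAULT_REGIONS
    region_topology: str = "chain"
    region_effect_scale: float = 0.1
    words_per_subcategory: int = 3
    partition: StagePartition = field(default_factory=default_stage_partition)

    def __post_init__(self) -> None:
        if self.doc_length_range[0] < 2:
            raise ValueError("minimum document length must be >= 2 (biterms)")
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        n_stages = len(self.partition.stages)
        if len(self.emotion_word_rate) != n_stages or len(self.stage_negativity) != n_stages:
            raise ValueError("per-stage parameter lengths must match the partition")
        for p in (*self.emotion_word_rate, *self.stage_negativity):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, token-consistent with the corpus."""

    topic_word: np.ndarray  # (K_true, vocab_size)
    doc_topic: list[int]
    doc_injections: list[list[tuple[int, str, str]]]  # (position, word, category)
    polarity_labels: list[int]
    region_effects: dict[str, float]
    region_stage_negativity: dict[tuple[str, str], float]

    def save_jsonl(self, path: str | Path, corpus: Corpus) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, doc in enumerate(corpus):
                rec = {
                    "doc_id": doc.doc_id,
                    "topic": self.doc_topic[i],
                    "polarity_label": self.polarity_labels[i],
                    "injections": [
                        {"position": p, "word": w, "category": c}
                        for p, w, c in self.doc_injections[i]
                    ],
                }
                fh.write(json.dumps(rec) + "\n")


def make_lexicon(seed: int = 0, words_per_subcategory: int = 3) -> SentimentLexicon:
    """Synthetic lexicon covering all 21 subcategories.

    Word identifiers encode their subcategory (e.g. eNI000); intensities are
    sampled from the canonical grid {1,3,5,7,9} and polarity follows the
    category's sign, so every entry passes the lexicon validator.
    """
    if words_per_subcategory < 1:
        raise ValueError("words_per_subcategory must be >= 1")
    rng = np.random.default_rng(seed)
    tax = default_taxonomy()
    lex = SentimentLexicon(taxonomy=tax)
    pos_tags = ("adj", "noun", "verb")
    for sub in sorted(tax.subcategory_map):
        category = tax.subcategory_map[sub]
        polarity = tax.category_polarity(category)
        for i in range(words_per_subcategory):
            lex.add(
                LexiconEntry(
                    word=f"e{sub}{i:03d}",
                    pos=pos_tags[int(rng.integers(len(pos_tags)))],
                    sense_count=1,
                    subcategory=sub,
                    intensity=int(rng.choice([1, 3, 5, 7, 9])),
                    polarity=polarity,
                )
            )
    return lex


def make_adjacency(regions: tuple[str, ...] | list[str], topology: str = "chain",
                   pairs: list[tuple[str, str]] | None = None) -> nx.Graph:
    """Undirected connected region graph: chain, near-square grid, or custom."""
    regions = list(regions)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    g = nx.Graph()
    g.add_nodes_from(regions)
    if topology == "chain":
        g.add_edges_from(zip(regions, regions[1:]))
    elif topology == "grid":
        n = len(regions)
        ncol = int(math.ceil(math.sqrt(n)))
        for i in range(n):
            r, c = divmod(i, ncol)
            if c + 1 < ncol and i + 1 < n:
                g.add_edge(regions[i], regions[i + 1])
            if i + ncol < n:
                g.add_edge(regions[i], regions[i + ncol])
    elif topology == "custom":
        if not pairs:
            raise ValueError("custom topology requires pairs")
        for a, b in pairs:
            if a not in g or b not in g:
                raise ValueError(f"pair ({a!r}, {b!r}) references unknown region")
            g.add_edge(a, b)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    if not nx.is_connected(g):
        raise ValueError("region graph is not connected")
    return g


def _smooth_region_effects(
    regions: list[str], graph: nx.Graph, scale: float, rng: np.random.Generator
) -> dict[str, float]:
    # iid noise smoothed twice over the graph -> positive spatial autocorrelation
    x = {r: rng.normal(0.0, scale) for r in regions}
    for _ in range(2):
        x = {
            r: float(np.mean([x[r]] + [x[nb] for nb in graph.neighbors(r)]))
            for r in regions
        }
    return x


_NEG_CATS = tuple(sorted(NEGATIVE_CATEGORIES, key=MAIN_CATEGORIES.index))
_POS_CATS = tuple(c for c in MAIN_CATEGORIES if c not in NEGATIVE_CATEGORIES)


def make_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus its ground truth, fully reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    K = config.K_true
    V = config.vocab_size
    vocab = [f"w{i:04d}" for i in range(V)]

    if config.disjoint_topics:
        topic_word = np.zeros((K, V))
        bounds = np.linspace(0, V, K + 1).astype(int)
        for k in range(K):
            topic_word[k, bounds[k] : bounds[k + 1]] = 1.0 / (bounds[k + 1] - bounds[k])
    else:
        topic_word = rng.dirichlet([config.topic_concentration] * V, size=K)

    lexicon = make_lexicon(seed=config.seed, words_per_subcategory=config.words_per_subcategory)
    cat_words: dict[str, list[str]] = {c: [] for c in MAIN_CATEGORIES}
    tax = lexicon.taxonomy
    for entry in lexicon.entries():
        cat_words[tax.main_category_of(entry.subcategory)].append(entry.word)
    for c in cat_words:
        cat_words[c].sort()

    graph = make_adjacency(config.regions, config.region_topology)
    region_effects = _smooth_region_effects(
        list(config.regions), graph, config.region_effect_scale, rng
    )
    stages = config.partition.stages
    region_stage_q = {
        (r, s.name): float(np.clip(config.stage_negativity[si] + region_effects[r], 0, 1))
        for r in config.regions
        for si, s in enumerate(stages)
    }

    docs: list[Document] = []
    doc_topic: list[int] = []
    doc_injections: list[list[tuple[int, str, str]]] = []
    polarity_labels: list[int] = []

    lo, hi = config.doc_length_range
    for i in range(config.n_documents):
        si = int(rng.integers(len(stages)))
        stage = stages[si]
        span = (stage.end - stage.start).days
        date = stage.start + _dt.timedelta(days=int(rng.integers(span + 1)))
        region = str(config.regions[int(rng.integers(len(config.regions)))])
        topic = int(rng.integers(K))
        L = int(rng.integers(lo, hi + 1))
        tokens = [vocab[j] for j in rng.choice(V, size=L, p=topic_word[topic])]

        q = region_stage_q[(region, stage.name)]
        injections: list[tuple[int, str, str]] = []
        n_neg = n_pos = 0
        for pos in range(L):
            if rng.random() >= config.emotion_word_rate[si]:
                continue
            if rng.random() < q:
                cat = _NEG_CATS[int(rng.integers(len(_NEG_CATS)))]
                n_neg += 1
            else:
                cat = _POS_CATS[int(rng.integers(len(_POS_CATS)))]
                n_pos += 1
            word = cat_words[cat][int(rng.integers(len(cat_words[cat])))]
            tokens[pos] = word
            injections.append((pos, word, cat))

        label = 0 if n_neg > n_pos else 1
        counts: dict[str, int] = {}
        for _, _, c in injections:
            counts[c] = counts.get(c, 0) + 1
        emotion = (
            max(counts, key=lambda c: (counts[c], -MAIN_CATEGORIES.index(c)))
            if counts
            else None
        )
        docs.append(
            Document(
                doc_id=f"d{i:06d}",
                text=" ".join(tokens),
                tokens=tokens,
                date=date,
                region=region,
                polarity_label=label,
                emotion_label=emotion,
            )
        )
        doc_topic.append(topic)
        doc_injections.append(injections)
        polarity_labels.append(label)

    corpus = Corpus(
        documents=docs,
        metadata={"generator_seed": config.seed, "n_documents": config.n_documents},
    )
    truth = GroundTruth(
        topic_word=topic_word,
        doc_topic=doc_topic,
        doc_injections=doc_injections,
        polarity_labels=polarity_labels,
        region_effects=region_effects,
        region_stage_negativity=region_stage_q,
    )
    return corpus, truth


def expected_negative_fraction(
    config: GeneratorConfig, truth: GroundTruth, stage_index: int
) -> float:
    """Closed-form P(polarity label = 0) for documents of one stage.

    A document of length L gets m ~ Binomial(L, rate) injected emotion words,
    each negative with the region's realized probability q; the label is 0
    iff negatives strictly outnumber positives, i.e. X > m/2 with
    X ~ Binomial(m, q).  Averaged over the uniform length and region draws.
    """
    from scipy.stats import binom

    rate = config.emotion_word_rate[stage_index]
    stage_name = config.partition.stages[stage_index].name
    lo, hi = config.doc_length_range
    lengths = range(lo, hi + 1)
    p_len = 1.0 / len(lengths)
    p_region = 1.0 / len(config.regions)

    total = 0.0
    for region in config.regions:
        q = truth.region_stage_negativity[(region, stage_name)]
        for L in lengths:
            for m in range(1, L + 1):
                p_m = binom.pmf(m, L, rate)
                # P(X > m/2) = P(X >= floor(m/2) + 1)
                p_neg_majority = binom.sf(m // 2, m, q)
                total += p_region * p_len * p_m * p_neg_majority
    return total
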