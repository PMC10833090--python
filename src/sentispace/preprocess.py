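"""Text cleaning ladder: clean -> deduplicate -> tokenize -> stop words -> low-frequency filter.

Each step is a pure function Corpus -> Corpus; the full ladder is idempotent
and never increases the number of documents or tokens.  Tokenization is
pluggable through a registry so the pipeline is language independent: the
default tokenizer splits on whitespace and strips edge punctuation, and a
CJK segmenter (jieba) can be registered when available.  A depth-1 decision
tree imputes missing categorical columns (e.g. region) from the complete
records.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .corpus import Corpus, Document

__all__ = [
    "PreprocessConfig",
    "Tokenizer",
    "register_tokenizer",
    "get_tokenizer",
    "clean_text",
    "deduplicate",
    "tokenize_corpus",
    "remove_stopwords",
    "filter_low_frequency",
    "impute_missing",
    "load_stopwords",
    "load_user_dictionary",
    "run_pipeline",
]


@dataclass
class Tokenizer:
    """A named, deterministic segmentation function."""

    name: str
    segment: Callable[[str], list[str]]


_TOKENIZERS: dict[str, Tokenizer] = {}


def register_tokenizer(tokenizer: Tokenizer) -> None:
    _TOKENIZERS[tokenizer.name] = tokenizer


def get_tokenizer(name: str) -> Tokenizer:
    try:
        return _TOKENIZERS[name]
    except KeyError:
        raise KeyError(
            f"no tokenizer registered under {name!r}; known: {sorted(_TOKENIZERS)}"
        ) from None


_EDGE_PUNCT = re.compile(r"^[^\w一-鿿]+|[^\w一-鿿]+$")


def _whitespace_segment(text: str) -> list[str]:
    toks = []
    for raw in text.split():
        tok = _EDGE_PUNCT.sub("", raw)
        if tok:
            toks.append(tok)
    return toks


register_tokenizer(Tokenizer(name="whitespace", segment=_whitespace_segment))


def _jieba_segment(text: str) -> list[str]:
    import jieba  # optional CJK segmenter, registered lazily

    return [t for t in jieba.lcut(text) if t.strip()]


register_tokenizer(Tokenizer(name="jieba", segment=_jieba_segment))


@dataclass
class PreprocessConfig:
    stopword_path: str | Path | None = None
    user_dictionary_path: str | Path | None = None
    min_token_count: int = 1
    strip_html: bool = True
    tokenizer_name: str = "whitespace"

    def __post_init__(self) -> None:
        if self.min_token_count < 0:
            raise ValueError("min_token_count must be >= 0")
        get_tokenizer(self.tokenizer_name)  # fail fast on unknown name


_TAG_RE = re.compile(r"<[^>]*>")
_URL_RE = re.compile(r"https?://\S+|www\.\S+")
# keep letters, digits, CJK, whitespace and basic punctuation
_ALLOWED_RE = re.compile(r"[^\w\s一-鿿.,;:!?'\"()\[\]%-]")
_WS_RE = re.compile(r"\s+")
_PRE_PUNCT_RE = re.compile(r"\s+([.,;:!?%)\]])")


def clean_text(text: str, config: PreprocessConfig | None = None) -> str:
    """Strip HTML/XML tags, URLs and characters outside the allowed set.

    Total and idempotent: clean(clean(x)) == clean(x).
    """
    strip_html = config.strip_html if config is not None else True
    s = text
    if strip_html:
        s = _TAG_RE.sub(" ", s)
    s = _URL_RE.sub(" ", s)
    s = _ALLOWED_RE.sub("", s)
    s = _WS_RE.sub(" ", s).strip()
    # tag/URL removal can leave a stray space before trailing punctuation
    s = _PRE_PUNCT_RE.sub(r"\1", s)
    return s


def clean_corpus(corpus: Corpus, config: PreprocessConfig | None = None) -> Corpus:
    out = corpus.copy()
    for doc in out:
        doc.text = clean_text(doc.text, config)
    return out


def deduplicate(corpus: Corpus) -> Corpus:
    """Keep the first occurrence of each exact text string, preserving order."""
    out = corpus.copy()
    seen: set[str] = set()
    docs: list[Document] = []
    for doc in out:
        if doc.text in seen:
            continue
        seen.add(doc.text)
        docs.append(doc)
    out.documents = docs
    return out


def _protect_terms(text: str, terms: Sequence[str]) -> str:
    # multi-token user-dictionary terms are joined with underscores so the
    # default tokenizer keeps them whole
    for term in sorted(terms, key=len, reverse=True):
        if " " in term and term in text:
            text = text.replace(term, term.replace(" ", "_"))
    return text


def tokenize_corpus(
    corpus: Corpus,
    tokenizer: Tokenizer | str = "whitespace",
    user_dictionary: Sequence[str] | None = None,
) -> Corpus:
    """Populate each document's tokens; user-dictionary terms are never split."""
    tok = get_tokenizer(tokenizer) if isinstance(tokenizer, str) else tokenizer
    out = corpus.copy()
    for doc in out:
        text = doc.text
        if user_dictionary:
            text = _protect_terms(text, user_dictionary)
        doc.tokens = tok.segment(text)
    return out


def remove_stopwords(corpus: Corpus, stoplist: Iterable[str]) -> Corpus:
    stopset = set(stoplist)
    out = corpus.copy()
    for doc in out:
        doc.tokens = [t for t in doc.tokens if t not in stopset]
    return out


def filter_low_frequency(corpus: Corpus, min_count: int) -> Corpus:
    """Drop token types whose corpus-wide frequency is below ``min_count``."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = corpus.vocabulary_counts()
    keep = {w for w, c in counts.items() if c >= min_count}
    out = corpus.copy()
    for doc in out:
        doc.tokens = [t for t in doc.tokens if t in keep]
    return out


def load_stopwords(path: str | Path) -> set[str]:
    """UTF-8 plain text, one token per line; '#' comment lines ignored."""
    stops: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                stops.add(line)
    return stops


def load_user_dictionary(path: str | Path) -> list[str]:
    """UTF-8 plain text, one (possibly multi-token) term per line."""
    terms: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                terms.append(line)
    return terms


def _entropy(counter: Counter) -> float:
    total = sum(counter.values())
    h = 0.0
    for c in counter.values():
        p = c / total
        h -= p * math.log(p)
    return h


def impute_missing(corpus: Corpus, column: str = "region") -> Corpus:
    """Fill missing values of one categorical column with a depth-1 decision rule.

    Learns from records where the target column is present.  Candidate
    predictors are the other document attributes (date, region, labels); the
    single split with the highest information gain wins.  Dates are treated
    as a thresholded numeric predictor (best midpoint between consecutive
    distinct dates).  Within a stratum the majority target value is imputed,
    falling back to the global mode.  Imputed doc_ids are recorded under
    ``metadata["imputed_<column>"]``.
    """
    if column not in {"region", "date", "polarity_label", "emotion_label"}:
        raise ValueError(f"cannot impute column {column!r}")

    def get(doc: Document, col: str):
        return getattr(doc, col)

    complete = [d for d in corpus if get(d, column) is not None]
    missing = [d for d in corpus if get(d, column) is None]
    if not complete:
        raise ValueError(f"column {column!r} has no observed values to learn from")
    if not missing:
        return corpus.copy()

    target = [get(d, column) for d in complete]
    base_entropy = _entropy(Counter(target))
    global_mode = Counter(target).most_common(1)[0][0]

    candidates = [
        c for c in ("date", "region", "polarity_label", "emotion_label") if c != column
    ]

    best_gain = -1.0
    best_rule: Callable[[Document], object] | None = None
    for pred in candidates:
        vals = [get(d, pred) for d in complete]
        if all(v is None for v in vals):
            continue
        if pred == "date":
            dated = sorted({v for v in vals if v is not None})
            if len(dated) < 2:
                continue
            for a, b in zip(dated, dated[1:]):
                thr = a + (b - a) / 2
                left = Counter(t for d, t in zip(complete, target) if get(d, "date") and get(d, "date") <= thr)
                right = Counter(t for d, t in zip(complete, target) if get(d, "date") and get(d, "date") > thr)
                n = sum(left.values()) + sum(right.values())
                if not left or not right:
                    continue
                cond = (
                    sum(left.values()) / n * _entropy(left)
                    + sum(right.values()) / n * _entropy(right)
                )
                gain = base_entropy - cond
                if gain > best_gain:
                    best_gain = gain
                    left_mode = left.most_common(1)[0][0]
                    right_mode = right.most_common(1)[0][0]
                    best_rule = (
                        lambda d, thr=thr, lm=left_mode, rm=right_mode: (
                            lm if (d.date is not None and d.date <= thr) else rm
                        )
                        if d.date is not None
                        else None
                    )
        else:
            strata: dict[object, Counter] = {}
            for d, t in zip(complete, target):
                v = get(d, pred)
                if v is None:
                    continue
                strata.setdefault(v, Counter())[t] += 1
            n = sum(sum(c.values()) for c in strata.values())
            if n == 0 or len(strata) < 2:
                continue
            cond = sum(sum(c.values()) / n * _entropy(c) for c in strata.values())
            gain = base_entropy - cond
            if gain > best_gain:
                best_gain = gain
                modes = {v: c.most_common(1)[0][0] for v, c in strata.items()}
                best_rule = lambda d, pred=pred, modes=modes: modes.get(get(d, pred))

    out = corpus.copy()
    imputed: list[str] = []
    for doc in out:
        if get(doc, column) is None:
            value = best_rule(doc) if best_rule is not None else None
            if value is None:
                value = global_mode
            setattr(doc, column, value)
            imputed.append(doc.doc_id)
    out.metadata[f"imputed_{column}"] = imputed
    return out


def run_pipeline(
    corpus: Corpus,
    config: PreprocessConfig,
    stoplist: Iterable[str] | None = None,
    user_dictionary: Sequence[str] | None = None,
) -> Corpus:
    """The full cleaning ladder in the canonical order."""
    if stoplist is None:
        stoplist = load_stopwords(config.stopword_path) if config.stopword_path else set()
    if user_dictionary is None and config.user_dictionary_path:
        user_dictionary = load_user_dictionary(config.user_dictionary_path)
    c = clean_corpus(corpus, config)
    c = deduplicate(c)
    c = tokenize_corpus(c, config.tokenizer_name, user_dictionary)
    c = remove_stopwords(c, stoplist)
    c = filter_low_frequency(c, config.min_token_count)
    return c
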