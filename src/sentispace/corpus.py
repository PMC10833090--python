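"""Data model and I/O for documents, corpora, the sentiment lexicon and the emotion taxonomy.

The corpus container is deliberately lightweight: a :class:`Document` is a short
social-media comment with an optional calendar date, a region label (an opaque
string such as a province name) and optional polarity / emotion annotations.
The lexicon follows the layout of the Dalian University of Technology emotion
ontology: each word carries a part of speech, a sense count, one of 21 emotion
subcategories (grouped into 7 main categories), an intensity level and a signed
polarity.  Word sentiment is the product intensity x polarity, so negative
categories must carry polarity -1 for the product to come out negative.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "Document",
    "Corpus",
    "LexiconEntry",
    "SentimentLexicon",
    "EmotionTaxonomy",
    "CorpusSchemaError",
    "CorpusIntegrityError",
    "LexiconValidationError",
    "default_taxonomy",
    "read_corpus",
    "write_corpus",
    "partition_by_day",
    "load_lexicon",
    "main_category_of",
    "NEGATIVE_CATEGORIES",
    "POSITIVE_CATEGORIES",
    "MAIN_CATEGORIES",
]


class CorpusSchemaError(ValueError):
    """A required column or key is missing from a corpus file."""


class CorpusIntegrityError(ValueError):
    """Corpus-level invariant violated (duplicate ids, bad dates, ...)."""


class LexiconValidationError(ValueError):
    """A lexicon row violates the entry invariants."""


# The 7 main emotion categories.  Order matters: it is the fixed tie-break
# order used when choosing a dominant category (negatives first).
MAIN_CATEGORIES: tuple[str, ...] = (
    "anger",
    "disgust",
    "fear",
    "sadness",
    "surprise",
    "good",
    "happy",
)

NEGATIVE_CATEGORIES: frozenset[str] = frozenset({"anger", "disgust", "fear", "sadness"})
POSITIVE_CATEGORIES: frozenset[str] = frozenset({"surprise", "good", "happy"})

# 21 subcategory codes of the Dalian-style emotion ontology, grouped under the
# 7 main categories.
_SUBCATEGORY_MAP: dict[str, str] = {
    # happy
    "PA": "happy",  # happiness
    "PE": "happy",  # peace of mind
    # good
    "PD": "good",  # respect
    "PH": "good",  # praise
    "PG": "good",  # belief
    "PB": "good",  # love
    "PK": "good",  # wish
    # surprise
    "PC": "surprise",
    # anger
    "NAU": "anger",
    # sadness
    "NB": "sadness",  # grief
    "NJ": "sadness",  # disappointment
    "NH": "sadness",  # guilt
    "PF": "sadness",  # yearning
    # fear
    "NI": "fear",  # panic
    "NC": "fear",  # fright
    "NG": "fear",  # shame
    # disgust
    "ND": "disgust",  # annoyance
    "NE": "disgust",  # hate
    "NN": "disgust",  # criticism
    "NK": "disgust",  # jealousy
    "NL": "disgust",  # suspicion
}


@dataclass
class Document:
    """One short text with optional date, region and sentiment annotations.

    ``polarity_label`` uses 0 = negative, 1 = positive.  ``emotion_label`` is
    one of the 7 main categories.  ``tokens`` stays empty until preprocessing.
    """

    doc_id: str
    text: str
    tokens: list[str] = field(default_factory=list)
    date: _dt.date | None = None
    region: str | None = None
    polarity_label: int | None = None
    emotion_label: str | None = None

    def __post_init__(self) -> None:
        for tok in self.tokens:
            if not tok or any(ch.isspace() for ch in tok):
                raise ValueError(
                    f"document {self.doc_id!r}: token {tok!r} is empty or contains whitespace"
                )


@dataclass
class Corpus:
    """Ordered collection of documents plus free-form metadata."""

    documents: list[Document] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusIntegrityError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    def copy(self) -> "Corpus":
        docs = [
            Document(
                doc_id=d.doc_id,
                text=d.text,
                tokens=list(d.tokens),
                date=d.date,
                region=d.region,
                polarity_label=d.polarity_label,
                emotion_label=d.emotion_label,
            )
            for d in self.documents
        ]
        return Corpus(documents=docs, metadata=dict(self.metadata))

    def vocabulary_counts(self) -> dict[str, int]:
        """Corpus-wide token frequency table."""
        counts: dict[str, int] = {}
        for doc in self.documents:
            for tok in doc.tokens:
                counts[tok] = counts.get(tok, 0) + 1
        return counts


@dataclass(frozen=True)
class EmotionTaxonomy:
    """7 main emotion categories, 21 subcategory codes, and category polarity."""

    main_categories: tuple[str, ...] = MAIN_CATEGORIES
    subcategory_map: Mapping[str, str] = field(
        default_factory=lambda: dict(_SUBCATEGORY_MAP)
    )
    polarity_map: Mapping[str, int] = field(
        default_factory=lambda: {
            c: (-1 if c in NEGATIVE_CATEGORIES else +1) for c in MAIN_CATEGORIES
        }
    )

    def __post_init__(self) -> None:
        if len(self.main_categories) != 7:
            raise ValueError("taxonomy must have exactly 7 main categories")
        mains = set(self.subcategory_map.values())
        if not mains <= set(self.main_categories):
            raise ValueError(f"subcategories map to unknown categories: {mains}")

    def main_category_of(self, subcategory: str) -> str:
        try:
            return self.subcategory_map[subcategory]
        except KeyError:
            raise KeyError(f"unknown emotion subcategory code {subcategory!r}") from None

    def category_polarity(self, category: str) -> int:
        return self.polarity_map[category]


def default_taxonomy() -> EmotionTaxonomy:
    """The built-in 7-category / 21-subcategory taxonomy."""
    return EmotionTaxonomy()


@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon row: word, POS, sense count, subcategory, intensity, polarity."""

    word: str
    pos: str
    sense_count: int
    subcategory: str
    intensity: int
    polarity: int
    auxiliary_subcategory: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.intensity <= 9):
            raise LexiconValidationError(
                f"word {self.word!r}: intensity {self.intensity} outside 1..9"
            )
        if self.polarity not in (-1, +1):
            raise LexiconValidationError(
                f"word {self.word!r}: polarity {self.polarity} not in {{-1,+1}}"
            )
        if self.sense_count < 1:
            raise LexiconValidationError(
                f"word {self.word!r}: sense_count must be positive"
            )


# canonical 5-level intensity grid of the ontology
CANONICAL_INTENSITY_LEVELS: tuple[int, ...] = (1, 3, 5, 7, 9)


class SentimentLexicon:
    """Word -> entries mapping with a taxonomy.

    A word may carry several entries (multiple senses).  ``lookup`` raises
    ``KeyError`` for absent words rather than returning a default; use
    ``get`` for optional access.
    """

    def __init__(
        self,
        entries: Iterable[LexiconEntry] = (),
        taxonomy: EmotionTaxonomy | None = None,
    ) -> None:
        self.taxonomy = taxonomy if taxonomy is not None else default_taxonomy()
        self._entries: dict[str, list[LexiconEntry]] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: LexiconEntry) -> None:
        if entry.subcategory not in self.taxonomy.subcategory_map:
            raise LexiconValidationError(
                f"word {entry.word!r}: unknown subcategory {entry.subcategory!r}"
            )
        self._entries.setdefault(entry.word, []).append(entry)

    def lookup(self, word: str) -> list[LexiconEntry]:
        return self._entries[word]

    def get(self, word: str) -> list[LexiconEntry] | None:
        return self._entries.get(word)

    def __contains__(self, word: str) -> bool:
        return word in self._entries

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())

    @property
    def words(self) -> list[str]:
        return list(self._entries)

    def entries(self) -> Iterator[LexiconEntry]:
        for lst in self._entries.values():
            yield from lst


_CORPUS_COLUMNS = ("doc_id", "text", "date", "region", "polarity_label", "emotion_label")


def _parse_date(value, doc_id: str) -> _dt.date | None:
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"nan", "none"}:
        return None
    try:
        return _dt.date.fromisoformat(s)
    except ValueError:
        raise CorpusIntegrityError(
            f"doc_id {doc_id!r}: unparseable date {s!r} (expected YYYY-MM-DD)"
        ) from None


def _opt_str(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    s = str(value)
    return s if s and s.lower() != "nan" else None


def _opt_int(value) -> int | None:
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    return int(float(s))


def _record_to_document(rec: Mapping) -> Document:
    doc_id = str(rec["doc_id"])
    return Document(
        doc_id=doc_id,
        text=str(rec["text"]) if not (isinstance(rec["text"], float) and pd.isna(rec["text"])) else "",
        tokens=list(rec.get("tokens") or []),
        date=_parse_date(rec.get("date"), doc_id),
        region=_opt_str(rec.get("region")),
        polarity_label=_opt_int(rec.get("polarity_label")),
        emotion_label=_opt_str(rec.get("emotion_label")),
    )


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from CSV or JSONL.

    Required columns/keys: ``doc_id`` and ``text``.  Optional: ``date``
    (ISO-8601), ``region``, ``polarity_label`` (0/1), ``emotion_label``.
    Records are read in file order; tokens stay empty unless the file carries
    a ``tokens`` key (JSONL only).
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    if format not in {"csv", "jsonl"}:
        raise ValueError(f"unknown corpus format {format!r}")

    records: list[Mapping]
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("doc_id", "text"):
            if col not in df.columns:
                raise CorpusSchemaError(f"missing required column {col!r}")
        records = df.to_dict(orient="records")
    else:
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                for key in ("doc_id", "text"):
                    if key not in rec:
                        raise CorpusSchemaError(
                            f"line {lineno}: missing required key {key!r}"
                        )
                records.append(rec)

    docs = [_record_to_document(rec) for rec in records]
    return Corpus(documents=docs, metadata={"source": str(path)})


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus to CSV or JSONL (inverse of :func:`read_corpus`)."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    if format == "csv":
        rows = []
        for d in corpus:
            rows.append(
                {
                    "doc_id": d.doc_id,
                    "text": d.text,
                    "date": d.date.isoformat() if d.date else "",
                    "region": d.region or "",
                    "polarity_label": "" if d.polarity_label is None else str(d.polarity_label),
                    "emotion_label": d.emotion_label or "",
                }
            )
        pd.DataFrame(rows, columns=list(_CORPUS_COLUMNS)).to_csv(path, index=False)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for d in corpus:
                rec: dict = {"doc_id": d.doc_id, "text": d.text}
                if d.tokens:
                    rec["tokens"] = d.tokens
                if d.date:
                    rec["date"] = d.date.isoformat()
                if d.region is not None:
                    rec["region"] = d.region
                if d.polarity_label is not None:
                    rec["polarity_label"] = d.polarity_label
                if d.emotion_label is not None:
                    rec["emotion_label"] = d.emotion_label
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def partition_by_day(corpus: Corpus) -> dict[_dt.date, list[Document]]:
    """Partition a corpus into per-day document sets, days ascending.

    Every document must carry a date; each appears in exactly one day-set.
    """
    undated = [d.doc_id for d in corpus if d.date is None]
    if undated:
        raise CorpusIntegrityError(f"documents without a date: {undated}")
    days: dict[_dt.date, list[Document]] = {}
    for doc in corpus:
        days.setdefault(doc.date, []).append(doc)
    return dict(sorted(days.items()))


_LEXICON_COLUMNS = ("word", "pos", "sense_count", "subcategory", "intensity", "polarity", "auxiliary")


def load_lexicon(
    path: str | Path, taxonomy: EmotionTaxonomy | None = None
) -> SentimentLexicon:
    """Load a sentiment lexicon from a tab- or comma-separated table.

    Expected columns: word, pos, sense_count, subcategory, intensity,
    polarity, auxiliary.  Polarity may be coded signed (-1/+1) or as 0/1
    (0 = negative), which is mapped to the signed form on input.  Intensity
    must be an integer in 1..9; values off the canonical 5-level grid
    {1,3,5,7,9} are accepted with a warning.  Invalid rows raise with their
    row number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _LEXICON_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise CorpusSchemaError(f"lexicon missing columns: {missing}")

    lex = SentimentLexicon(taxonomy=taxonomy)
    for rownum, rec in enumerate(df.to_dict(orient="records"), start=2):
        try:
            intensity = int(rec["intensity"])
            polarity = int(rec["polarity"])
            if polarity == 0:  # 0/1 coding on input
                polarity = -1
            if intensity not in CANONICAL_INTENSITY_LEVELS and 1 <= intensity <= 9:
                warnings.warn(
                    f"lexicon row {rownum}: intensity {intensity} off the canonical "
                    f"5-level grid {CANONICAL_INTENSITY_LEVELS}",
                    stacklevel=2,
                )
            aux = rec.get("auxiliary", "") or None
            if aux is not None and aux.lower() in {"nan", "none", ""}:
                aux = None
            entry = LexiconEntry(
                word=rec["word"],
                pos=rec["pos"],
                sense_count=int(rec["sense_count"]),
                subcategory=rec["subcategory"],
                intensity=intensity,
                polarity=polarity,
                auxiliary_subcategory=aux,
            )
            lex.add(entry)
        except (LexiconValidationError, ValueError) as exc:
            raise LexiconValidationError(f"lexicon row {rownum}: {exc}") from exc
    return lex


def main_category_of(subcategory: str, taxonomy: EmotionTaxonomy | None = None) -> str:
    """Map one of the 21 subcategory codes to its main emotion category."""
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    return tax.main_category_of(subcategory)
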