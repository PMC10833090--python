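"""Daily/monthly sentiment aggregation, pandemic-stage partitioning, regional
negative-emotion proportions, adjacent-stage differencing, Jenks natural
breaks, and a spatial-similarity permutation test.

The daily score S_D is the mean over a day's documents of the rescaled
classifier output: a positive-class probability s-hat in [0, 1] is mapped to
2*s-hat - 1 in [-1, 1], so scores below 0 indicate net-negative sentiment.
The study window splits into three fixed stages (Jul-Oct 2020, Nov 2020 -
Feb 2021, Mar-Jun 2021); per region and stage the fraction of documents whose
dominant lexicon emotion is negative (anger, disgust, fear, sadness) is
aggregated, differenced across adjacent stages, and classified with the exact
Fisher-Jenks natural-breaks optimizer.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import networkx as nx

from .corpus import Corpus, NEGATIVE_CATEGORIES
from .lexicon_sentiment import EmotionProfile, dominant_category

__all__ = [
    "DailySentiment",
    "Stage",
    "StagePartition",
    "RegionStageSummary",
    "BreaksClassification",
    "SpatialSimilarityResult",
    "default_stage_partition",
    "shift_score",
    "daily_score",
    "monthly_aggregate",
    "assign_stage",
    "region_stage_summary",
    "stage_difference",
    "jenks_breaks",
    "spatial_similarity",
]


@dataclass(frozen=True)
class DailySentiment:
    date: _dt.date
    m: int  # document count
    S_D: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.S_D <= 1.0 + 1e-12:
            raise ValueError(f"S_D {self.S_D} outside [-1, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass(frozen=True)
class Stage:
    name: str
    start: _dt.date
    end: _dt.date  # inclusive


@dataclass(frozen=True)
class StagePartition:
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        prev_end = None
        for s in self.stages:
            if s.start > s.end:
                raise ValueError(f"stage {s.name}: start after end")
            if prev_end is not None and s.start <= prev_end:
                raise ValueError("stages overlap or are out of order")
            prev_end = s.end


def default_stage_partition() -> StagePartition:
    """The three pandemic phases: Jul-Oct 2020, Nov 2020-Feb 2021, Mar-Jun 2021."""
    return StagePartition(
        stages=(
            Stage("stage1", _dt.date(2020, 7, 1), _dt.date(2020, 10, 31)),
            Stage("stage2", _dt.date(2020, 11, 1), _dt.date(2021, 2, 28)),
            Stage("stage3", _dt.date(2021, 3, 1), _dt.date(2021, 6, 30)),
        )
    )


def shift_score(shat: float) -> float:
    """Map a positive-class probability in [0, 1] onto [-1, 1] via 2*s - 1.

    Negative iff s-hat < 0.5, so the sign of the rescaled score reads
    directly as net sentiment.
    """
    if not 0.0 <= shat <= 1.0:
        raise ValueError(f"s-hat {shat} outside [0, 1]")
    return 2.0 * shat - 1.0


def daily_score(
    day_docs: Sequence, scorer: Callable[[object], float], date: _dt.date | None = None
) -> DailySentiment:
    """S_D = (1/m) * sum_i (2*s-hat_i - 1) over one day's documents."""
    if len(day_docs) == 0:
        raise ValueError("cannot score an empty day")
    scores = [shift_score(scorer(d)) for d in day_docs]
    if date is None:
        date = day_docs[0].date
    return DailySentiment(date=date, m=len(day_docs), S_D=float(np.mean(scores)))


def monthly_aggregate(
    daily: Sequence[DailySentiment],
) -> list[tuple[str, float, int]]:
    """Document-weighted mean S_D per calendar month, chronological order.

    Returns (\"YYYY-MM\", mean score, document count) triples.
    """
    buckets: dict[str, list[DailySentiment]] = {}
    for d in daily:
        buckets.setdefault(d.date.strftime("%Y-%m"), []).append(d)
    out = []
    for month in sorted(buckets):
        days = buckets[month]
        n = sum(d.m for d in days)
        mean = sum(d.S_D * d.m for d in days) / n
        out.append((month, mean, n))
    return out


def assign_stage(date: _dt.date, partition: StagePartition | None = None) -> str:
    """Unique stage containing the date; raises outside the study window."""
    part = partition if partition is not None else default_stage_partition()
    for s in part.stages:
        if s.start <= date <= s.end:
            return s.name
    raise ValueError(f"date {date} outside the study window")


@dataclass(frozen=True)
class RegionStageSummary:
    region: str
    stage: str
    n: int
    negative_proportion: float | None  # None when the cell is empty

    def __post_init__(self) -> None:
        if self.negative_proportion is not None and not (
            0.0 <= self.negative_proportion <= 1.0
        ):
            raise ValueError("proportion outside [0, 1]")


def region_stage_summary(
    corpus: Corpus,
    profiles: Mapping[str, EmotionProfile],
    partition: StagePartition | None = None,
) -> list[RegionStageSummary]:
    """Per (region, stage): document count and negative-emotion proportion.

    Every document needs a region and a date.  Region/stage cells with no
    documents are reported with n=0 and a missing proportion.
    """
    part = partition if partition is not None else default_stage_partition()
    missing = [d.doc_id for d in corpus if d.region is None or d.date is None]
    if missing:
        raise ValueError(f"documents without region or date: {missing[:10]}")

    regions = sorted({d.region for d in corpus})
    cells: dict[tuple[str, str], list[str]] = {}
    for d in corpus:
        cells.setdefault((d.region, assign_stage(d.date, part)), []).append(d.doc_id)

    out: list[RegionStageSummary] = []
    for region in regions:
        for s in part.stages:
            ids = cells.get((region, s.name), [])
            if not ids:
                out.append(RegionStageSummary(region, s.name, 0, None))
                continue
            neg = sum(
                1
                for i in ids
                if (dominant_category(profiles[i]) or "") in NEGATIVE_CATEGORIES
            )
            out.append(RegionStageSummary(region, s.name, len(ids), neg / len(ids)))
    return out


def stage_difference(
    summaries: Sequence[RegionStageSummary],
) -> list[tuple[str, str, str, float | None]]:
    """Adjacent-stage deltas per region: proportion(t+1) - proportion(t).

    Returns (region, stage_from, stage_to, delta); delta is None when the
    region is missing (empty cell) in either stage.
    """
    stages: list[str] = []
    for s in summaries:
        if s.stage not in stages:
            stages.append(s.stage)
    by_cell = {(s.region, s.stage): s for s in summaries}
    regions = sorted({s.region for s in summaries})
    out = []
    for region in regions:
        for a, b in zip(stages, stages[1:]):
            pa = by_cell.get((region, a))
            pb = by_cell.get((region, b))
            if (
                pa is None
                or pb is None
                or pa.negative_proportion is None
                or pb.negative_proportion is None
            ):
                out.append((region, a, b, None))
            else:
                out.append((region, a, b, pb.negative_proportion - pa.negative_proportion))
    return out


@dataclass
class BreaksClassification:
    breaks: list[float]  # upper bound of each class, ascending
    class_index: list[int]  # class of each input value, in input order
    n_classes: int


def jenks_breaks(values: Sequence[float], n_classes: int) -> BreaksClassification:
    """Exact Fisher-Jenks natural breaks by dynamic programming.

    Minimizes the total within-class sum of squared deviations over all
    partitions of the sorted values into ``n_classes`` contiguous classes.
    Requires at least ``n_classes`` distinct values.  Class edges are the
    maxima (upper bounds) of each class.
    """
    vals = [float(v) for v in values]
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if len(set(vals)) < n_classes:
        raise ValueError(
            f"need at least {n_classes} distinct values, got {len(set(vals))}"
        )
    order = np.argsort(vals, kind="stable")
    x = np.asarray(vals)[order]
    n = len(x)

    # prefix sums for O(1) within-class SSD
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:
        # SSD of x[i:j]
        m = j - i
        s = csum[j] - csum[i]
        q = csq[j] - csq[i]
        return q - s * s / m

    INF = float("inf")
    # cost[c][j]: best SSD for first j points in c classes
    cost = np.full((n_classes + 1, n + 1), INF)
    back = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, n_classes + 1):
        for j in range(c, n + 1):
            best = INF
            arg = c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < best:
                    best = v
                    arg = i
            cost[c, j] = best
            back[c, j] = arg

    # recover boundaries
    bounds = [n]
    j = n
    for c in range(n_classes, 0, -1):
        j = back[c, j]
        bounds.append(j)
    bounds = bounds[::-1]  # [0, b1, ..., n]

    breaks = [float(x[b - 1]) for b in bounds[1:]]
    cls_sorted = np.empty(n, dtype=int)
    for c in range(n_classes):
        cls_sorted[bounds[c] : bounds[c + 1]] = c
    class_index = np.empty(n, dtype=int)
    class_index[order] = cls_sorted
    return BreaksClassification(
        breaks=breaks, class_index=class_index.tolist(), n_classes=n_classes
    )


@dataclass(frozen=True)
class SpatialSimilarityResult:
    statistic: float  # mean |difference| over adjacent region pairs
    p_value: float
    n_permutations: int
    null_quantiles: tuple[float, float, float]  # 5th, 50th, 95th percentile


def spatial_similarity(
    proportions: Mapping[str, float],
    adjacency: nx.Graph,
    n_permutations: int = 999,
    seed: int = 0,
) -> SpatialSimilarityResult:
    """Test whether neighboring regions carry similar values.

    Statistic: mean absolute difference of the per-region values across the
    adjacency graph's edges (small = similar neighbors).  The null shuffles
    the values over regions; the one-sided p-value is the fraction of
    permutations with a statistic at least as small as observed, with the
    +1 correction, so it lies in [1/(P+1), 1].
    """
    if adjacency.number_of_edges() == 0:
        raise ValueError("adjacency graph has no edges")
    regions = sorted(proportions)
    missing = [r for r in regions if r not in adjacency]
    if missing:
        raise ValueError(f"regions absent from adjacency graph: {missing}")
    vals = {r: float(proportions[r]) for r in regions}
    edges = [(a, b) for a, b in adjacency.edges() if a in vals and b in vals]
    if not edges:
        raise ValueError("no graph edge joins two regions with values")

    def stat(assign: Mapping[str, float]) -> float:
        return float(np.mean([abs(assign[a] - assign[b]) for a, b in edges]))

    observed = stat(vals)
    rng = np.random.default_rng(seed)
    arr = np.asarray([vals[r] for r in regions])
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = arr[rng.permutation(len(arr))]
        null[p] = stat(dict(zip(regions, perm)))
    p_value = (1 + int(np.sum(null <= observed))) / (n_permutations + 1)
    q5, q50, q95 = np.percentile(null, [5, 50, 95])
    return SpatialSimilarityResult(
        statistic=observed,
        p_value=float(p_value),
        n_permutations=n_permutations,
        null_quantiles=(float(q5), float(q50), float(q95)),
    )
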