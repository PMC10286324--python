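"""Per-cohort fusion accounting, per-sample burden and specimen-age effects.

Counting conventions
--------------------
Confidence-level counts are computed *before* deduplication, on distinct
(key, level) pairs per sample: a fusion called at two levels in one sample
contributes once to each level, which is why per-level counts can sum to
more than the all-confidence total. The analysis call set, in contrast, is
deduplicated to one best call per (sample, key): highest confidence first,
then highest supporting reads, then first occurrence.
"""

from __future__ import annotations

import itertools
import math
import statistics
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CONFIDENCE_LEVELS, CONFIDENCE_RANK, ClinicalRecord, CohortConfig, FusionCall

__all__ = [
    "BurdenTable",
    "CohortCallSet",
    "LevelStats",
    "SummaryTable",
    "AgeGroupResult",
    "age_group_comparison",
    "dedup_sample_fusions",
    "per_sample_burden",
    "rank_sum_test",
    "summarize_cohort",
]


def dedup_sample_fusions(calls: Sequence[FusionCall]) -> list[FusionCall]:
    """Collapse repeated calls of the same fusion within one sample.

    Keeps, per canonical key, the call with the highest confidence, breaking
    ties by total supporting reads and then by first occurrence in input
    order. Idempotent; never increases the call count.
    """
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(samples)}")
    best: dict[str, tuple[tuple[int, int, int], FusionCall]] = {}
    for i, call in enumerate(calls):
        rank = (CONFIDENCE_RANK[call.confidence], call.supporting_reads, -i)
        k = call.key.key
        if k not in best or rank > best[k][0]:
            best[k] = (rank, call)
    return [pair[1] for pair in best.values()]


@dataclass
class CohortCallSet:
    """Raw calls of one cohort plus the per-sample deduplicated analysis set."""

    cohort: CohortConfig
    calls: list[FusionCall]
    analysis_calls: list[FusionCall] = field(init=False)

    def __post_init__(self) -> None:
        self.analysis_calls = []
        for sample_calls in self.calls_by_sample().values():
            self.analysis_calls.extend(dedup_sample_fusions(sample_calls))

    def calls_by_sample(self) -> dict[str, list[FusionCall]]:
        grouped: dict[str, list[FusionCall]] = {}
        for c in self.calls:
            grouped.setdefault(c.sample_id, []).append(c)
        return grouped

    def analysis_by_sample(self) -> dict[str, list[FusionCall]]:
        grouped: dict[str, list[FusionCall]] = {}
        for c in self.analysis_calls:
            grouped.setdefault(c.sample_id, []).append(c)
        return grouped

    def keys_at_level(self, level: str) -> set[str]:
        """Distinct canonical keys called at a given confidence level (pre-dedup)."""
        return {c.key.key for c in self.calls if c.confidence == level}

    def all_keys(self) -> set[str]:
        return {c.key.key for c in self.calls}


@dataclass
class LevelStats:
    n_fusions: int
    mean_per_sample: float
    n_unique: int
    pct_of_all: float


@dataclass
class SummaryTable:
    """Cohort fusion accounting per confidence level (plus 'all')."""

    cohort: str
    n_samples: int
    levels: dict[str, LevelStats]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in ("all",) + CONFIDENCE_LEVELS:
            s = self.levels[level]
            rows.append(
                {
                    "cohort": self.cohort,
                    "confidence": level,
                    "n_fusions": s.n_fusions,
                    "mean_per_sample": s.mean_per_sample,
                    "n_unique": s.n_unique,
                    "pct_of_all": s.pct_of_all,
                }
            )
        return pd.DataFrame(rows)

    def validate(self) -> None:
        total = self.levels["all"].n_fusions
        for level in CONFIDENCE_LEVELS:
            if self.levels[level].n_fusions > total:
                raise AssertionError(f"level {level} count exceeds all-confidence total")
            if self.levels[level].n_unique > self.levels[level].n_fusions:
                raise AssertionError(f"level {level} unique count exceeds its count")
        if sum(self.levels[lv].n_fusions for lv in CONFIDENCE_LEVELS) < total:
            raise AssertionError("per-level counts sum below the all-confidence total")


def summarize_cohort(cohort_calls: CohortCallSet) -> SummaryTable:
    """Cohort-level fusion counts per confidence level.

    ``n_fusions`` sums, over samples, the distinct keys seen in the sample
    (for 'all') or the distinct keys seen at that level in the sample; a key
    present at two levels in one sample counts once per level. ``n_unique``
    counts each key once per cohort. Means divide by the configured number of
    samples, including samples without calls.
    """
    n = cohort_calls.cohort.n_samples
    if n == 0:
        raise ValueError("cohort has zero samples")
    per_sample = cohort_calls.calls_by_sample()

    n_all = sum(len({c.key.key for c in calls}) for calls in per_sample.values())
    levels: dict[str, LevelStats] = {
        "all": LevelStats(n_all, n_all / n, len(cohort_calls.all_keys()), 100.0)
    }
    for level in CONFIDENCE_LEVELS:
        n_level = sum(
            len({c.key.key for c in calls if c.confidence == level})
            for calls in per_sample.values()
        )
        levels[level] = LevelStats(
            n_fusions=n_level,
            mean_per_sample=n_level / n,
            n_unique=len(cohort_calls.keys_at_level(level)),
            pct_of_all=100.0 * n_level / n_all if n_all else 0.0,
        )
    table = SummaryTable(cohort_calls.cohort.name, n, levels)
    table.validate()
    return table


@dataclass
class BurdenTable:
    """Per-sample fusion burden (count of deduplicated fusions in scope)."""

    burdens: dict[str, int]
    median_burden: float
    confidence_scope: str  # high_only | combined | all

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.burdens), "burden": list(self.burdens.values())}
        )


def per_sample_burden(
    cohort_calls: CohortCallSet,
    confidence_scope: str = "high_only",
    clinical: Sequence[ClinicalRecord] | None = None,
    combined_keys: set[str] | None = None,
) -> BurdenTable:
    """Count deduplicated fusions per sample within a confidence scope.

    Scopes: ``high_only`` counts fusions whose best call is high confidence;
    ``all`` counts every deduplicated fusion; ``combined`` counts fusions in
    the supplied cross-cohort combined key set regardless of local
    confidence (the FFPE confirmation analysis). Samples present in the
    clinical table but absent from the calls get burden 0; the median is
    taken over all listed samples.
    """
    if confidence_scope not in ("high_only", "combined", "all"):
        raise ValueError(f"unknown confidence scope {confidence_scope!r}")
    if confidence_scope == "combined" and combined_keys is None:
        raise ValueError("combined scope requires combined_keys")

    burdens: dict[str, int] = {}
    if clinical is not None:
        for rec in clinical:
            burdens[rec.sample_id] = 0
    for sample, calls in cohort_calls.analysis_by_sample().items():
        if confidence_scope == "high_only":
            count = sum(1 for c in calls if c.confidence == "high")
        elif confidence_scope == "combined":
            count = sum(1 for c in calls if c.key.key in combined_keys)
        else:
            count = len(calls)
        burdens[sample] = count
    if not burdens:
        raise ValueError("no samples to compute burden over")
    median = float(statistics.median(burdens.values()))
    return BurdenTable(burdens, median, confidence_scope)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test; returns (rank sum of x, p).

    Uses exact enumeration over all assignments of pooled midranks when both
    groups have at most 10 observations (correct under ties), otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[: len(x)].sum())

    if len(x) <= 10 and len(y) <= 10:
        n, nx = len(pooled), len(x)
        mu = nx * ranks.mean()
        dev_obs = abs(w_obs - mu)
        total = math.comb(n, nx)
        hits = 0
        for combo in itertools.combinations(range(n), nx):
            w = ranks[list(combo)].sum()
            if alternative == "two-sided":
                hits += abs(w - mu) >= dev_obs - 1e-9
            elif alternative == "less":
                hits += w <= w_obs + 1e-9
            else:
                hits += w >= w_obs - 1e-9
        return w_obs, hits / total

    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic", use_continuity=True)
    return w_obs, float(res.pvalue)


@dataclass
class AgeGroupResult:
    groups: dict[str, int]  # sample -> tertile index (0 = youngest)
    boundaries: tuple[float, ...]
    group_means: list[float]
    statistic: float
    p_value: float


def age_group_comparison(
    burdens: BurdenTable,
    clinical: Sequence[ClinicalRecord],
    n_groups: int = 3,
) -> AgeGroupResult:
    """Split samples into specimen-age groups and compare fusion burdens.

    Samples are split at empirical quantiles of specimen age (tertiles by
    default); a sample whose age equals a boundary goes to the younger
    group. The youngest group's burdens are compared against all older
    samples with a two-sided Wilcoxon rank-sum test.
    """
    age_index = {rec.sample_id: rec.specimen_age for rec in clinical}
    missing = [s for s in burdens.burdens if age_index.get(s) is None]
    if missing:
        raise ValueError(f"specimen_age missing for samples: {', '.join(sorted(missing))}")
    ages = {s: age_index[s] for s in burdens.burdens}
    qs = np.quantile(list(ages.values()), [i / n_groups for i in range(1, n_groups)])
    groups: dict[str, int] = {}
    for sample, age in ages.items():
        g = int(np.sum(age > qs))  # age <= boundary -> younger group
        groups[sample] = g
    young = [burdens.burdens[s] for s, g in groups.items() if g == 0]
    older = [burdens.burdens[s] for s, g in groups.items() if g > 0]
    if not young or not older:
        raise ValueError("age grouping produced an empty group")
    stat, p = rank_sum_test(young, older, alternative="two-sided")
    means = [
        float(np.mean([burdens.burdens[s] for s, g in groups.items() if g == gi] or [np.nan]))
        for gi in range(n_groups)
    ]
    return AgeGroupResult(groups, tuple(float(q) for q in qs), means, stat, p)
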