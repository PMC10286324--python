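"""Cross-cohort fusion matching, ranking and concordance.

Discovery cohorts (fresh-frozen) nominate fusions at high confidence.
Confirmation (FFPE) cohorts re-detect them at *any* confidence — RNA
degradation in FFPE tissue demotes true calls to lower confidence — and
additionally contribute their own high-confidence fusions. Candidates are
then restricted to fusions seen in at least ``min_cohorts`` cohorts and
ranked by catalog status and cohort count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import KnownFusionCatalog
from .summary import CohortCallSet

__all__ = [
    "CohortFusionSet",
    "ConcordanceResult",
    "build_candidate_sets",
    "gene_fusion_status",
    "gene_status_concordance",
    "novel_candidates",
    "overlap_and_rank",
]


@dataclass
class CohortFusionSet:
    """Key sets of one cohort, as used for cross-cohort matching."""

    name: str
    role: str
    keys_by_level: dict[str, set[str]]
    combined_keys: set[str] | None = None  # confirmation cohorts only

    def detected_keys(self) -> set[str]:
        """Keys counting as 'detected in this cohort' for overlap tables."""
        if self.role == "confirmation":
            return set(self.combined_keys or set())
        return set(self.keys_by_level.get("high", set()))

    def all_keys(self) -> set[str]:
        out: set[str] = set()
        for keys in self.keys_by_level.values():
            out |= keys
        return out


def build_candidate_sets(cohorts: Sequence[CohortCallSet]) -> list[CohortFusionSet]:
    """Build per-cohort candidate key sets per the discovery/confirmation rule.

    Discovery and evaluation cohorts contribute their unique high-confidence
    keys. Each confirmation cohort's combined set is the union of (a) its
    calls at any confidence that match a discovery high-confidence fusion
    and (b) its own high-confidence calls.
    """
    if not any(c.cohort.role == "discovery" for c in cohorts):
        raise ValueError("at least one discovery cohort is required")
    discovery_high: set[str] = set()
    for c in cohorts:
        if c.cohort.role == "discovery":
            discovery_high |= c.keys_at_level("high")

    sets: list[CohortFusionSet] = []
    for c in cohorts:
        levels = {lv: c.keys_at_level(lv) for lv in ("high", "medium", "low")}
        fs = CohortFusionSet(c.cohort.name, c.cohort.role, levels)
        if c.cohort.role == "confirmation":
            fs.combined_keys = (c.all_keys() & discovery_high) | levels["high"]
        sets.append(fs)
    return sets


def overlap_and_rank(
    sets: Sequence[CohortFusionSet],
    catalog: KnownFusionCatalog,
    min_cohorts: int = 2,
    known_first: bool = False,
    rediscovery_cohort: str | None = None,
) -> pd.DataFrame:
    """Multi-cohort overlap table restricted to keys seen in >= min_cohorts.

    Columns: ``fusion``, one 0/1 detection column per cohort, ``known``
    (exact catalog membership) and ``n_cohorts``. Rows are grouped by known
    status (unknown first by default), then by descending cohort count, then
    by re-detection in the named confirmation cohort, then lexicographically.
    """
    if len(sets) < 2:
        raise ValueError("need at least two cohort fusion sets")
    detected = {s.name: s.detected_keys() for s in sets}
    if rediscovery_cohort is None:
        confirm = [s.name for s in sets if s.role == "confirmation"]
        rediscovery_cohort = confirm[0] if confirm else None

    all_keys = sorted(set().union(*detected.values()))
    rows = []
    for key in all_keys:
        flags = {name: int(key in keys) for name, keys in detected.items()}
        n_cohorts = sum(flags.values())
        if n_cohorts < min_cohorts:
            continue
        rows.append({"fusion": key, **flags, "known": key in catalog, "n_cohorts": n_cohorts})
    df = pd.DataFrame(rows, columns=["fusion", *detected, "known", "n_cohorts"])
    if df.empty:
        return df
    df["_rediscovered"] = df[rediscovery_cohort] if rediscovery_cohort else 0
    df = df.sort_values(
        by=["known", "n_cohorts", "_rediscovered", "fusion"],
        ascending=[not known_first, False, False, True],
        kind="stable",
    ).drop(columns="_rediscovered")
    return df.reset_index(drop=True)


def novel_candidates(table: pd.DataFrame, require_all_cohorts: bool = True) -> list[str]:
    """Unknown fusions detected in all (or >= the table's minimum) cohorts."""
    if table.empty:
        return []
    n_total = len([c for c in table.columns if c not in ("fusion", "known", "n_cohorts")])
    mask = ~table["known"]
    if require_all_cohorts:
        mask &= table["n_cohorts"] == n_total
    return table.loc[mask, "fusion"].tolist()


@dataclass
class ConcordanceResult:
    """2x2 fusion-status contingency between two call sources on one sample set."""

    n: int
    both_positive: int
    a_only: int
    b_only: int
    both_negative: int
    agreement: float
    pct_positive_a: float
    pct_positive_b: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def gene_status_concordance(
    set_a: Mapping[str, bool], set_b: Mapping[str, bool]
) -> ConcordanceResult:
    """Compare per-sample fusion status between two sources one-to-one."""
    if set(set_a) != set(set_b):
        only_a = sorted(set(set_a) - set(set_b))
        only_b = sorted(set(set_b) - set(set_a))
        raise ValueError(f"sample sets differ: only in A {only_a}, only in B {only_b}")
    n = len(set_a)
    if n == 0:
        raise ValueError("empty sample set")
    both_pos = sum(1 for s in set_a if set_a[s] and set_b[s])
    a_only = sum(1 for s in set_a if set_a[s] and not set_b[s])
    b_only = sum(1 for s in set_a if not set_a[s] and set_b[s])
    both_neg = n - both_pos - a_only - b_only
    return ConcordanceResult(
        n=n,
        both_positive=both_pos,
        a_only=a_only,
        b_only=b_only,
        both_negative=both_neg,
        agreement=(both_pos + both_neg) / n,
        pct_positive_a=100.0 * (both_pos + a_only) / n,
        pct_positive_b=100.0 * (both_pos + b_only) / n,
    )


def gene_fusion_status(
    cohort_calls: CohortCallSet,
    gene: str,
    confidence_levels: tuple[str, ...] = ("high",),
    samples: Sequence[str] | None = None,
) -> dict[str, bool]:
    """Per-sample flag: does any call at the given levels involve ``gene``?

    Composite partners are expanded, so a call listing the gene among
    alternatives counts. ``samples`` fixes the sample universe (samples
    without calls become False).
    """
    status: dict[str, bool] = {s: False for s in samples} if samples else {}
    for call in cohort_calls.calls:
        if call.confidence not in confidence_levels:
            continue
        if samples is not None and call.sample_id not in status:
            continue
        if gene in call.key.genes():
            status[call.sample_id] = True
        else:
            status.setdefault(call.sample_id, False)
    return status
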