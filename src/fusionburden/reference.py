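"""Published reference overlap of fusions across three prostate-cancer cohorts.

Ships a transcription of a published multi-cohort overlap table: 36 fusions
detected in at least two of three cohorts (an FFPE biopsy confirmation
cohort and two fresh-frozen discovery cohorts, one of them TCGA-PRAD), with
per-cohort 0/1 detection flags and a known-fusion flag from a curated
cancer-fusion catalog. Fusion names carry the caller's parenthesized
distance annotations and are normalized on load.

Used as a ground-truth fixture for the cross-cohort matching and novelty
operations, and available to users as a reference candidate list.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .crosscohort import CohortFusionSet
from .io import KnownFusionCatalog, canonical_key

__all__ = ["load_reference_overlap", "reference_fusion_sets"]

REFERENCE_COHORTS = ("FFPE_Bx", "FF_RP", "TCGA_PRAD")


def load_reference_overlap() -> pd.DataFrame:
    """The reference overlap table with canonicalized fusion keys."""
    with resources.files("fusionburden.data").joinpath("three_cohort_overlap.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["fusion"] = [
        canonical_key(*f.split("::", 1)).key if "::" in f else f for f in df["fusion"]
    ]
    df["known"] = df["known"].astype(str).str.upper() == "TRUE"
    return df


def reference_fusion_sets() -> tuple[list[CohortFusionSet], KnownFusionCatalog]:
    """Rebuild per-cohort fusion sets and the known catalog from the table.

    The confirmation cohort's flags populate its combined set; the two
    discovery cohorts' flags populate their high-confidence sets, so the
    table round-trips through the overlap/ranking operations.
    """
    df = load_reference_overlap()
    sets = []
    for name in REFERENCE_COHORTS:
        keys = set(df.loc[df[name] == 1, "fusion"])
        if name == "FFPE_Bx":
            sets.append(
                CohortFusionSet(name, "confirmation", {"high": set(), "medium": set(), "low": set()},
                                combined_keys=keys)
            )
        else:
            sets.append(
                CohortFusionSet(name, "discovery", {"high": keys, "medium": set(), "low": set()})
            )
    catalog = KnownFusionCatalog.from_keys(df.loc[df["known"], "fusion"], "reference")
    return sets, catalog
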