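"""Functional annotation of fusion partners.

Covers partner classification (ETS family, snoRNA/snRNA, BAC-clone-derived
symbols), snoRNA/host-gene fusion discovery, read-through candidate
flagging from genomic adjacency, 5'/3' partner promiscuity across cohorts,
and hypergeometric gene-set enrichment with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import FusionKey, GeneRecord
from .summary import CohortCallSet

__all__ = [
    "DEFAULT_ETS_FAMILY",
    "AnnotatedFusion",
    "PrefixRules",
    "classify_partner",
    "find_sno_fusions",
    "gene_set_enrichment",
    "promiscuity",
    "readthrough_candidates",
]

logger = logging.getLogger(__name__)

# Editable default list of human ETS-family transcription factors; callers
# analysing other organisms or newer nomenclature should supply their own
# membership via the annotation table's gene_sets column.
DEFAULT_ETS_FAMILY = (
    "ETS1", "ETS2", "ERG", "FLI1", "FEV", "ERF", "ETV3", "ETV3L",
    "ELK1", "ELK3", "ELK4", "ETV1", "ETV2", "ETV4", "ETV5", "ETV6", "ETV7",
    "ELF1", "ELF2", "ELF3", "ELF4", "ELF5", "EHF", "SPDEF", "GABPA",
    "SPI1", "SPIB", "SPIC",
)


@dataclass(frozen=True)
class PrefixRules:
    """Symbol-prefix fallbacks used when a gene is absent from the annotation."""

    snrna: tuple[str, ...] = ("RNU",)
    snorna: tuple[str, ...] = ("SNOR",)
    clone_derived: tuple[str, ...] = ("RP11", "CTC-", "AC0", "LL0")


_CLASS_TAGS = {"snoRNA": "snoRNA_partner", "snRNA": "snRNA_partner"}


def classify_partner(
    symbol: str,
    annotation: Mapping[str, GeneRecord],
    prefix_rules: PrefixRules = PrefixRules(),
) -> set[str]:
    """Tag one partner gene by class, gene-set membership and symbol prefix.

    Annotation entries take precedence; the prefix rules only apply to
    symbols missing from the annotation. Unknown genes get an empty tag set.
    """
    tags: set[str] = set()
    record = annotation.get(symbol)
    if record is not None:
        if record.gene_class in _CLASS_TAGS:
            tags.add(_CLASS_TAGS[record.gene_class])
        if record.host_of:
            tags.add("snoRNA_host_partner")
        tags |= set(record.gene_sets)
    else:
        if any(symbol.startswith(p) for p in prefix_rules.snorna):
            tags.add("snoRNA_partner")
        elif any(symbol.startswith(p) for p in prefix_rules.snrna):
            tags.add("snRNA_partner")
        elif any(symbol.startswith(p) for p in prefix_rules.clone_derived):
            tags.add("clone_derived_partner")
    return tags


@dataclass
class AnnotatedFusion:
    key: FusionKey
    tags: set[str] = field(default_factory=set)
    partner_classes: dict[str, str | None] = field(default_factory=dict)
    snrna_snorna_pair: bool = False


def annotate_fusion(
    key: FusionKey,
    annotation: Mapping[str, GeneRecord],
    prefix_rules: PrefixRules = PrefixRules(),
) -> AnnotatedFusion:
    """Full per-fusion annotation; composite partners are expanded per gene."""
    out = AnnotatedFusion(key)
    for gene in key.genes():
        out.tags |= classify_partner(gene, annotation, prefix_rules)
        rec = annotation.get(gene)
        out.partner_classes[gene] = rec.gene_class if rec else None

    def side_has(genes: tuple[str, ...], tag: str) -> bool:
        return any(tag in classify_partner(g, annotation, prefix_rules) for g in genes)

    sno_tags = ("snoRNA_partner", "snoRNA_host_partner")
    out.snrna_snorna_pair = (
        side_has(key.genes5, "snRNA_partner")
        and any(side_has(key.genes3, t) for t in sno_tags)
    ) or (
        side_has(key.genes3, "snRNA_partner")
        and any(side_has(key.genes5, t) for t in sno_tags)
    )
    return out


def find_sno_fusions(
    fusions: Iterable[FusionKey],
    annotation: Mapping[str, GeneRecord],
    prefix_rules: PrefixRules = PrefixRules(),
) -> list[AnnotatedFusion]:
    """Fusions involving a snoRNA or a snoRNA host gene.

    snRNA::snoRNA(/host) pairs get ``snrna_snorna_pair`` set — these stand
    out in deeply sequenced total-RNA libraries and are invisible to
    poly(A)-selected protocols.
    """
    out = []
    for key in fusions:
        ann = annotate_fusion(key, annotation, prefix_rules)
        if "snoRNA_partner" in ann.tags or "snoRNA_host_partner" in ann.tags:
            out.append(ann)
    return out


def readthrough_candidates(
    fusions: Iterable[FusionKey],
    annotation: Mapping[str, GeneRecord],
    max_gap_bp: int = 200_000,
) -> dict[str, bool]:
    """Flag fusions whose partners are adjacent on the same chromosome.

    Transcription running past a gene's end into a nearby downstream gene
    produces chimeric transcripts without genomic rearrangement; partners on
    one chromosome whose spans lie within ``max_gap_bp`` (inclusive; 0 for
    overlapping spans) are flagged as read-through candidates. Fusions with
    an unlocatable partner are omitted with a warning.
    """
    flags: dict[str, bool] = {}
    for key in fusions:
        recs5 = [annotation.get(g) for g in key.genes5]
        recs3 = [annotation.get(g) for g in key.genes3]
        if not any(recs5) or not any(recs3):
            logger.warning("read-through check skipped for %s: unlocatable partner", key.key)
            continue
        flagged = False
        for a in recs5:
            for b in recs3:
                if a is None or b is None or a.chrom != b.chrom:
                    continue
                gap = max(a.start - b.end, b.start - a.end, 0)
                if gap <= max_gap_bp:
                    flagged = True
        flags[key.key] = flagged
    return flags


def promiscuity(
    cohort_call_sets: Sequence[CohortCallSet], side: str
) -> pd.DataFrame:
    """How often each gene participates in fusions on the given side.

    An occurrence is one deduplicated (sample, fusion) event in which the
    gene appears on the 5' or 3' side; composite partners contribute one
    occurrence to each listed gene. The combined frequency pools occurrences
    and sample sizes across the cohorts and sorts the table.
    """
    if side not in ("5prime", "3prime"):
        raise ValueError("side must be '5prime' or '3prime'")
    counts: dict[str, dict[str, int]] = {}
    for ccs in cohort_call_sets:
        for call in ccs.analysis_calls:
            genes = call.key.genes5 if side == "5prime" else call.key.genes3
            for gene in genes:
                counts.setdefault(gene, {}).setdefault(ccs.cohort.name, 0)
                counts[gene][ccs.cohort.name] += 1

    n_total = sum(ccs.cohort.n_samples for ccs in cohort_call_sets)
    rows = []
    for gene, per_cohort in counts.items():
        row: dict[str, object] = {"gene": gene, "side": side}
        total = 0
        for ccs in cohort_call_sets:
            name = ccs.cohort.name
            c = per_cohort.get(name, 0)
            row[f"count_{name}"] = c
            row[f"freq_{name}"] = c / ccs.cohort.n_samples
            total += c
        row["combined_frequency"] = total / n_total
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(
        by=["combined_frequency", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def gene_set_enrichment(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    p is the upper tail P(X >= k) of drawing ``k`` set members in a query of
    size ``n`` from a universe of size ``N`` containing ``K`` set members;
    adjusted p-values use Benjamini–Hochberg across all sets tested in this
    call. Query and sets must be drawn from the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")

    N, n = len(universe), len(query)
    rows = []
    for label, members in gene_sets.items():
        members = set(members) & universe
        K = len(members)
        k = len(query & members)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"gene_set": label, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
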