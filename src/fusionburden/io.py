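"""Input tables and the canonical fusion identity.

Fusion calls arrive in the Arriba TSV dialect: tab-separated, header line
beginning ``#gene1``, one row per called fusion with 5'/3' partner names,
breakpoints (``chrom:pos``), a three-level confidence label and the three
read-support columns (``split_reads1``, ``split_reads2``,
``discordant_mates``). Partner names as printed by the caller may list
comma-separated alternative genes, each optionally suffixed with a
parenthesized genomic distance, e.g. ``MBTPS2(33,120),LL0XNC01-39B3.1(20,917)``.

Everything downstream compares fusions by their *canonical key*: the
order-preserving string ``"G1::G2"`` after stripping those distance
annotations. The 5'→3' orientation is part of the identity: ``A::B`` and
``B::A`` are different fusions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CONFIDENCE_LEVELS",
    "CONFIDENCE_RANK",
    "Breakpoint",
    "ClinicalRecord",
    "CohortConfig",
    "FusionCall",
    "FusionKey",
    "FusionTableError",
    "GeneRecord",
    "KnownFusionCatalog",
    "canonical_key",
    "read_catalog",
    "read_clinical",
    "read_fusion_table",
    "read_gene_annotation",
    "write_fusion_table",
]

CONFIDENCE_LEVELS = ("high", "medium", "low")
CONFIDENCE_RANK = {"high": 2, "medium": 1, "low": 0}

# Parenthesized groups containing only digits and commas are caller-reported
# distances, never part of a gene symbol; other parentheses are left alone.
_PAREN_DISTANCE = re.compile(r"\(\s*[\d,]+\s*\)")

REQUIRED_FUSION_COLUMNS = (
    "gene1",
    "gene2",
    "breakpoint1",
    "breakpoint2",
    "confidence",
    "split_reads1",
    "split_reads2",
    "discordant_mates",
)


class FusionTableError(ValueError):
    """Raised for malformed fusion-call, clinical or annotation tables."""


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int  # 1-based

    def __str__(self) -> str:  # round-trips the caller's "chrom:pos" form
        return f"{self.chrom}:{self.pos}"

    @classmethod
    def parse(cls, text: str) -> "Breakpoint":
        chrom, _, pos = str(text).rpartition(":")
        if not chrom or not pos:
            raise FusionTableError(f"unparseable breakpoint {text!r}")
        try:
            return cls(chrom, int(pos))
        except ValueError as exc:
            raise FusionTableError(f"unparseable breakpoint {text!r}") from exc


@dataclass(frozen=True)
class FusionKey:
    """Canonical cohort-comparable identity of a fusion.

    ``key`` is ``"G1::G2"`` with the normalized 5' partner(s) before the
    ``::`` separator. Composite partners (comma-separated alternatives the
    caller could not resolve) are retained in order as one partner.
    """

    key: str
    genes5: tuple[str, ...]
    genes3: tuple[str, ...]

    def genes(self) -> tuple[str, ...]:
        return self.genes5 + self.genes3


def _normalize_partner(name: str) -> tuple[str, ...]:
    cleaned = _PAREN_DISTANCE.sub("", str(name))
    parts = tuple(p.strip() for p in cleaned.split(",") if p.strip())
    if not parts:
        raise FusionTableError(f"gene name {name!r} is empty after normalization")
    return parts


def canonical_key(gene1: str, gene2: str) -> FusionKey:
    """Build the canonical ``"G1::G2"`` identity for a 5'/3' partner pair.

    Parenthesized digit/comma groups (caller distance annotations) are
    stripped; comma-separated alternative genes are kept in order.
    Orientation is preserved: ``canonical_key(a, b) != canonical_key(b, a)``
    whenever ``a != b``.
    """
    genes5 = _normalize_partner(gene1)
    genes3 = _normalize_partner(gene2)
    return FusionKey(",".join(genes5) + "::" + ",".join(genes3), genes5, genes3)


@dataclass
class FusionCall:
    """One called fusion event in one sample, as reported by the caller."""

    sample_id: str
    gene1: str
    gene2: str
    breakpoint1: Breakpoint
    breakpoint2: Breakpoint
    confidence: str
    split_reads1: int
    split_reads2: int
    discordant_mates: int
    filters: str | None = None
    type: str | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise FusionTableError("sample_id must be non-empty")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise FusionTableError(
                f"confidence must be one of {CONFIDENCE_LEVELS}, got {self.confidence!r}"
            )
        for name in ("split_reads1", "split_reads2", "discordant_mates"):
            if getattr(self, name) < 0:
                raise FusionTableError(f"{name} must be >= 0")

    @property
    def supporting_reads(self) -> int:
        """Total read support: split reads on both sides plus discordant mates."""
        return self.split_reads1 + self.split_reads2 + self.discordant_mates

    @cached_property
    def key(self) -> FusionKey:
        return canonical_key(self.gene1, self.gene2)


@dataclass(frozen=True)
class CohortConfig:
    """Role and technical characteristics of one cohort."""

    name: str
    role: str  # discovery | confirmation | evaluation
    preservation: str  # fresh_frozen | FFPE
    n_samples: int
    library: str = "totalRNA"  # totalRNA | polyA
    endpoint_label: str = "BCR"

    def __post_init__(self) -> None:
        if self.role not in ("discovery", "confirmation", "evaluation"):
            raise ValueError(f"unknown cohort role {self.role!r}")
        if self.preservation not in ("fresh_frozen", "FFPE"):
            raise ValueError(f"unknown preservation {self.preservation!r}")
        if self.library not in ("totalRNA", "polyA"):
            raise ValueError(f"unknown library {self.library!r}")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class ClinicalRecord:
    sample_id: str
    patient_id: str
    time: float  # months
    event: bool
    ggg: int | None = None  # Gleason Grading Group 1-5
    tcc: float | None = None  # tumor cell content, percent
    specimen_age: float | None = None  # years
    score: float | None = None  # optional external transcriptome score

    def __post_init__(self) -> None:
        if self.time < 0:
            raise FusionTableError(f"sample {self.sample_id}: time must be >= 0")
        if self.ggg is not None and self.ggg not in (1, 2, 3, 4, 5):
            raise FusionTableError(f"sample {self.sample_id}: ggg must be in 1..5")
        if self.tcc is not None and not 0 <= self.tcc <= 100:
            raise FusionTableError(f"sample {self.sample_id}: tcc must be in [0, 100]")
        if self.specimen_age is not None and self.specimen_age < 0:
            raise FusionTableError(f"sample {self.sample_id}: specimen_age must be >= 0")


@dataclass
class GeneRecord:
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "unknown"
    gene_class: str = "other"
    host_of: tuple[str, ...] = ()
    gene_sets: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FusionTableError(f"gene {self.symbol}: start > end")
        if self.strand not in ("+", "-", "unknown"):
            raise FusionTableError(f"gene {self.symbol}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class KnownFusionCatalog:
    """Exact-membership catalog of known fusions (canonical keys)."""

    entries: frozenset[str]
    source_label: str = "catalog"

    def __contains__(self, key: str | FusionKey) -> bool:
        return (key.key if isinstance(key, FusionKey) else key) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_keys(cls, keys: Iterable[str], source_label: str = "catalog") -> "KnownFusionCatalog":
        normalized = set()
        for raw in keys:
            raw = raw.strip()
            if not raw:
                continue
            g1, sep, g2 = raw.partition("::")
            if not sep:
                raise FusionTableError(f"catalog entry {raw!r} lacks '::'")
            normalized.add(canonical_key(g1, g2).key)
        return cls(frozenset(normalized), source_label)


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_fusion_table(path: str | Path, sample_id: str = "from-column") -> list[FusionCall]:
    """Read an Arriba-dialect fusion table into :class:`FusionCall` records.

    ``sample_id="from-column"`` takes per-row sample ids from a
    ``sample_id`` (or ``sample``) column; any other value is used as the
    constant sample id for every row (the per-sample ``<sample>.fusions.tsv``
    layout). Extra columns are preserved opaquely on ``FusionCall.extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    missing = [c for c in REQUIRED_FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise FusionTableError(f"{path}: missing required column(s) {', '.join(missing)}")

    sample_column = None
    if sample_id == "from-column":
        for cand in ("sample_id", "sample"):
            if cand in df.columns:
                sample_column = cand
                break
        if sample_column is None:
            raise FusionTableError(f"{path}: sample_id='from-column' but no sample_id/sample column")

    known = set(REQUIRED_FUSION_COLUMNS) | {"filters", "type", sample_column}
    extra_cols = [c for c in df.columns if c not in known]

    calls: list[FusionCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        conf = rec["confidence"].strip().lower()
        if conf not in CONFIDENCE_LEVELS:
            raise FusionTableError(
                f"{path}: row {i}: unparseable confidence {rec['confidence']!r}"
            )
        try:
            calls.append(
                FusionCall(
                    sample_id=rec[sample_column] if sample_column else sample_id,
                    gene1=rec["gene1"],
                    gene2=rec["gene2"],
                    breakpoint1=Breakpoint.parse(rec["breakpoint1"]),
                    breakpoint2=Breakpoint.parse(rec["breakpoint2"]),
                    confidence=conf,
                    split_reads1=int(rec["split_reads1"]),
                    split_reads2=int(rec["split_reads2"]),
                    discordant_mates=int(rec["discordant_mates"]),
                    filters=rec.get("filters") or None,
                    type=rec.get("type") or None,
                    extra={c: rec[c] for c in extra_cols},
                )
            )
        except (ValueError, FusionTableError) as exc:
            raise FusionTableError(f"{path}: row {i}: {exc}") from exc
    return calls


def write_fusion_table(calls: Sequence[FusionCall], path: str | Path, with_sample_column: bool = True) -> None:
    """Write calls back out in the Arriba TSV dialect (header ``#gene1 ...``)."""
    columns = [
        "gene1",
        "gene2",
        "breakpoint1",
        "breakpoint2",
        "split_reads1",
        "split_reads2",
        "discordant_mates",
        "confidence",
        "filters",
        "type",
    ]
    if with_sample_column:
        columns.append("sample_id")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for c in calls:
            row = {
                "gene1": c.gene1,
                "gene2": c.gene2,
                "breakpoint1": str(c.breakpoint1),
                "breakpoint2": str(c.breakpoint2),
                "split_reads1": str(c.split_reads1),
                "split_reads2": str(c.split_reads2),
                "discordant_mates": str(c.discordant_mates),
                "confidence": c.confidence,
                "filters": c.filters or "",
                "type": c.type or "",
                "sample_id": c.sample_id,
            }
            fh.write("\t".join(row[col] for col in columns) + "\n")


def _opt_float(value: str) -> float | None:
    value = value.strip()
    return float(value) if value not in ("", "NA", "nan", "None") else None


def read_clinical(path: str | Path, one_per_patient: bool = False) -> list[ClinicalRecord]:
    """Read a clinical CSV (sample_id, patient_id, time, event, ggg, tcc, ...).

    With ``one_per_patient`` set, patients represented by multiple samples
    are reduced to their first sample in file order.
    """
    df = _read_table(path, sep=",")
    required = ("sample_id", "patient_id", "time", "event")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FusionTableError(f"{path}: missing required column(s) {', '.join(missing)}")

    records: list[ClinicalRecord] = []
    seen_samples: set[str] = set()
    seen_patients: set[str] = set()
    for i, row in enumerate(df.to_dict("records"), start=1):
        sid = row["sample_id"].strip()
        pid = row["patient_id"].strip() or sid
        if sid in seen_samples:
            raise FusionTableError(f"{path}: row {i}: duplicate sample_id {sid!r}")
        seen_samples.add(sid)
        if one_per_patient:
            if pid in seen_patients:
                continue
            seen_patients.add(pid)
        event_raw = row["event"].strip()
        if event_raw not in ("0", "1"):
            raise FusionTableError(f"{path}: row {i}: event flag must be 0 or 1, got {event_raw!r}")
        ggg = _opt_float(row.get("ggg", ""))
        try:
            records.append(
                ClinicalRecord(
                    sample_id=sid,
                    patient_id=pid,
                    time=float(row["time"]),
                    event=event_raw == "1",
                    ggg=int(ggg) if ggg is not None else None,
                    tcc=_opt_float(row.get("tcc", "")),
                    specimen_age=_opt_float(row.get("specimen_age", "")),
                    score=_opt_float(row.get("score", "")),
                )
            )
        except (ValueError, FusionTableError) as exc:
            raise FusionTableError(f"{path}: row {i}: {exc}") from exc
    return records


def read_catalog(path: str | Path, source_label: str | None = None) -> KnownFusionCatalog:
    """Read a known-fusion catalog: one key per line, or a CSV with a ``fusion`` column."""
    path = Path(path)
    label = source_label or path.stem
    text = path.read_text()
    first = text.splitlines()[0] if text.strip() else ""
    if "," in first and "fusion" in first.split(","):
        df = _read_table(path, sep=",")
        keys = df["fusion"].tolist()
    else:
        keys = [line for line in text.splitlines() if line.strip() and not line.startswith("#")]
    return KnownFusionCatalog.from_keys(keys, label)


def read_gene_annotation(path: str | Path) -> dict[str, GeneRecord]:
    """Read the simplified gene-annotation TSV into a symbol-keyed table.

    Columns: symbol, chrom, start, end, strand, gene_class, host_of,
    gene_sets (the last two semicolon-delimited, may be empty).
    """
    df = _read_table(path, sep="\t")
    required = ("symbol", "chrom", "start", "end")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FusionTableError(f"{path}: missing required column(s) {', '.join(missing)}")
    table: dict[str, GeneRecord] = {}
    for i, row in enumerate(df.to_dict("records"), start=1):
        symbol = row["symbol"].strip()
        if symbol in table:
            raise FusionTableError(f"{path}: row {i}: duplicate gene symbol {symbol!r}")
        host_of = tuple(s for s in row.get("host_of", "").split(";") if s)
        gene_sets = frozenset(s for s in row.get("gene_sets", "").split(";") if s)
        try:
            table[symbol] = GeneRecord(
                symbol=symbol,
                chrom=row["chrom"].strip(),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row.get("strand", "unknown").strip() or "unknown",
                gene_class=row.get("gene_class", "other").strip() or "other",
                host_of=host_of,
                gene_sets=gene_sets,
            )
        except (ValueError, FusionTableError) as exc:
            raise FusionTableError(f"{path}: row {i}: {exc}") from exc
    return table
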