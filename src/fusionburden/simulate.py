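"""Synthetic multi-cohort fusion-call and outcome generator.

Emulates the statistical structure the pipeline assumes, so every stage is
testable without sequencing data:

* per-sample true fusions = catalog fusions drawn by prevalence (e.g.
  TMPRSS2::ERG in ~50% of samples) plus a negative-binomial count of random
  background gene pairs drawn from the annotation;
* each true fusion is emitted once, plus a duplicated call with probability
  ``duplicate_rate`` (independent confidence draws), exercising the
  per-sample dedup rule;
* FFPE samples get a specimen age, confidence probabilities that shift
  mass from high toward low by ``degradation_slope`` per year of storage,
  read supports shrunk by a fixed factor, and Poisson(rho * age * lambda)
  spurious low-confidence calls — degradation changes how fusions are
  *called*, not which fusions are truly present;
* survival times follow a Weibull proportional-hazards model whose hazard
  multiplier is exp(beta_burden * 1[true burden >= cohort median] +
  beta_ggg * GGG), with independent uniform censoring.

One global seed drives everything; per-cohort streams are spawned
deterministically from it, so the same seed reproduces byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    Breakpoint,
    ClinicalRecord,
    CohortConfig,
    FusionCall,
    GeneRecord,
    canonical_key,
    write_fusion_table,
)
from .summary import CohortCallSet

__all__ = [
    "CohortSimSpec",
    "SimConfig",
    "SimCohort",
    "SurvivalSimSpec",
    "default_gene_table",
    "recovery_report",
    "simulate_cohort",
    "simulate_study",
    "simulate_survival",
    "write_gene_annotation",
]

_MARQUEE_GENES = [
    # (symbol, chrom, start, end, strand, class, host_of, gene_sets)
    ("TMPRSS2", "21", 41464300, 41531116, "-", "protein_coding", "", "androgen_response"),
    ("ERG", "21", 38380027, 38661780, "-", "protein_coding", "", "ETS_family"),
    ("ETV1", "7", 13891229, 13991425, "-", "protein_coding", "", "ETS_family"),
    ("ETV4", "17", 43527843, 43579620, "-", "protein_coding", "", "ETS_family"),
    ("ELK4", "1", 205588395, 205602000, "-", "protein_coding", "", "ETS_family"),
    ("FLI1", "11", 128556430, 128683162, "+", "protein_coding", "", "ETS_family"),
    ("SLC45A3", "1", 205626669, 205649172, "-", "protein_coding", "", "androgen_response"),
    ("AMACR", "5", 34000220, 34008003, "-", "protein_coding", "", ""),
    ("MBTPS2", "X", 21839616, 21885457, "+", "protein_coding", "", ""),
    ("LL0XNC01-39B3.1", "X", 21886000, 21932000, "+", "lncRNA", "", ""),
    ("SMS", "X", 21940700, 21994840, "+", "protein_coding", "", "androgen_response"),
    ("TTC6", "14", 37549702, 38124927, "+", "protein_coding", "SNORD127", ""),
    ("SNORD127", "14", 37600000, 37600110, "+", "snoRNA", "", ""),
    ("MIPOL1", "14", 37245170, 37593479, "+", "protein_coding", "", "tumor_suppressor"),
    ("RP11-356O9.1", "14", 37593900, 37601500, "+", "lncRNA", "", ""),
    ("PTEN", "10", 87863113, 87971930, "+", "protein_coding", "", "tumor_suppressor"),
    ("TP53", "17", 7668421, 7687490, "-", "protein_coding", "", "tumor_suppressor"),
    ("FOXP1", "3", 70954708, 71583978, "-", "protein_coding", "", "tumor_suppressor"),
    ("RNU4-2", "12", 120291825, 120291966, "+", "snRNA", "", ""),
    ("SNORD3A", "17", 19188647, 19188863, "+", "snoRNA", "", ""),
]


def default_gene_table(n_background: int = 300) -> dict[str, GeneRecord]:
    """Deterministic synthetic gene annotation used as the simulation gene pool.

    A handful of genes recurrent in prostate-cancer fusions (with
    approximately realistic GRCh38 spans) plus ``n_background`` evenly
    spaced filler genes across the autosomes; every third filler gene on
    chromosome 2 joins a 'housekeeping' gene set so enrichment calls have a
    null set to test against.
    """
    table: dict[str, GeneRecord] = {}
    for sym, chrom, start, end, strand, cls, host_of, sets in _MARQUEE_GENES:
        table[sym] = GeneRecord(
            symbol=sym,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            gene_class=cls,
            host_of=tuple(h for h in host_of.split(";") if h),
            gene_sets=frozenset(s for s in sets.split(";") if s),
        )
    chroms = [str(c) for c in range(1, 23)]
    for i in range(n_background):
        sym = f"GENE{i + 1:04d}"
        chrom = chroms[i % len(chroms)]
        start = 1_000_000 + 400_000 * (i // len(chroms))
        sets = frozenset(["housekeeping"]) if chrom == "2" and i % 3 == 0 else frozenset()
        table[sym] = GeneRecord(sym, chrom, start, start + 50_000, "+", "protein_coding", (), sets)
    return table


def write_gene_annotation(table: Mapping[str, GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\tchrom\tstart\tend\tstrand\tgene_class\thost_of\tgene_sets\n")
        for rec in table.values():
            fh.write(
                "\t".join(
                    [
                        rec.symbol,
                        rec.chrom,
                        str(rec.start),
                        str(rec.end),
                        rec.strand,
                        rec.gene_class,
                        ";".join(rec.host_of),
                        ";".join(sorted(rec.gene_sets)),
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class CohortSimSpec:
    name: str
    role: str
    preservation: str
    n_samples: int
    mean_burden: float = 40.0  # lambda: expected true fusions per sample
    overdispersion: float = 0.4  # negative-binomial 1/size; 0 -> Poisson
    library: str = "totalRNA"
    endpoint_label: str = "BCR"


@dataclass(frozen=True)
class SurvivalSimSpec:
    shape: float = 1.5  # Weibull shape k
    scale: float = 360.0  # Weibull scale s, months (~30% events under censoring)
    beta_burden: float = 0.7  # logHR of the high-burden group
    beta_ggg: float = 0.6  # logHR per GGG step
    censor_max: float = 120.0  # uniform censoring window, months


def _study_cohorts() -> tuple[CohortSimSpec, ...]:
    return (
        CohortSimSpec("FF_RP", "discovery", "fresh_frozen", 40, 59.0, 0.4,
                      library="totalRNA", endpoint_label="DoD"),
        CohortSimSpec("TCGA_PRAD", "discovery", "fresh_frozen", 332, 39.0, 0.4,
                      library="polyA"),
        CohortSimSpec("FFPE_Bx", "confirmation", "FFPE", 176, 40.0, 0.4,
                      library="totalRNA"),
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    cohorts: tuple[CohortSimSpec, ...] = field(default_factory=_study_cohorts)
    catalog_prevalences: tuple[tuple[str, float], ...] = (
        ("TMPRSS2::ERG", 0.5),
        ("SLC45A3::ELK4", 0.10),
        ("TTC6::MIPOL1", 0.05),
        ("AMACR::AMACR", 0.04),
        ("MBTPS2,LL0XNC01-39B3.1::SMS", 0.03),
    )
    confidence_probs: tuple[tuple[str, tuple[float, float, float]], ...] = (
        ("fresh_frozen", (0.21, 0.30, 0.49)),
        ("FFPE", (0.085, 0.30, 0.615)),  # at the youngest specimen age
    )
    ffpe_age_range: tuple[float, float] = (4.5, 11.1)  # years
    degradation_slope: float = 0.013  # delta: high->low probability mass per year
    spurious_rate: float = 1.8  # rho: spurious low-conf calls ~ Poisson(rho*age*lambda-scaled)
    duplicate_rate: float = 0.3
    read_mean: float = 12.0
    read_dispersion: float = 2.0
    ffpe_read_factor: float = 0.4
    ggg_probs: tuple[float, ...] = (0.3, 0.3, 0.2, 0.1, 0.1)
    survival: SurvivalSimSpec = field(default_factory=SurvivalSimSpec)

    def confidence_for(self, preservation: str, age: float | None) -> np.ndarray:
        probs = dict(self.confidence_probs)[preservation]
        p = np.array(probs, dtype=float)
        if preservation == "FFPE" and age is not None:
            shift = min(self.degradation_slope * max(age - self.ffpe_age_range[0], 0.0),
                        p[0] - 0.002)
            p = p + np.array([-shift, 0.0, shift])
        return p / p.sum()


@dataclass
class SimCohort:
    """One simulated cohort: calls, clinical records and the ground truth."""

    spec: CohortSimSpec
    config: SimConfig
    calls: list[FusionCall]
    clinical: list[ClinicalRecord]
    truth: pd.DataFrame  # sample_id, true_burden, true_group, ggg, specimen_age, time, event

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            name=self.spec.name,
            role=self.spec.role,
            preservation=self.spec.preservation,
            n_samples=self.spec.n_samples,
            library=self.spec.library,
            endpoint_label=self.spec.endpoint_label,
        )

    def call_set(self) -> CohortCallSet:
        return CohortCallSet(self.cohort_config(), list(self.calls))

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "calls": str(out_dir / f"{self.spec.name}.fusions.tsv"),
            "clinical": str(out_dir / f"{self.spec.name}.clinical.csv"),
            "truth": str(out_dir / f"{self.spec.name}.truth.csv"),
        }
        write_fusion_table(self.calls, paths["calls"])
        with open(paths["clinical"], "w") as fh:
            fh.write("sample_id,patient_id,time,event,ggg,tcc,specimen_age,score\n")
            for r in self.clinical:
                fh.write(
                    f"{r.sample_id},{r.patient_id},{r.time:.4f},{int(r.event)},"
                    f"{r.ggg},{r.tcc:.1f},"
                    f"{'' if r.specimen_age is None else f'{r.specimen_age:.3f}'},"
                    f"{'' if r.score is None else f'{r.score:.4f}'}\n"
                )
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _nb_count(rng: np.random.Generator, mean: float, overdispersion: float) -> int:
    if mean <= 0:
        return 0
    if overdispersion <= 0:
        return int(rng.poisson(mean))
    size = 1.0 / overdispersion
    return int(rng.negative_binomial(size, size / (size + mean)))


def _read_support(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    return _nb_count(rng, mean, 1.0 / max(dispersion, 1e-9))


def _random_breakpoint(rng: np.random.Generator, rec: GeneRecord | None) -> Breakpoint:
    if rec is None:
        return Breakpoint("0", 1)
    return Breakpoint(rec.chrom, int(rng.integers(rec.start, rec.end + 1)))


def simulate_survival(
    rng: np.random.Generator,
    group: np.ndarray,
    ggg: np.ndarray,
    spec: SurvivalSimSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull proportional-hazards event times with uniform censoring.

    T = s * (-log U / exp(eta))**(1/k) with eta = beta_burden*group +
    beta_ggg*ggg (centered at GGG 1 so baseline times stay on scale).
    Returns (observed time, event flag).
    """
    eta = spec.beta_burden * group + spec.beta_ggg * (ggg - 1.0)
    u = rng.uniform(size=group.size)
    t_event = spec.scale * (-np.log(u) / np.exp(eta)) ** (1.0 / spec.shape)
    t_cens = rng.uniform(0.0, spec.censor_max, size=group.size)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return time, event


def simulate_cohort(
    config: SimConfig,
    cohort: str | CohortSimSpec,
    annotation: Mapping[str, GeneRecord] | None = None,
    rng: np.random.Generator | None = None,
) -> SimCohort:
    """Simulate one cohort's fusion calls, clinical outcomes and truth table."""
    spec = cohort if isinstance(cohort, CohortSimSpec) else next(
        c for c in config.cohorts if c.name == cohort
    )
    if annotation is None:
        annotation = default_gene_table()
    if len(annotation) < 2:
        raise ValueError("annotation must contain at least two genes")
    if rng is None:
        idx = [c.name for c in config.cohorts].index(spec.name)
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(len(config.cohorts))[idx])

    genes = list(annotation)
    prevalences = dict(config.catalog_prevalences)
    is_ffpe = spec.preservation == "FFPE"
    read_factor = config.ffpe_read_factor if is_ffpe else 1.0
    survival_spec = config.survival

    calls: list[FusionCall] = []
    rows = []
    for i in range(spec.n_samples):
        sid = f"{spec.name}_S{i + 1:04d}"
        age = float(rng.uniform(*config.ffpe_age_range)) if is_ffpe else None

        true_keys: list[tuple[str, str]] = []  # (gene1 label, gene2 label)
        taken = set()
        for key, prev in prevalences.items():
            if rng.uniform() < prev:
                g1, _, g2 = key.partition("::")
                true_keys.append((g1, g2))
                taken.add(key)
        bg_mean = max(spec.mean_burden - sum(prevalences.values()), 0.0)
        n_bg = _nb_count(rng, bg_mean, spec.overdispersion)
        n_catalog = len(true_keys)
        while len(true_keys) < n_catalog + n_bg:
            a, b = rng.choice(len(genes), size=2, replace=False)
            key = canonical_key(genes[a], genes[b]).key
            if key in taken or key in prevalences:
                continue
            taken.add(key)
            true_keys.append((genes[a], genes[b]))

        conf_probs = config.confidence_for(spec.preservation, age)
        for g1, g2 in true_keys:
            n_copies = 1 + int(rng.uniform() < config.duplicate_rate)
            for _ in range(n_copies):
                conf = ("high", "medium", "low")[int(rng.choice(3, p=conf_probs))]
                rec1 = annotation.get(g1.split(",")[0])
                rec2 = annotation.get(g2.split(",")[0])
                calls.append(
                    FusionCall(
                        sample_id=sid,
                        gene1=g1,
                        gene2=g2,
                        breakpoint1=_random_breakpoint(rng, rec1),
                        breakpoint2=_random_breakpoint(rng, rec2),
                        confidence=conf,
                        split_reads1=_read_support(rng, config.read_mean * read_factor, config.read_dispersion),
                        split_reads2=_read_support(rng, config.read_mean * read_factor, config.read_dispersion),
                        discordant_mates=_read_support(rng, config.read_mean * read_factor / 2, config.read_dispersion),
                        type="simulated",
                    )
                )

        n_spurious = 0
        if is_ffpe and config.spurious_rate > 0:
            # spurious-call intensity scales with storage age and with the
            # cohort's fusion-call scale lambda (rate rho per year per unit)
            n_spurious = int(rng.poisson(config.spurious_rate * age * spec.mean_burden))
            idx_a = rng.integers(0, len(genes), size=n_spurious)
            idx_b = rng.integers(0, len(genes) - 1, size=n_spurious)
            idx_b = np.where(idx_b >= idx_a, idx_b + 1, idx_b)  # uniform distinct pair
            reads = rng.integers(0, 3, size=(n_spurious, 3))
            for a, b, (s1, s2, dm) in zip(idx_a, idx_b, reads):
                calls.append(
                    FusionCall(
                        sample_id=sid,
                        gene1=genes[a],
                        gene2=genes[b],
                        breakpoint1=_random_breakpoint(rng, annotation[genes[a]]),
                        breakpoint2=_random_breakpoint(rng, annotation[genes[b]]),
                        confidence="low",
                        split_reads1=int(s1),
                        split_reads2=int(s2),
                        discordant_mates=int(dm),
                        filters="degradation_artifact",
                        type="spurious",
                    )
                )

        ggg = 1 + int(rng.choice(5, p=np.array(config.ggg_probs) / sum(config.ggg_probs)))
        tcc = float(rng.uniform(5, 100)) if is_ffpe else float(rng.uniform(50, 100))
        rows.append(
            {
                "sample_id": sid,
                "true_burden": len(true_keys),
                "ggg": ggg,
                "tcc": tcc,
                "specimen_age": age,
                "n_spurious": n_spurious,
            }
        )

    truth = pd.DataFrame(rows)
    median = float(truth["true_burden"].median())
    truth["true_group"] = (truth["true_burden"] >= median).astype(int)
    time, event = simulate_survival(
        rng,
        truth["true_group"].to_numpy(dtype=float),
        truth["ggg"].to_numpy(dtype=float),
        survival_spec,
    )
    truth["time"] = np.round(time, 4)
    truth["event"] = event.astype(int)
    truth["beta_burden"] = survival_spec.beta_burden
    truth["beta_ggg"] = survival_spec.beta_ggg

    clinical = [
        ClinicalRecord(
            sample_id=r.sample_id,
            patient_id=r.sample_id.replace("_S", "_P"),
            time=float(r.time),
            event=bool(r.event),
            ggg=int(r.ggg),
            tcc=float(r.tcc),
            specimen_age=None if r.specimen_age is None or np.isnan(r.specimen_age) else float(r.specimen_age),
        )
        for r in truth.itertuples(index=False)
    ]
    return SimCohort(spec, config, calls, clinical, truth)


def simulate_study(
    config: SimConfig,
    annotation: Mapping[str, GeneRecord] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, SimCohort]:
    """Simulate all configured cohorts; optionally write a run directory.

    Per-cohort random streams are spawned deterministically from the global
    seed, so results are reproducible per cohort and as a whole.
    """
    if annotation is None:
        annotation = default_gene_table()
    streams = np.random.SeedSequence(config.seed).spawn(len(config.cohorts))
    cohorts = {
        spec.name: simulate_cohort(config, spec, annotation, np.random.default_rng(ss))
        for spec, ss in zip(config.cohorts, streams)
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": config.seed, "cohorts": {}}
        for name, sim in cohorts.items():
            manifest["cohorts"][name] = sim.write(out_dir)
        write_gene_annotation(annotation, out_dir / "genes.tsv")
        with open(out_dir / "catalog.txt", "w") as fh:
            for key, _ in config.catalog_prevalences:
                fh.write(key + "\n")
        manifest["annotation"] = str(out_dir / "genes.tsv")
        manifest["catalog"] = str(out_dir / "catalog.txt")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cohorts


def recovery_report(
    sim: SimCohort,
    burdens: Mapping[str, int],
    beta_hat: float | None = None,
    ci: tuple[float, float] | None = None,
) -> dict:
    """Score pipeline output against the simulation's ground truth."""
    from scipy import stats as sps

    truth = sim.truth.set_index("sample_id")
    est = np.array([burdens.get(s, 0) for s in truth.index])
    true = truth["true_burden"].to_numpy()
    exact = float(np.mean(est == true))
    if np.ptp(est) == 0 or np.ptp(true) == 0:
        rank_corr = float("nan")
    else:
        rank_corr = float(sps.spearmanr(est, true).statistic)
    report = {
        "cohort": sim.spec.name,
        "n_samples": int(truth.shape[0]),
        "burden_exact_fraction": exact,
        "burden_rank_correlation": rank_corr,
        "true_beta_burden": sim.config.survival.beta_burden,
    }
    if beta_hat is not None:
        report["beta_hat"] = float(beta_hat)
        report["beta_error"] = float(beta_hat - sim.config.survival.beta_burden)
    if ci is not None:
        report["ci_covers_truth"] = bool(ci[0] <= sim.config.survival.beta_burden <= ci[1])
    return report
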