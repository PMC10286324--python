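"""End-to-end pipeline: summarize -> crosscohort -> annotate -> prognosis.

Driven by a YAML config naming per-cohort fusion-call and clinical files,
the known-fusion catalog and the gene-annotation table. Each stage writes
its outputs before the next starts; a run manifest records the config
snapshot, input checksums, per-stage row counts and the seed, so re-running
an identical manifest reproduces identical outputs for deterministic
stages.

Config schema (YAML)::

    seed: 1
    output_dir: results
    min_cohorts: 2
    confidence_scope: high_only   # high_only | combined | all
    ties: breslow                 # breslow | efron
    catalog: catalog.txt
    annotation: genes.tsv
    stages: [summarize, crosscohort, annotate, prognosis]
    cohorts:
      - name: FF_RP
        role: discovery           # discovery | confirmation | evaluation
        preservation: fresh_frozen
        library: totalRNA
        calls: FF_RP.fusions.tsv
        clinical: FF_RP.clinical.csv
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import annotation as ann
from . import crosscohort as cc
from .io import (
    ClinicalRecord,
    CohortConfig,
    KnownFusionCatalog,
    read_catalog,
    read_clinical,
    read_fusion_table,
    read_gene_annotation,
)
from .summary import CohortCallSet, age_group_comparison, per_sample_burden, summarize_cohort
from .survival import GroupingSpec, assign_groups, burden_survival_analysis

__all__ = ["PipelineError", "RunManifest", "load_config", "run_pipeline"]

ALL_STAGES = ("summarize", "crosscohort", "annotate", "prognosis")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_checksums: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if not config.get("cohorts"):
        raise PipelineError("config must name at least one cohort")
    base = Path(path).parent
    for key in ("catalog", "annotation"):
        if config.get(key):
            config[key] = str((base / config[key]).resolve())
    for cohort in config["cohorts"]:
        for key in ("calls", "clinical"):
            if cohort.get(key):
                cohort[key] = str((base / cohort[key]).resolve())
    return config


def _load_cohort(entry: dict) -> tuple[CohortCallSet, list[ClinicalRecord]]:
    calls = read_fusion_table(entry["calls"], sample_id=entry.get("sample_id", "from-column"))
    clinical = (
        read_clinical(entry["clinical"], one_per_patient=entry.get("one_per_patient", False))
        if entry.get("clinical")
        else []
    )
    sample_ids = {c.sample_id for c in calls} | {r.sample_id for r in clinical}
    cohort = CohortConfig(
        name=entry["name"],
        role=entry.get("role", "discovery"),
        preservation=entry.get("preservation", "fresh_frozen"),
        n_samples=entry.get("n_samples", len(sample_ids)),
        library=entry.get("library", "totalRNA"),
        endpoint_label=entry.get("endpoint", "BCR"),
    )
    return CohortCallSet(cohort, calls), clinical


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> RunManifest:
    """Execute the configured stages in order and write a run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(output_dir or config.get("output_dir", "fusionburden_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", ALL_STAGES))
    manifest = RunManifest(config=config, seed=int(config.get("seed", 0)))

    cohort_sets: dict[str, CohortCallSet] = {}
    clinical_by_cohort: dict[str, list[ClinicalRecord]] = {}
    try:
        for entry in config["cohorts"]:
            ccs, clinical = _load_cohort(entry)
            cohort_sets[entry["name"]] = ccs
            clinical_by_cohort[entry["name"]] = clinical
            manifest.input_checksums[entry["calls"]] = _sha256(entry["calls"])
            if entry.get("clinical"):
                manifest.input_checksums[entry["clinical"]] = _sha256(entry["clinical"])
    except Exception as exc:
        raise PipelineError(f"stage load: {exc}") from exc

    catalog = (
        read_catalog(config["catalog"]) if config.get("catalog") else KnownFusionCatalog(frozenset())
    )
    annotation = read_gene_annotation(config["annotation"]) if config.get("annotation") else {}
    scope = config.get("confidence_scope", "high_only")
    min_cohorts = int(config.get("min_cohorts", 2))
    ties = config.get("ties", "breslow")

    def record(stage: str, rows: int, outputs: Sequence[Path]) -> None:
        manifest.stages.append({"stage": stage, "rows": rows})
        manifest.outputs.extend(str(p) for p in outputs)

    fusion_sets = None
    combined = {}
    for stage in stages:
        try:
            if stage == "summarize":
                outputs = []
                rows = 0
                for name, ccs in cohort_sets.items():
                    table = summarize_cohort(ccs).to_frame()
                    path = out / f"summary_{name}.tsv"
                    table.to_csv(path, sep="\t", index=False)
                    outputs.append(path)
                    rows += len(table)
                    burdens = per_sample_burden(ccs, "all", clinical_by_cohort[name] or None)
                    bpath = out / f"burden_{name}.tsv"
                    burdens.to_frame().to_csv(bpath, sep="\t", index=False)
                    outputs.append(bpath)
                record(stage, rows, outputs)
            elif stage == "crosscohort":
                fusion_sets = cc.build_candidate_sets(list(cohort_sets.values()))
                combined = {
                    s.name: s.combined_keys for s in fusion_sets if s.combined_keys is not None
                }
                table = cc.overlap_and_rank(fusion_sets, catalog, min_cohorts=min_cohorts)
                path = out / "overlap.tsv"
                table.to_csv(path, sep="\t", index=False)
                novel = cc.novel_candidates(table, require_all_cohorts=True)
                npath = out / "novel_candidates.txt"
                npath.write_text("".join(k + "\n" for k in novel))
                record(stage, len(table), [path, npath])
            elif stage == "annotate":
                keys = {c.key.key: c.key for ccs in cohort_sets.values() for c in ccs.analysis_calls}
                annotated = [ann.annotate_fusion(k, annotation) for k in keys.values()]
                rt = ann.readthrough_candidates(keys.values(), annotation)
                rows = []
                for a in annotated:
                    tags = set(a.tags)
                    if rt.get(a.key.key):
                        tags.add("readthrough_candidate")
                    if a.key.key in catalog:
                        tags.add("known")
                    rows.append(
                        {
                            "fusion": a.key.key,
                            "tags": ";".join(sorted(tags)),
                            "snrna_snorna_pair": int(a.snrna_snorna_pair),
                        }
                    )
                import pandas as pd

                apath = out / "annotated_fusions.tsv"
                pd.DataFrame(rows).to_csv(apath, sep="\t", index=False)
                outputs = [apath]
                for side in ("5prime", "3prime"):
                    table = ann.promiscuity(list(cohort_sets.values()), side)
                    path = out / f"promiscuity_{side}.tsv"
                    table.to_csv(path, sep="\t", index=False)
                    outputs.append(path)
                if annotation:
                    sets: dict[str, set[str]] = {}
                    for rec in annotation.values():
                        for label in rec.gene_sets:
                            sets.setdefault(label, set()).add(rec.symbol)
                    query = {
                        g
                        for k in keys.values()
                        for g in k.genes()
                        if g in annotation
                    }
                    if sets and query:
                        enr = ann.gene_set_enrichment(query, sets, annotation.keys())
                        epath = out / "enrichment.tsv"
                        enr.to_csv(epath, sep="\t", index=False)
                        outputs.append(epath)
                record(stage, len(rows), outputs)
            elif stage == "prognosis":
                outputs = []
                rows = 0
                for name, ccs in cohort_sets.items():
                    clinical = clinical_by_cohort[name]
                    if not clinical:
                        continue
                    cohort_scope = scope
                    ckeys = None
                    if ccs.cohort.role == "confirmation" and combined.get(name):
                        cohort_scope = "combined"
                        ckeys = combined[name]
                    burdens = per_sample_burden(ccs, cohort_scope, clinical, combined_keys=ckeys)
                    groups = assign_groups(GroupingSpec("burden_median"), burdens=burdens)
                    result = burden_survival_analysis(clinical, groups, ties=ties)
                    result["median_burden"] = burdens.median_burden
                    result["confidence_scope"] = cohort_scope
                    path = out / f"prognosis_{name}.json"
                    path.write_text(json.dumps(result, indent=2))
                    outputs.append(path)
                    rows += 1
                    if all(r.specimen_age is not None for r in clinical) and clinical:
                        age = age_group_comparison(burdens, clinical)
                        agepath = out / f"age_effect_{name}.json"
                        agepath.write_text(
                            json.dumps(
                                {
                                    "boundaries": age.boundaries,
                                    "group_means": age.group_means,
                                    "statistic": age.statistic,
                                    "p": age.p_value,
                                },
                                indent=2,
                            )
                        )
                        outputs.append(agepath)
                record(stage, rows, outputs)
            else:
                raise PipelineError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest
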