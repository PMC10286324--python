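"""Simulate a three-cohort study and run the whole pipeline on its files.

Writes a synthetic run directory (Arriba-dialect call tables, clinical
CSVs, ground-truth tables, gene annotation, catalog), builds a pipeline
config, executes summarize -> crosscohort -> annotate -> prognosis, and
scores the recovered burdens against the simulation truth.
"""

import json
import tempfile
from pathlib import Path

import yaml

from fusionburden import SimConfig, per_sample_burden, recovery_report, simulate_study
from fusionburden.pipeline import run_pipeline
from fusionburden.simulate import CohortSimSpec

config = SimConfig(
    seed=7,
    cohorts=(
        CohortSimSpec("FF_RP", "discovery", "fresh_frozen", 40, 12.0, 0.4),
        CohortSimSpec("FFPE_Bx", "confirmation", "FFPE", 60, 12.0, 0.4),
    ),
)

with tempfile.TemporaryDirectory() as tmp:
    run_dir = Path(tmp) / "sim"
    sims = simulate_study(config, out_dir=run_dir)
    print("simulated:", {n: f"{len(s.calls)} calls" for n, s in sims.items()})

    pipeline_config = {
        "seed": 7,
        "min_cohorts": 2,
        "confidence_scope": "high_only",
        "catalog": "catalog.txt",
        "annotation": "genes.tsv",
        "cohorts": [
            {"name": n, "role": s.spec.role, "preservation": s.spec.preservation,
             "calls": f"{n}.fusions.tsv", "clinical": f"{n}.clinical.csv"}
            for n, s in sims.items()
        ],
    }
    (run_dir / "config.yaml").write_text(yaml.safe_dump(pipeline_config))

    manifest = run_pipeline(run_dir / "config.yaml", output_dir=Path(tmp) / "out")
    print("stages run:", [s["stage"] for s in manifest.stages])

    prognosis = json.loads((Path(tmp) / "out" / "prognosis_FF_RP.json").read_text())
    print(f"FF_RP log-rank p = {prognosis['logrank']['p']:.3g}")

    ff = sims["FF_RP"]
    burdens = per_sample_burden(ff.call_set(), "all", ff.clinical)
    report = recovery_report(ff, burdens.burdens)
    print(
        "FF_RP burden recovery after dedup: "
        f"{report['burden_exact_fraction']:.0%} exact "
        f"(duplicated calls collapse to the true fusion count)"
    )

    ffpe = sims["FFPE_Bx"]
    raw = per_sample_burden(ffpe.call_set(), "all", ffpe.clinical)
    report = recovery_report(ffpe, raw.burdens)
    print(
        "FFPE all-confidence burden vs truth: rank correlation "
        f"{report['burden_rank_correlation']:.2f} — degradation artifacts swamp"
    )
    print("the raw count, which is why FFPE cohorts are analysed through the")
    print("high-confidence or discovery-matched 'combined' scopes instead.")
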