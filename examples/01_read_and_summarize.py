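"""Read an Arriba-dialect fusion table and reproduce the cohort accounting.

Builds a tiny two-sample call table (one fusion called twice at different
confidence levels in sample S1), reads it back, deduplicates per sample and
prints the per-level summary. Note how TMPRSS2::ERG counts once for 'all'
but once per level it appears at, and how the analysis set keeps only the
best call per fusion.
"""

import tempfile
from pathlib import Path

from fusionburden import (
    CohortConfig,
    CohortCallSet,
    dedup_sample_fusions,
    read_fusion_table,
    summarize_cohort,
)

TABLE = """\
#gene1	gene2	breakpoint1	breakpoint2	confidence	split_reads1	split_reads2	discordant_mates	sample_id
TMPRSS2	ERG	21:41498119	21:38445621	high	12	9	4	S1
TMPRSS2	ERG	21:41498119	21:38445621	low	1	0	1	S1
SLC45A3	ELK4	1:205642673	1:205590570	medium	3	2	1	S1
TMPRSS2	ERG	21:41498119	21:38445621	high	8	7	2	S2
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cohort.fusions.tsv"
    path.write_text(TABLE)
    calls = read_fusion_table(path)

print(f"parsed {len(calls)} calls from {len({c.sample_id for c in calls})} samples")

s1 = [c for c in calls if c.sample_id == "S1"]
best = dedup_sample_fusions(s1)
print(f"S1: {len(s1)} calls -> {len(best)} deduplicated fusions")
for call in best:
    print(f"  kept {call.key.key} at {call.confidence} ({call.supporting_reads} reads)")

cohort = CohortCallSet(CohortConfig("DEMO", "discovery", "fresh_frozen", 2), calls)
print("\nper-level accounting (a fusion at two levels counts once per level):")
print(summarize_cohort(cohort).to_frame().to_string(index=False))
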