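# fusionburden

Gene-fusion characterization and fusion-burden prognosis for multi-cohort
prostate-cancer RNA-seq studies.

Prostate cancer is unusual among solid tumors in that gene fusions —
chimeric transcripts joining a 5' partner to a 3' partner, with
*TMPRSS2::ERG* present in roughly half of patients of European descent —
are central to tumorigenesis. This package implements the downstream
analysis for studies that call fusions with Arriba-style tools across
several cohorts differing in preservation (fresh-frozen vs FFPE), library
chemistry (total RNA vs poly(A)) and endpoint (biochemical recurrence vs
death of disease): harmonizing the calls, comparing cohorts, annotating
candidate fusions, and testing whether a sample's total fusion burden — a
surrogate for genomic instability — carries prognostic information beyond
the Gleason Grading Group (GGG). It is written for computational biologists
who already have fusion-call tables and matched clinical follow-up and want
a tested, reproducible path from those tables to candidate lists and
survival statistics.

## What it computes

**Fusion identity and per-sample dedup.** Fusions are compared by the
canonical ordered key `G1::G2` (caller distance annotations such as
`MBTPS2(33,120)` stripped; `A::B` ≠ `B::A`). When one sample carries
repeated calls of the same fusion, the call with the highest confidence,
then the most supporting reads (split reads + discordant mates), is kept.

**Cohort accounting.** Per-cohort counts and per-sample means by Arriba
confidence level (high/medium/low), counted per level before dedup — a
fusion called at two levels in one sample contributes to both levels, so
level percentages can exceed 100% in total. FFPE cohorts are additionally
split by specimen-age tertiles and compared with a Wilcoxon rank-sum test
(exact enumeration for small groups), since RNA degradation suppresses
high-confidence calls as specimens age.

**Cross-cohort candidates.** Fresh-frozen discovery cohorts nominate
fusions at high confidence; the FFPE confirmation cohort re-detects them at
*any* confidence and contributes its own high-confidence calls. Fusions
seen in ≥ 2 cohorts are ranked by catalog status (e.g. a Mitelman-DB-style
known-fusion list) and cohort count; unknown fusions seen everywhere are
the novel candidates. Per-gene fusion-status concordance against an
external call set is summarized in 2×2 contingency tables.

**Annotation.** Partner classification (ETS family, snoRNA/snRNA and their
host genes, BAC-clone-derived `RP11-…` symbols), read-through flags for
partners adjacent on one chromosome, 5'/3' promiscuity pooled across
cohorts, and hypergeometric gene-set enrichment with Benjamini–Hochberg
adjustment.

**Prognosis.** Samples are dichotomized at the cohort median burden (or by
carrier status of one fusion). The package fits the Kaplan–Meier
product-limit estimator Ŝ(t) = Π_{t_i ≤ t} (1 − d_i/n_i), the g-sample
log-rank test, and a Cox proportional-hazards model
h(t|x) = h₀(t)·exp(β₁·1[burden ≥ median] + β₂·GGG) maximized by
Newton–Raphson on the Breslow (or Efron) partial likelihood, reporting
logHR with Wald 95% CIs.

A synthetic-cohort generator (`fusionburden.simulate`) produces call
tables, clinical files and ground truth with the structure the analysis
assumes — catalog fusions by prevalence, negative-binomial background
burden, duplicate calls, FFPE age-dependent confidence degradation and
spurious calls, and Weibull proportional-hazards outcomes — so the entire
pipeline is testable without sequencing data.

## Worked example

`examples/04_fusion_burden_prognosis.py` simulates a 332-sample cohort in
which high fusion burden carries a true logHR of 0.7 and runs the full
prognostic analysis:

```
n = 332 samples, median high-confidence burden = 8.0
events: 65
  burden <  median: n=147, 5-year survival 84.2%
  burden >= median: n=185, 5-year survival 72.4%
log-rank: chi2 = 6.12, p = 0.01338
Cox (burden group adjusted for GGG on a continuous scale):
  burden_group  logHR +0.76 (95% CI +0.23, +1.30)  p = 0.00475
  ggg           logHR +0.57 (95% CI +0.39, +0.76)  p = 2.11e-09
```

The high-burden group recurs earlier (lower five-year recurrence-free
survival), the log-rank test rejects equality of the two survival curves,
and the Cox fit recovers the simulated burden effect (+0.76, truth 0.7)
while adjusting for GGG. The other examples cover reading and summarizing
call tables (`01`), cross-cohort candidate ranking on the shipped reference
overlap table (`02`), partner annotation and enrichment (`03`), and the
simulate-then-run-pipeline round trip (`05`).

## Command line

A thin CLI wraps the pipeline: `fusionburden run config.yaml`,
with `summarize`, `crosscohort`, `annotate`, `prognosis` and `simulate`
subcommands and `--min-cohorts`, `--confidence-scope {high_only,combined,all}`,
`--ties {breslow,efron}` flags. The YAML config names per-cohort call and
clinical files, the known-fusion catalog and the gene-annotation table; the
schema is documented in `fusionburden/pipeline.py`. Every run writes a
manifest with input checksums so identical configs reproduce identical
outputs.

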