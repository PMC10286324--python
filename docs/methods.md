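# Methods

## Fusion identity and deduplication

A fusion is identified by the ordered pair of its partner names,
`"G1::G2"`, after normalization: parenthesized groups containing only
digits and commas — the caller's distance annotations, e.g.
`MBTPS2(33,120)` — are removed; all other parentheses are preserved as part
of the symbol. Comma-separated alternative genes on one side (the caller's
unresolved multi-candidate partners) are kept in order as a single
composite partner for identity purposes, and expanded to their member genes
only for classification, promiscuity counting and enrichment. Orientation
is meaningful: `TMPRSS2::ERG` and `ERG::TMPRSS2` are distinct fusions.
Breakpoints are retained for reporting but deliberately excluded from the
identity, because cross-cohort comparison operates at the gene-pair level;
two breakpoint isoforms of one gene pair are one fusion.

When a sample carries multiple calls of the same key, the analysis keeps
the call with the highest confidence (high > medium > low), breaking ties
by total supporting reads — defined as `split_reads1 + split_reads2 +
discordant_mates`, the three read-support columns the caller emits — and
then by first occurrence in file order. The operation is idempotent.

Confidence-level *counts*, in contrast, are taken before deduplication on
distinct (key, level) pairs per sample: a fusion called at two levels in
one sample contributes once to each level. This is the only convention
under which per-level counts can exceed the all-confidence total while each
single level stays below it, which is the arithmetic the per-cohort
accounting requires. Per-sample means divide by the cohort's full sample
count, including samples without calls.

## Cross-cohort matching

Fresh-frozen cohorts act as discovery cohorts: their contribution is the
set of unique high-confidence keys. FFPE confirmation cohorts suffer
age-dependent RNA degradation that demotes true calls to lower confidence,
so their combined set is

    (all-level keys ∩ union of discovery high-confidence keys)
    ∪ (their own high-confidence keys).

"Detected in cohort C" then means membership in C's high-confidence set
(discovery/evaluation) or combined set (confirmation). The overlap table
keeps keys detected in at least `min_cohorts` cohorts (default 2) and sorts
by known-catalog status (unknown first by default; configurable), then
descending cohort count, then re-detection in the confirmation cohort, then
key — all stable. Catalog matching is exact on canonical keys; no fuzzy
gene-pair fallback is applied by default because composite partners make
partial matching ambiguous. Novel candidates are the unknown keys detected
in every cohort.

Concordance with an external per-sample call set (e.g. consortium-published
ERG status) is a 2×2 contingency table over an identical sample universe,
reporting the agreement fraction and the percentage positive per source.

## Annotation

Partner tags come from the gene-annotation table when the symbol is
present (gene class, snoRNA-host links via `host_of`, gene-set labels such
as `ETS_family`); symbol-prefix rules (`SNOR*` → snoRNA, `RNU*` → snRNA,
`RP11`/`CTC-`/`AC0`/`LL0` → clone-derived) apply only to unannotated
symbols, so curated annotation always wins. The shipped ETS-family list is
an editable default of 28 human ETS transcription factors, not asserted
ground truth.

Read-through candidates are fusions whose partners lie on one chromosome
with at most `max_gap_bp` between their spans (0 if overlapping; the
boundary is inclusive). The default of 200 kb is a judgment call — genomic
adjacency has no canonical cutoff — chosen to comfortably cover documented
read-through pairs separated by tens of kilobases while excluding
same-chromosome partners megabases apart.

Promiscuity counts, per gene and side, the number of deduplicated
(sample, fusion) events in which the gene appears: a gene fused to two
different partners in one sample counts twice, the same key twice counts
once. Frequencies divide by cohort sample size; the combined frequency
pools occurrences and sample sizes across cohorts and drives the sort.

Enrichment is the hypergeometric upper tail P(X ≥ k) for drawing k set
members in a query of size n from a universe of size N containing K
members, with Benjamini–Hochberg adjustment across the sets tested in one
call. The universe defaults to all genes in the annotation table; sets are
intersected with the universe, and the query must be contained in it.

## Survival analysis

Samples are dichotomized either at the cohort median burden — group 1 is
`burden ≥ median`, the median being the midpoint of the central order
statistics for even n — or by carrier status of a target fusion within a
confidence scope. Burden scopes: `high_only` (fusions whose best call is
high confidence), `all`, or `combined` (membership in the cross-cohort
combined set, the scope appropriate for FFPE confirmation cohorts, where
raw all-confidence counts are dominated by degradation artifacts).

The Kaplan–Meier estimator is the standard product-limit form with
Greenwood variance; `survival_at(t)` reads the step function at the largest
event time ≤ t. Five-year survival is read at t = 60 with time in months
(the package is unit-agnostic; months are the documented default). The
log-rank test accumulates observed minus hypergeometric-expected events per
group at each distinct event time with the usual covariance, and refers the
quadratic form over g−1 groups to chi-square. Zero total events yields
p = 1 with a warning rather than an error.

Cox regression maximizes the Breslow partial likelihood by default (Efron
available) via Newton–Raphson with analytic gradient and Hessian,
convergence at score norm < 1e-9 within 50 iterations, and step-halving for
non-ascent steps. A step is accepted if it does not decrease the
log-likelihood by more than summation round-off (1e-9·|ℓ|): with thousands
of risk-set terms, genuine improvements near the optimum fall below
absolute float noise, and rejecting them stalls the iteration. Risk-set
sums S0, S1, S2 are read off cumulative sums over descending-time order, so
one evaluation costs O(n·p²) regardless of the number of distinct event
times. Standard errors come from the inverse observed information at the
optimum; CIs are Wald at 95% (±1.96·SE). Covariates are centered
internally for conditioning (estimates are invariant). GGG enters as an
integer 1–5 on a continuous scale. Degenerate fits are flagged rather than
reported: constant covariates and <2 events are errors; non-convergence, a
singular information matrix, or a monotone partial likelihood (detected as
|β| > 20 or SE > 50·max(1, |β|), the signature of score vanishing while β
diverges under complete separation) return a result with no estimates.

The Wilcoxon rank-sum test used for specimen-age comparisons enumerates
all assignments of pooled midranks when both groups have ≤ 10 observations
(exact under ties; two-sided p is the fraction of assignments at least as
far from the null mean as observed) and otherwise uses the normal
approximation with tie and continuity corrections. Specimen-age groups are
empirical tertiles with boundary values assigned to the younger group.

## Synthetic cohorts

The generator emulates the structure of a three-cohort prostate-cancer
study: a deeply sequenced fresh-frozen prostatectomy cohort (n = 40, total
RNA, death-of-disease endpoint), a large fresh-frozen poly(A) cohort
(n = 332), and an FFPE biopsy cohort (n = 176, total RNA). Per sample,
catalog fusions are drawn by prevalence — TMPRSS2::ERG at 0.5, reflecting
its frequency in patients of European descent, plus SLC45A3::ELK4 (0.10),
TTC6::MIPOL1 (0.05), AMACR::AMACR (0.04) and MBTPS2,LL0XNC01-39B3.1::SMS
(0.03) — and background fusions are random ordered gene pairs, distinct
within a sample, with a negative-binomial count (mean λ of 59, 39 and 40
respectively; overdispersion 0.4) chosen to match the observed per-sample
call scale and its long right tail, which a Poisson model would miss. Each
true fusion is emitted once plus a duplicate with probability 0.3, with
independent confidence draws, so deduplication is genuinely exercised.

Confidence probabilities are keyed by preservation: (0.21, 0.30, 0.49) for
fresh-frozen — matching the observed high/medium/low mix — and
(0.085, 0.30, 0.615) for FFPE at the youngest specimen age. FFPE specimen
ages are uniform on 4.5–11.1 years; each year of storage moves 0.013 of
probability mass from high to low (floor 0.002 on high), and spurious
low-confidence calls arrive as Poisson(ρ·age·λ) with ρ = 1.8 per year per
unit of λ. These three numbers were set so that simulated FFPE cohorts
reproduce the reported study-scale behaviour: per-sample totals near 600,
and young-versus-old tertile means of high-confidence calls near 2–4 versus
under 1. Degradation deliberately affects only how fusions are *called*
(confidence, read support — FFPE read supports are scaled by 0.4 — and
spurious additions), never which fusions are truly present.

Outcomes follow a Weibull proportional-hazards model: T = s·(−log U /
exp(η))^{1/k} with shape k = 1.5, scale s = 360 months, η = β₁·1[true
burden ≥ cohort median] + β₂·(GGG − 1), β₁ = 0.7, β₂ = 0.6 (the reported
burden and GGG logHRs fall in 0.5–0.8), GGG drawn categorically with
probabilities (0.3, 0.3, 0.2, 0.1, 0.1), and independent uniform censoring
on (0, 120) months, giving roughly 30% events. One global seed drives
everything; per-cohort streams are spawned deterministically from it, and
identical seeds reproduce byte-identical output files.

What the generator does *not* emulate: breakpoint sequence context,
expression levels, correlated fusion co-occurrence, batch effects, tumor
cell content effects (TCC is drawn but inert), or inter-cohort biological
differences beyond preservation and library. Passing tests therefore
demonstrate that the pipeline's logic and statistics behave correctly under
the stated generative assumptions — dedup exactness, degradation
direction, effect recovery, error calibration — not that any biological
conclusion transfers to real cohorts.

## Test and verification sizes

The suite checks survival operations against independent routes: a
10,000-permutation oracle for the log-rank p at n = 10, hand product-limit
values for KM, lifelines as an external cross-check for KM/log-rank/Efron-
Cox, the analytic identity between the Cox score test and the log-rank
statistic on untied data, and seeded recovery simulations (β within 3 SE at
n = 2000; type-I error over 400 null replicates at n = 150; CI coverage
over 200 replicates at n = 300 with scale 380 for ~30% events). Rank-sum
and hypergeometric results are compared to exhaustive enumeration for small
groups and universes ≤ 20. Simulation-based tests use cohorts of 20–2000
samples with λ between 3 and 59, sizes chosen to keep the full suite under
a minute of statistical computation while leaving Monte-Carlo error well
inside the asserted bounds.

## Known limitations

- Fusion identity ignores breakpoints; isoform-level questions are out of
  scope.
- Catalog matching is exact-string; renamed or aliased gene symbols must be
  harmonized upstream.
- The Cox implementation covers right censoring, Breslow/Efron ties and
  Wald inference only — no stratification, time-varying covariates,
  robust variance or proportional-hazards diagnostics.
- The log-rank p relies on the chi-square approximation; for very small
  groups an exact permutation approach (as used in the tests) is
  preferable.
- The specimen-age model is linear in age with uniform ages; real FFPE
  archives have skewed age distributions and nonlinear degradation.
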