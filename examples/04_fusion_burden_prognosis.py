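"""Fusion burden as a prognostic marker: KM, log-rank and adjusted Cox.

Simulates a TCGA-sized cohort in which a high true fusion burden carries a
logHR of 0.7 for biochemical recurrence on top of a GGG effect, then runs
the full prognostic analysis: per-sample burden, dichotomization at the
cohort median, Kaplan-Meier five-year survival per group, the log-rank
test, and Cox regression adjusted for GGG.
"""

from fusionburden import (
    GroupingSpec,
    SimConfig,
    assign_groups,
    burden_survival_analysis,
    per_sample_burden,
    simulate_cohort,
)

sim = simulate_cohort(SimConfig(seed=42), "TCGA_PRAD")
burdens = per_sample_burden(sim.call_set(), "high_only", sim.clinical)
print(f"n = {len(sim.clinical)} samples, median high-confidence burden = {burdens.median_burden}")

groups = assign_groups(GroupingSpec("burden_median"), burdens=burdens)
result = burden_survival_analysis(sim.clinical, groups, ties="breslow")

print(f"events: {result['n_events']}")
for label, km in sorted(result["km"].items()):
    name = "burden >= median" if label else "burden <  median"
    print(f"  {name}: n={km['n']}, 5-year survival {km['five_year_survival']:.1%}")

lr = result["logrank"]
print(f"log-rank: chi2 = {lr['chi_square']:.2f}, p = {lr['p']:.4g}")

print("Cox (burden group adjusted for GGG on a continuous scale):")
for row in result["cox"]["coefficients"]:
    print(
        f"  {row['covariate']:13s} logHR {row['logHR']:+.2f} "
        f"(95% CI {row['ci_low']:+.2f}, {row['ci_high']:+.2f})  p = {row['p']:.3g}"
    )
print("\nA positive burden-group logHR that persists after GGG adjustment is")
print("the signature the analysis is designed to detect (truth here: 0.7).")
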