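"""A full gene-prioritization run on a synthetic cohort.

Simulates 300 genes of rare variants for 400 fully genotyped cases and
8000 summary-count controls, plants one risk gene with carrier odds ratio
8, and runs the whole pipeline: consistent QC, joint-AF filtering,
category selection, carrier counting, exact tests, inflation factor and
resampling-based FDR.
"""

from raresum import RunConfig, SimSpec, run_burden, simulate_cohort

spec = SimSpec(
    n_genes=300,
    variants_per_gene=4,
    n_cases={"nfe": 400},
    n_controls={"nfe": 8000},
    risk_genes={"G0123": 8.0},
    seed=11,
)
sim = simulate_cohort(spec)

cfg = RunConfig(models=("DOM",), fdr_method="RBH_UL", seed=1)
res = run_burden(
    sim.cases,
    sim.control_summaries,
    cfg,
    case_coverage=sim.case_coverage,
    control_coverage=sim.control_coverage,
)

dom = res.results[res.results.model == "DOM"]
print("top 5 genes (dominant model):")
print(
    dom.head(5)[
        ["gene", "n1", "n2", "n3", "n4", "p_value", "odds_ratio", "p_adjusted"]
    ].to_string(index=False)
)
print(f"\nlambda_emp = {res.lambdas['DOM'].value:.3f} (≈1: no systematic inflation)")
print(f"variant attrition by stage: {res.filter_log.attrition()}")
print(
    "\nn1/n2: cases with/without qualifying alleles; n3/n4: the same for"
    "\nsummary-count controls (estimated). The planted gene G0123 should"
    "\ntop the table with adjusted P < 0.05."
)
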