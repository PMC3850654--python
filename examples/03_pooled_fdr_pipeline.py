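"""Run the pooled FDR pipelines (region-specific vs single-HMM) once.

Two chromosomes, two regions each (the region-2 dynamics are perturbed
by upsilon1 = 0.15), nominal FDR level alpha = 0.1.  RSPLIS partitions
each chromosome before fitting; PLIS fits one HMM per chromosome.  Both
pool the per-SNP LIS statistics and reject the longest prefix of the
ranking whose running mean stays below alpha.
"""

from rsplis import (
    AnalysisConfig,
    evaluate_decisions,
    make_scenario,
    plis_run,
    rsplis_run,
    simulate_scenario,
)

scenario = make_scenario("case1", upsilon1=0.15, mu_base=1.0)
chromosomes = simulate_scenario(scenario, seed=5)
truth = {z.chrom: z.theta_truth for z in chromosomes}
config = AnalysisConfig(K_max=4, m_max=3, h=2, alpha=0.1)

for name, runner in (("RSPLIS", rsplis_run), ("PLIS", plis_run)):
    result = runner(chromosomes, alpha=0.1, config=config, seed=17)
    fdp, fnp, sens = evaluate_decisions(result, truth)
    print(f"{name}: rejected {result.l_cut} of {len(result.records)} SNPs | "
          f"FDP = {fdp:.3f}, FNR = {fnp:.4f}, sensitivity = {sens:.3f}")
print("FDP fluctuates around the nominal 0.1 on single replications;")
print("the region-specific fit should accept fewer true signals (lower FNR).")
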