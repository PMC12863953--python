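"""Simulate a herd with a liability-model binary defect.

Builds a three-generation population of 600 animals with a defect of 6%
prevalence and liability-scale heritability 0.35, partial genotyping at
150 SNPs, and prints what the generative truth looks like.
"""

import liabel as lb

cfg = lb.SimConfig(n_founders=200, n_generations=3, n_snps=150, seed=7)
pop = lb.simulate_population(cfg)

print(f"animals:            {len(pop.pedigree)}")
print(f"genotyped:          {pop.genotypes.n_animals} x {pop.genotypes.n_snps} SNPs")
print(f"realized prevalence: {pop.phenotypes['y'].mean():.3f} (target {cfg.prevalence})")
print(f"founder BV variance: {pop.true_bv[pop.pedigree.query('generation==0')['animal']].var():.3f}"
      f" (target h2_l = {cfg.h2_liability})")
print(f"liability threshold: {pop.true_params['threshold']:.3f} = Phi^-1(1 - alpha)")
# The phenotype is the indicator that the standardized liability
# (breeding value + residual) exceeds the threshold.
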