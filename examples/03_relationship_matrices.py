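"""Pedigree, genomic, and single-step relationship matrices.

Builds A by the tabular method, G from centred gene contents, blends G
with the pedigree relationships of the genotyped animals, and assembles
the single-step H^-1.
"""

import numpy as np

import liabel as lb

pop = lb.simulate_population(lb.SimConfig(n_founders=200, n_generations=3, n_snps=150, seed=7))

A = lb.build_A(pop.pedigree)
G = lb.build_G(pop.genotypes)
A22 = A.subset(pop.genotypes.ids, "A22")
hinv = lb.h_inverse_single_step(A, G, blend_weight=0.95)

print(f"A:  {A.n} x {A.n}, mean diagonal {np.diag(A.values).mean():.4f} (1 + mean F)")
print(f"G:  {G.n} x {G.n}, mean diagonal {np.diag(G.values).mean():.4f}")
print(f"A22 mean diagonal:  {np.diag(A22.values).mean():.4f}")
print(f"H^-1 assembled for {hinv.n} animals "
      f"({G.n} genotyped get the G^-1 - A22^-1 increment)")
# Close agreement between mean diag(G) and mean diag(A22) indicates the
# genomic and pedigree relationships are on a compatible scale.
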