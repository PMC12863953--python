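"""Phenotypic and genomic QC on a simulated herd.

Removes undersized and invariant contemporary groups, keeps the largest
sire-connected CG network, filters SNPs on HWE / call rate / MAF, and
prints the report tallies.
"""

import liabel as lb

pop = lb.simulate_population(lb.SimConfig(n_founders=200, n_generations=3, n_snps=150,
                                          n_cgs=40, seed=7))
phen, report = lb.filter_cgs(pop.phenotypes, min_size=10)
phen, report = lb.check_connectedness(phen, pop.pedigree, report=report)
geno, report = lb.genotype_qc(pop.genotypes, report=report)

print(f"CGs in/out:            {report.cgs_in} -> {report.cgs_out}")
print(f"  removed by size:     {report.cgs_removed_size}")
print(f"  removed no-variance: {report.cgs_removed_no_variability}")
print(f"  removed disconnected:{report.cgs_removed_disconnected}")
print(f"records kept:          {report.records_out} of {report.records_in}")
print(f"SNPs kept:             {report.snps_out} of {report.snps_in} "
      f"(HWE {report.snps_removed_hwe}, call rate {report.snps_removed_call_rate}, "
      f"MAF {report.snps_removed_maf})")
# Groups without case/control contrast carry no information about a
# binary trait; disconnected groups would confound CG and genetic effects.
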