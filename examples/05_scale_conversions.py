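"""Heritability and breeding-value scale conversions on published data.

Applies the Dempster-Lerner formula to the bundled summary of a large
Nellore defect evaluation, then shows the threshold-density adjustment
and the probability transform on a small set of breeding values.
"""

import numpy as np
import pandas as pd

import liabel as lb
from liabel.containers import GEBVTable

summary = lb.nellore_defect_summary()
print("trait             prevalence   h2_liability -> h2_observed")
for trait, row in summary.iterrows():
    h2_o = lb.h2_liability_to_observed(row.h2_liability, row.prevalence)
    print(f"{trait:16s}  {100 * row.prevalence:6.2f}%      {row.h2_liability:.2f}  ->  {h2_o:.2f}")

# observed-scale GEBVs for five sires of a 6%-prevalence defect
alpha, h2_l = 0.06, 0.35
h2_o = lb.h2_liability_to_observed(h2_l, alpha)
bv_o = GEBVTable(pd.Series([-0.04, -0.01, 0.0, 0.02, 0.05], index=list("abcde")),
                 scale="observed", model="linear")
bv_l = lb.gebv_threshold_density_adjust(bv_o, h2_o, h2_l, alpha)
prob = lb.gebv_to_probability(bv_l, alpha)
print(f"\nthreshold-density scaling factor z* = {bv_l.meta['z_star']:.4f} "
      f"(= normal ordinate at the threshold)")
print("sire  BV_observed  BV_liability  P(defect)")
for sire in bv_o.ids:
    print(f"  {sire}   {bv_o.values[sire]:+.3f}       {bv_l.values[sire]:+.3f}        "
          f"{prob.values[sire]:.3f}")
# Probabilities rise monotonically with liability GEBV; the average sire
# sits at the trait prevalence.
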