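"""Published summary statistics bundled for worked examples.

``nellore_defect_summary`` ships the post-QC record counts, defect
counts, liability-scale heritability estimates (threshold model), and
sire-selection tallies from a large published single-step genetic
evaluation of seven morphological defects in Nellore cattle. The raw
records are proprietary; these per-trait summaries are the printed,
public numbers and are the inputs for the scale-conversion and
selection-bookkeeping examples.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["nellore_defect_summary"]

_ROWS = [
    # trait, n_records, n_defect, n_cgs, h2_liability, n_sires, n_both_selected
    ("depigmentation", 182_964, 11_310, 5_629, 0.54, 1_338, 106),
    ("feet_and_legs", 108_782, 8_098, 3_534, 0.23, 987, 24),
    ("chamfer", 118_354, 5_972, 3_628, 0.18, 1_050, 74),
    ("loin", 81_818, 3_894, 2_488, 0.37, 804, 65),
    ("hump", 60_188, 3_363, 1_857, 0.35, 637, 47),
    ("jaw", 38_105, 1_613, 1_201, 0.26, 463, 31),
    ("navel", 13_745, 665, 456, 0.50, 219, 17),
]


def nellore_defect_summary() -> pd.DataFrame:
    """Per-trait summary of a published Nellore defect evaluation.

    Columns: ``n_records`` and ``n_defect`` (post-QC record and affected
    counts, so prevalence = n_defect / n_records), ``n_cgs``
    (contemporary groups retained), ``h2_liability`` (posterior-mean
    liability-scale heritability from the threshold model), ``n_sires``
    (sires with >= 10 phenotyped offspring entering selection), and
    ``n_both_selected`` (sires in the top 10% under both the linear and
    threshold model).
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "trait", "n_records", "n_defect", "n_cgs",
            "h2_liability", "n_sires", "n_both_selected",
        ],
    ).set_index("trait")
    df["prevalence"] = df["n_defect"] / df["n_records"]
    return df
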