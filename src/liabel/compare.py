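"""Model-comparison analytics: sire selection concordance and
GEBV-correlation proxies for genetic correlations.

Selection studies on binary defect traits restrict attention to sires
with enough phenotyped offspring (default 10), select the top fraction
(default 10%, ceiling convention) of the most desirable GEBVs under each
model, and classify every sire as selected by both models, by one only,
or by neither. Genetic correlations among traits are approximated by
Pearson correlations among GEBVs over a common sire set — a proxy used
when multi-trait models cannot be fitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GEBVTable

__all__ = [
    "eligible_sires",
    "select_top",
    "ConcordanceReport",
    "concordance",
    "spearman",
    "gebv_correlation_matrix",
]


def eligible_sires(
    pedigree: pd.DataFrame,
    phenotypes: pd.DataFrame,
    min_offspring: int = 10,
) -> pd.DataFrame:
    """Sires with at least ``min_offspring`` phenotyped offspring.

    Returns a DataFrame (sire, n_offspring) sorted by sire id; empty
    with a warning when no sire qualifies.
    """
    sire_of = dict(zip(pedigree["animal"], pedigree["sire"]))
    sires = phenotypes["animal"].map(sire_of)
    counts = sires[sires.notna() & (sires != 0)].value_counts()
    out = (
        counts[counts >= min_offspring]
        .rename("n_offspring")
        .rename_axis("sire")
        .reset_index()
        .sort_values("sire", ignore_index=True)
    )
    if out.empty:
        warnings.warn(f"no sires with >= {min_offspring} phenotyped offspring")
    return out


def select_top(
    gebvs: GEBVTable | pd.Series,
    fraction: float = 0.10,
    direction: str = "desirable_low",
) -> list:
    """Ids of the k = ceil(fraction * n) most desirable values.

    For defect traits the desirable extreme is the *lowest* GEBV
    (smallest defect liability); ``direction="desirable_high"`` flips
    this. Ties are broken by id order, deterministically.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if direction not in ("desirable_low", "desirable_high"):
        raise ValueError(f"unknown direction {direction!r}")
    values = gebvs.values if isinstance(gebvs, GEBVTable) else pd.Series(gebvs)
    k = math.ceil(fraction * len(values))
    ascending = direction == "desirable_low"
    ordered = values.sort_index().sort_values(ascending=ascending, kind="stable")
    return list(ordered.index[:k])


@dataclass
class ConcordanceReport:
    """Four-way selection classification across two models."""

    n_sires: int
    k: int
    both: int
    linear_only: int
    threshold_only: int
    neither: int
    spearman_all: float | None = None
    spearman_selected: float | None = None

    def __post_init__(self) -> None:
        assert self.both + self.linear_only == self.k
        assert self.both + self.threshold_only == self.k
        assert self.both + self.linear_only + self.threshold_only + self.neither == self.n_sires

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("zero rank variance: Spearman correlation undefined")
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def concordance(
    sel_linear,
    sel_threshold,
    all_sires,
    gebv_pairs: tuple[pd.Series, pd.Series] | None = None,
) -> ConcordanceReport:
    """Classify sires by selection status under the two models.

    ``gebv_pairs`` (linear, threshold series over the eligible sires)
    adds Spearman correlations over the whole eligible set and over the
    union of selected sires.
    """
    sel_l, sel_t, universe = set(sel_linear), set(sel_threshold), set(all_sires)
    if len(sel_l) != len(sel_t):
        raise ValueError(
            f"selection sizes differ: {len(sel_l)} (linear) vs {len(sel_t)} (threshold)"
        )
    if not (sel_l <= universe and sel_t <= universe):
        raise ValueError("selections must be subsets of all_sires")
    k = len(sel_l)
    both = len(sel_l & sel_t)
    rep = ConcordanceReport(
        n_sires=len(universe),
        k=k,
        both=both,
        linear_only=k - both,
        threshold_only=k - both,
        neither=len(universe) - (2 * k - both),
    )
    if gebv_pairs is not None:
        lin, thr = gebv_pairs
        common = lin.index.intersection(thr.index)
        rep.spearman_all = spearman(lin[common], thr[common])
        chosen = [s for s in common if s in (sel_l | sel_t)]
        if len(chosen) >= 3:
            rep.spearman_selected = spearman(lin[chosen], thr[chosen])
    return rep


def gebv_correlation_matrix(
    tables: dict, common_set
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of GEBVs over a common sire set.

    ``tables`` maps trait name to a :class:`GEBVTable` (or Series).
    Returns (correlation matrix, per-cell sample sizes).
    """
    ids = list(common_set)
    if len(ids) < 3:
        raise ValueError(f"common sire set too small: {len(ids)} < 3")
    cols = {}
    for trait, table in tables.items():
        values = table.values if isinstance(table, GEBVTable) else pd.Series(table)
        missing = set(ids) - set(values.index)
        if missing:
            raise ValueError(f"trait {trait!r} missing sires: {sorted(missing)[:5]}")
        cols[trait] = values[ids].to_numpy()
    frame = pd.DataFrame(cols, index=ids)
    corr = frame.corr(method="pearson")
    n = pd.DataFrame(len(ids), index=corr.index, columns=corr.columns)
    return corr, n
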