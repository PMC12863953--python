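"""Phenotypic and genomic quality control.

Phenotypic QC follows the fixed order used in routine evaluations of
binary defect traits: contemporary groups (CGs) smaller than a minimum
size are dropped, CGs without phenotypic variability (all 0 or all 1)
are dropped, and finally CGs disconnected from the main genetic network
are dropped. Genomic QC removes SNPs failing Hardy-Weinberg equilibrium
(asymptotic one-degree-of-freedom chi-square), call rate, or minor
allele frequency thresholds, then mean-imputes remaining missing gene
contents to twice the allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

from .containers import GenotypeMatrix

__all__ = [
    "QCReport",
    "build_contemporary_groups",
    "filter_cgs",
    "check_connectedness",
    "genotype_qc",
]

logger = logging.getLogger(__name__)

CG_SEPARATOR = "|"


class NoAnalyzableDataError(ValueError):
    """Raised when QC removes every record."""


@dataclass
class QCReport:
    """Tallies of what each filter removed and what survived."""

    cgs_removed_size: int = 0
    cgs_removed_no_variability: int = 0
    cgs_removed_disconnected: int = 0
    records_removed: int = 0
    records_missing_factors: int = 0
    records_missing_pedigree: int = 0
    snps_removed_hwe: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    cgs_in: int = 0
    cgs_out: int = 0
    records_in: int = 0
    records_out: int = 0
    snps_in: int = 0
    snps_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_contemporary_groups(
    records: pd.DataFrame, factor_columns: list[str]
) -> pd.Series:
    """CG label per record: ordered concatenation of the factor levels.

    Records with a missing factor value are excluded (logged); identical
    factor combinations always map to identical labels.
    """
    missing_cols = [c for c in factor_columns if c not in records.columns]
    if missing_cols:
        raise KeyError(f"factor columns absent from records: {missing_cols}")
    sub = records[factor_columns]
    ok = sub.notna().all(axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("build_contemporary_groups: excluded %d records with missing factors", n_bad)
    labels = (
        sub[ok].astype(str).agg(CG_SEPARATOR.join, axis=1)
    )
    labels.name = "cg"
    return labels


def filter_cgs(
    phenotypes: pd.DataFrame,
    min_size: int = 10,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop CGs with fewer than ``min_size`` records or no variability.

    ``phenotypes`` needs columns ``animal``, ``cg``, ``y`` with y in
    {0, 1}. Size is filtered before variability, matching the fixed
    filter order.
    """
    rep = report or QCReport()
    y = phenotypes["y"]
    if not y.isin((0, 1)).all():
        bad = y[~y.isin((0, 1))].iloc[0]
        raise ValueError(f"phenotypes must be coded 0/1, found {bad!r}")
    rep.records_in = rep.records_in or len(phenotypes)
    sizes = phenotypes.groupby("cg")["y"].size()
    rep.cgs_in = rep.cgs_in or len(sizes)
    big = sizes[sizes >= min_size].index
    rep.cgs_removed_size = len(sizes) - len(big)
    kept = phenotypes[phenotypes["cg"].isin(big)]
    means = kept.groupby("cg")["y"].mean()
    variable = means[(means > 0.0) & (means < 1.0)].index
    rep.cgs_removed_no_variability = len(big) - len(variable)
    out = kept[kept["cg"].isin(variable)].reset_index(drop=True)
    rep.records_removed += len(phenotypes) - len(out)
    rep.records_out = len(out)
    rep.cgs_out = len(variable)
    logger.info(
        "filter_cgs: removed %d CGs by size, %d for no variability (%d records dropped)",
        rep.cgs_removed_size, rep.cgs_removed_no_variability, len(phenotypes) - len(out),
    )
    if out.empty:
        raise NoAnalyzableDataError("no analyzable data: all CGs removed by size/variability filters")
    return out, rep


def check_connectedness(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    min_links: int = 1,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Keep only CGs in the largest sire-connected component.

    CGs are graph nodes; two CGs are joined when they share at least
    ``min_links`` sires of phenotyped animals. Records whose animal is
    absent from the pedigree are excluded first (logged).
    """
    rep = report or QCReport()
    sire_of = dict(zip(pedigree["animal"], pedigree["sire"]))
    known = phenotypes["animal"].map(lambda a: a in sire_of)
    rep.records_missing_pedigree = int((~known).sum())
    if rep.records_missing_pedigree:
        logger.info(
            "check_connectedness: excluded %d records not in pedigree",
            rep.records_missing_pedigree,
        )
    phen = phenotypes[known].copy()
    phen["_sire"] = phen["animal"].map(sire_of)
    cg_sires = (
        phen[phen["_sire"] != 0].groupby("cg")["_sire"].agg(set).to_dict()
    )
    graph = nx.Graph()
    all_cgs = list(dict.fromkeys(phen["cg"]))
    graph.add_nodes_from(all_cgs)
    items = [(c, cg_sires.get(c, set())) for c in all_cgs]
    for i, (ci, si) in enumerate(items):
        for cj, sj in items[i + 1:]:
            if len(si & sj) >= min_links:
                graph.add_edge(ci, cj)
    components = list(nx.connected_components(graph))
    sizes = phen.groupby("cg").size()
    # largest component by record count; deterministic tie-break by labels
    best = max(
        components,
        key=lambda c: (sum(sizes.get(g, 0) for g in c), len(c), tuple(sorted(c))),
    )
    rep.cgs_removed_disconnected = len(all_cgs) - len(best)
    out = phen[phen["cg"].isin(best)].drop(columns="_sire").reset_index(drop=True)
    rep.records_removed += len(phenotypes) - len(out)
    rep.records_out = len(out)
    rep.cgs_out = len(best)
    logger.info(
        "check_connectedness: removed %d disconnected CGs", rep.cgs_removed_disconnected
    )
    if out.empty:
        raise NoAnalyzableDataError("no analyzable data: all CGs disconnected")
    return out, rep


def genotype_qc(
    genotypes: GenotypeMatrix,
    hwe_p: float = 1e-15,
    min_call_rate: float = 0.90,
    min_maf: float = 0.02,
    min_animal_call_rate: float | None = None,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """SNP filters: HWE p < ``hwe_p``, call rate < ``min_call_rate``,
    MAF < ``min_maf``; then mean imputation of missing entries to 2p.

    The HWE test is the asymptotic 1-df chi-square comparing observed
    genotype counts with Hardy-Weinberg expectation at the observed
    allele frequency. An animal call-rate filter is available but off by
    default. A SNP failing several criteria is attributed to the first
    in the order HWE, call rate, MAF. Idempotent on clean data.
    """
    rep = report or QCReport()
    M = genotypes.matrix
    if min_animal_call_rate is not None:
        acr = 1.0 - np.isnan(M).mean(axis=1)
        keep_animals = acr >= min_animal_call_rate
        ids = [a for a, k in zip(genotypes.ids, keep_animals) if k]
        genotypes = genotypes.subset_animals(ids)
        M = genotypes.matrix
    n_obs = (~np.isnan(M)).sum(axis=0).astype(float)
    call_rate = genotypes.call_rate_snp()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = genotypes.allele_frequencies()
        maf = np.minimum(p, 1.0 - p)
        n2 = np.nansum(M == 2.0, axis=0).astype(float)
        n1 = np.nansum(M == 1.0, axis=0).astype(float)
        n0 = n_obs - n1 - n2
        e0 = n_obs * (1.0 - p) ** 2
        e1 = n_obs * 2.0 * p * (1.0 - p)
        e2 = n_obs * p**2
        stat = np.zeros(genotypes.n_snps)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            contrib = np.where(exp > 0.0, (obs - exp) ** 2 / np.where(exp > 0.0, exp, 1.0), 0.0)
            stat += contrib
    pvals = chi2.sf(stat, df=1)
    fail_hwe = pvals < hwe_p
    fail_cr = call_rate < min_call_rate
    fail_maf = ~(maf >= min_maf)  # NaN maf (no calls) fails too
    rep.snps_in = rep.snps_in or genotypes.n_snps
    rep.snps_removed_hwe = int(fail_hwe.sum())
    rep.snps_removed_call_rate = int((fail_cr & ~fail_hwe).sum())
    rep.snps_removed_maf = int((fail_maf & ~fail_hwe & ~fail_cr).sum())
    keep = ~(fail_hwe | fail_cr | fail_maf)
    if not keep.any():
        raise NoAnalyzableDataError("genotype_qc removed every SNP")
    out = genotypes.subset_snps(keep)
    # mean imputation to 2p on the surviving SNPs
    Mo = out.matrix.copy()
    po = out.allele_frequencies()
    nan_r, nan_c = np.where(np.isnan(Mo))
    Mo[nan_r, nan_c] = 2.0 * po[nan_c]
    out = GenotypeMatrix(out.ids, out.snp_ids, Mo)
    rep.snps_out = out.n_snps
    logger.info(
        "genotype_qc: removed %d SNPs (HWE %d, call rate %d, MAF %d); %d retained",
        rep.snps_in - rep.snps_out, rep.snps_removed_hwe,
        rep.snps_removed_call_rate, rep.snps_removed_maf, rep.snps_out,
    )
    return out, rep
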