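"""Contemporary-group and SNP quality control."""

import numpy as np
import pandas as pd
import pytest

import liabel as lb
from liabel.containers import GenotypeMatrix
from liabel.qc import NoAnalyzableDataError, build_contemporary_groups


def phen_frame(cgs_and_ys, start_id=1):
    """Build a phenotype frame from {cg_label: [y values]}."""
    rows = []
    i = start_id
    for cg, ys in cgs_and_ys.items():
        for y in ys:
            rows.append((i, cg, y))
            i += 1
    return pd.DataFrame(rows, columns=["animal", "cg", "y"])


class TestBuildContemporaryGroups:
    def test_single_factor(self):
        df = pd.DataFrame({"farm": ["A", "B", "A", "B"]})
        labels = build_contemporary_groups(df, ["farm"])
        assert labels.nunique() == 2

    def test_identical_combinations_share_label(self):
        df = pd.DataFrame({"year": [2020, 2020], "sex": ["M", "M"], "farm": [7, 7]})
        labels = build_contemporary_groups(df, ["year", "sex", "farm"])
        assert labels.iloc[0] == labels.iloc[1]

    def test_balanced_crossing_count(self):
        # 3 binary factors fully crossed, 10 records per cell: 8 CGs of 10
        cells = [(y, s, f) for y in (2020, 2021) for s in "MF" for f in (1, 2)]
        df = pd.DataFrame(
            [c for c in cells for _ in range(10)], columns=["year", "sex", "farm"]
        )
        labels = build_contemporary_groups(df, ["year", "sex", "farm"])
        assert labels.nunique() == 8
        assert (labels.value_counts() == 10).all()

    def test_missing_factor_excluded(self):
        df = pd.DataFrame({"farm": ["A", None, "B"]})
        labels = build_contemporary_groups(df, ["farm"])
        assert len(labels) == 2


class TestFilterCGs:
    def test_small_cg_removed(self):
        phen = phen_frame({"small": [0, 1] * 4 + [0], "big": [0, 1] * 6})
        out, rep = lb.filter_cgs(phen, min_size=10)
        assert set(out["cg"]) == {"big"}
        assert rep.cgs_removed_size == 1

    def test_no_variability_removed(self):
        phen = phen_frame({"allzero": [0] * 50, "mixed": [0, 1] * 10})
        out, rep = lb.filter_cgs(phen)
        assert set(out["cg"]) == {"mixed"}
        assert rep.cgs_removed_no_variability == 1

    def test_clean_data_untouched(self):
        phen = phen_frame({"a": [0, 1] * 5, "b": [0, 1] * 6})
        out, rep = lb.filter_cgs(phen)
        assert len(out) == len(phen)
        assert rep.cgs_removed_size == rep.cgs_removed_no_variability == 0
        # idempotence
        out2, _ = lb.filter_cgs(out)
        pd.testing.assert_frame_equal(out, out2)

    def test_tallies_conserved(self):
        phen = phen_frame({"s": [0, 1], "z": [0] * 12, "ok": [0, 1] * 6})
        out, rep = lb.filter_cgs(phen)
        assert rep.cgs_out + rep.cgs_removed_size + rep.cgs_removed_no_variability == rep.cgs_in
        assert rep.records_out + rep.records_removed == rep.records_in

    def test_everything_removed_raises(self):
        with pytest.raises(NoAnalyzableDataError):
            lb.filter_cgs(phen_frame({"tiny": [0, 1]}))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            lb.filter_cgs(phen_frame({"a": [0, 2] * 6}))


def chain_pedigree(phen, sire_map):
    """Pedigree giving each animal the sire from ``sire_map[cg]``."""
    rows = [(s, 0, 0) for s in set(sire_map.values()) if s != 0]
    for rec in phen.itertuples(index=False):
        rows.append((rec.animal, sire_map[rec.cg], 0))
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


class TestConnectedness:
    def test_single_sire_fully_connected(self):
        phen = phen_frame({"a": [0, 1] * 5, "b": [1, 0] * 5})
        ped = chain_pedigree(phen, {"a": 900, "b": 900})
        out, rep = lb.check_connectedness(phen, ped)
        assert len(out) == len(phen)
        assert rep.cgs_removed_disconnected == 0

    def test_disjoint_cluster_removed(self):
        phen = phen_frame({"a": [0, 1] * 8, "b": [0, 1] * 8, "c": [0, 1] * 3})
        ped = chain_pedigree(phen, {"a": 900, "b": 900, "c": 901})
        out, rep = lb.check_connectedness(phen, ped)
        assert set(out["cg"]) == {"a", "b"}
        assert rep.cgs_removed_disconnected == 1

    def test_chain_reachability(self):
        """CG1-CG2-CG3 connected through shared sires without a direct CG1-CG3 link."""
        rows = []
        i = 1
        for cg, sires in (("cg1", [901, 901]), ("cg2", [901, 902]), ("cg3", [902, 902])):
            for s in sires:
                rows.append((i, cg, s))
                i += 1
        phen = pd.DataFrame([(r[0], r[1], 0) for r in rows], columns=["animal", "cg", "y"])
        ped = pd.DataFrame(
            [(901, 0, 0), (902, 0, 0)] + [(r[0], r[2], 0) for r in rows],
            columns=["animal", "sire", "dam"],
        )
        out, rep = lb.check_connectedness(phen, ped)
        assert set(out["cg"]) == {"cg1", "cg2", "cg3"}

    def test_missing_pedigree_record_excluded(self):
        phen = phen_frame({"a": [0, 1] * 5})
        ped = chain_pedigree(phen.iloc[:-1], {"a": 900})
        out, rep = lb.check_connectedness(phen, ped)
        assert rep.records_missing_pedigree == 1
        assert len(out) == len(phen) - 1


class TestGenotypeQC:
    def test_monomorphic_removed(self):
        g = GenotypeMatrix(list(range(20)), ["fix", "ok"],
                           np.column_stack([np.zeros(20), [0, 1, 2, 1] * 5]))
        out, rep = lb.genotype_qc(g)
        assert out.snp_ids == ["ok"]
        assert rep.snps_removed_maf == 1

    def test_low_call_rate_removed(self):
        col = np.array([0, 1, 2, 1] * 5, dtype=float)
        half_missing = col.copy()
        half_missing[::2] = np.nan
        g = GenotypeMatrix(list(range(20)), ["half", "ok"],
                           np.column_stack([half_missing, col]))
        out, rep = lb.genotype_qc(g)
        assert out.snp_ids == ["ok"]
        assert rep.snps_removed_call_rate == 1

    def test_complete_heterozygosity_fails_hwe(self):
        # all 1000 animals heterozygous: chi-square = n = 1000, p << 1e-15
        ok = np.resize([0.0, 1.0, 2.0, 1.0], 1000)
        g = GenotypeMatrix(list(range(1000)), ["het", "ok"],
                           np.column_stack([np.ones(1000), ok]))
        out, rep = lb.genotype_qc(g)
        assert out.snp_ids == ["ok"]
        assert rep.snps_removed_hwe == 1

    def test_imputation_fills_missing_with_mean_dosage(self):
        # 10% missing keeps the SNP above the 0.90 call-rate threshold
        col = np.array([0, 1, 2, 1, 1, 0, 1, 2, 1, np.nan] * 4, dtype=float)
        g = GenotypeMatrix(list(range(40)), ["s"], col[:, None])
        out, _ = lb.genotype_qc(g)
        filled = out.matrix[np.isnan(col), 0]
        p = np.nanmean(col) / 2
        assert np.allclose(filled, 2 * p)

    def test_idempotent_and_tallies(self, small_population):
        out1, rep1 = lb.genotype_qc(small_population.genotypes)
        out2, rep2 = lb.genotype_qc(out1)
        assert out1.snp_ids == out2.snp_ids
        assert np.allclose(out1.matrix, out2.matrix)
        removed = rep1.snps_removed_hwe + rep1.snps_removed_call_rate + rep1.snps_removed_maf
        assert rep1.snps_in == rep1.snps_out + removed

    def test_all_removed_raises(self):
        g = GenotypeMatrix([1, 2], ["a"], [[0.0], [0.0]])
        with pytest.raises(NoAnalyzableDataError):
            lb.genotype_qc(g)
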