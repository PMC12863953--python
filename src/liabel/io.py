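"""File dialects: pedigree/phenotype CSV, genotype matrix, GEBV tables.

* Pedigree CSV: header ``animal,sire,dam`` (extra columns preserved),
  integer ids, 0 = unknown parent. Offspring listed before a parent are
  repaired by a topological sort with a warning; cycles are rejected.
* Phenotype CSV: ``animal,cg,<trait>`` with values 0/1/NA.
* Genotype matrix: whitespace-delimited, header row of SNP ids, first
  column the animal id, entries 0/1/2/NA (a PLINK-RAW-compatible subset).
* GEBV tables: TSV with ``#key=value`` provenance header lines.
* Relationship matrices: plain triplet text (row id, col id, value).
"""

from __future__ import annotations

import warnings
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GEBVTable
from .relationships import RelationshipMatrix

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "read_gebv_table",
    "write_gebv_table",
    "write_matrix_triplets",
    "read_matrix_triplets",
    "write_truth",
]

MISSING_TOKENS = ("NA", "na", "", "nan", "NaN")


def read_pedigree(path) -> pd.DataFrame:
    """Read and validate a pedigree CSV, repairing record order if needed."""
    ped = pd.read_csv(path)
    for col in ("animal", "sire", "dam"):
        if col not in ped.columns:
            raise ValueError(f"pedigree file missing column {col!r}: {path}")
        ped[col] = ped[col].astype(int)
    if ped["animal"].duplicated().any():
        dup = ped["animal"][ped["animal"].duplicated()].iloc[0]
        raise ValueError(f"duplicate animal id {dup} in {path}")
    known = set(ped["animal"])
    order_pos = {a: i for i, a in enumerate(ped["animal"])}
    needs_sort = False
    graph: dict = {}
    for rec in ped.itertuples(index=False):
        parents = [p for p in (rec.sire, rec.dam) if p != 0 and p in known]
        graph[rec.animal] = parents
        if any(order_pos[p] > order_pos[rec.animal] for p in parents):
            needs_sort = True
    if needs_sort:
        try:
            order = list(TopologicalSorter(graph).static_order())
        except CycleError as exc:
            raise ValueError(f"cyclic pedigree in {path}: {exc.args[1]}") from exc
        warnings.warn(f"pedigree records reordered parents-first: {path}")
        ped = ped.set_index("animal").loc[order].reset_index()
    return ped


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, index=False)


def read_phenotypes(path, trait: str | None = None) -> pd.DataFrame:
    """Read a phenotype CSV into the standard (animal, cg, y) frame.

    ``trait`` selects the phenotype column; by default the first column
    after ``animal`` and ``cg``. Records with missing phenotype are
    dropped.
    """
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=True)
    for col in ("animal", "cg"):
        if col not in df.columns:
            raise ValueError(f"phenotype file missing column {col!r}: {path}")
    if trait is None:
        candidates = [c for c in df.columns if c not in ("animal", "cg")]
        if not candidates:
            raise ValueError(f"phenotype file has no trait column: {path}")
        trait = candidates[0]
    out = df[["animal", "cg", trait]].rename(columns={trait: "y"})
    out = out[out["y"].notna()].reset_index(drop=True)
    bad = ~out["y"].isin((0, 1))
    if bad.any():
        i = out.index[bad][0]
        raise ValueError(
            f"phenotype value {out.loc[i, 'y']!r} at data row {i + 1} of {path} "
            "(expected 0/1/NA)"
        )
    out["y"] = out["y"].astype(int)
    return out


def write_phenotypes(phen: pd.DataFrame, path, trait: str = "defect") -> None:
    phen.rename(columns={"y": trait}).to_csv(path, index=False)


def read_genotypes(path) -> GenotypeMatrix:
    """Read the whitespace-delimited gene-content dialect."""
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ValueError(f"empty genotype file: {path}")
        snp_ids = header[1:]
        ids, rows = [], []
        for ln, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(snp_ids) + 1:
                raise ValueError(
                    f"{path}:{ln}: expected {len(snp_ids) + 1} fields, got {len(fields)}"
                )
            ids.append(int(fields[0]) if fields[0].isdigit() else fields[0])
            row = np.empty(len(snp_ids))
            for j, tok in enumerate(fields[1:]):
                if tok in MISSING_TOKENS:
                    row[j] = np.nan
                elif tok in ("0", "1", "2"):
                    row[j] = float(tok)
                else:
                    raise ValueError(
                        f"{path}:{ln}: column {j + 2}: invalid gene content {tok!r} "
                        "(expected 0/1/2/NA)"
                    )
            rows.append(row)
    return GenotypeMatrix(ids, snp_ids, np.array(rows))


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal " + " ".join(map(str, genotypes.snp_ids)) + "\n")
        for i, animal in enumerate(genotypes.ids):
            row = [
                "NA" if np.isnan(v) else str(int(v)) if v == int(v) else f"{v:.6g}"
                for v in genotypes.matrix[i]
            ]
            fh.write(f"{animal} " + " ".join(row) + "\n")


def write_gebv_table(table: GEBVTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#scale={table.scale}\n#model={table.model}\n")
        for key, val in sorted(table.meta.items()):
            fh.write(f"#{key}={val}\n")
        fh.write("animal\tvalue\n")
        for animal, value in table.values.items():
            fh.write(f"{animal}\t{value:.10g}\n")


def read_gebv_table(path) -> GEBVTable:
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
        df = pd.read_csv(fh, sep="\t")
    scale = meta.pop("scale", "observed")
    model = meta.pop("model", "linear")
    values = pd.Series(df["value"].to_numpy(), index=df["animal"].to_numpy())
    return GEBVTable(values, scale=scale, model=model, meta=meta)


def write_matrix_triplets(matrix: RelationshipMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#kind={matrix.kind}\n")
        for i, ri in enumerate(matrix.ids):
            for j in range(i + 1):
                v = matrix.values[i, j]
                if v != 0.0:
                    fh.write(f"{ri}\t{matrix.ids[j]}\t{v:.10g}\n")


def read_matrix_triplets(path) -> RelationshipMatrix:
    kind = "A"
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if line.startswith("#kind="):
                    kind = line.strip().split("=", 1)[1]
                continue
            i, j, v = line.split("\t")
            rows.append((int(i) if i.isdigit() else i, int(j) if j.isdigit() else j, float(v)))
    ids = pd.Index(dict.fromkeys([r[0] for r in rows] + [r[1] for r in rows]))
    pos = {a: k for k, a in enumerate(ids)}
    M = np.zeros((len(ids), len(ids)))
    for i, j, v in rows:
        M[pos[i], pos[j]] = v
        M[pos[j], pos[i]] = v
    return RelationshipMatrix(ids, M, kind)


def write_chain(chain, path, include_gebv: bool = False) -> None:
    """Tidy tab-separated draws file: iteration, parameter, value.

    Variance and heritability streams always; per-animal effect draws
    only on request (they dominate the file size).
    """
    spec = chain.spec
    with open(path, "w") as fh:
        fh.write(f"#model={chain.model_type}\n#seed={spec.seed}\n")
        fh.write(f"#n_iterations={spec.n_iterations}\n#burn_in={spec.burn_in}\n#thin={spec.thin}\n")
        fh.write("iteration\tparameter\tvalue\n")
        h2 = chain.h2()
        for k in range(chain.n_kept):
            it = spec.burn_in + k * spec.thin
            fh.write(f"{it}\tsigma2_a\t{chain.sigma2_a[k]:.10g}\n")
            fh.write(f"{it}\tsigma2_e\t{chain.sigma2_e[k]:.10g}\n")
            fh.write(f"{it}\th2\t{h2[k]:.10g}\n")
            if include_gebv:
                for j, animal in enumerate(chain.animal_ids):
                    fh.write(f"{it}\ta[{animal}]\t{chain.a[k, j]:.10g}\n")


def write_truth(population, path) -> None:
    """Tab-separated truth file for parameter-recovery tests."""
    with open(path, "w") as fh:
        for key, val in sorted(population.true_params.items()):
            fh.write(f"#{key}={val}\n")
        fh.write("animal\ttrue_bv\tliability\n")
        for animal in population.true_bv.index:
            fh.write(
                f"{animal}\t{population.true_bv[animal]:.10g}\t"
                f"{population.liabilities[animal]:.10g}\n"
            )
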