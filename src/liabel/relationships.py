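"""Pedigree, genomic, and combined relationship matrices.

The single-step evaluation needs three linked matrices: the numerator
relationship matrix ``A`` built from the pedigree by the tabular method
(with inbreeding), the genomic relationship matrix ``G`` built from
centred gene contents (VanRaden's first method), and the inverse of the
combined matrix ``H`` obtained by adding the genomic information as a
block update on the genotyped animals:

    H^-1 = A^-1 + [0 0; 0 G_b^-1 - A22^-1]

where ``A22`` is the pedigree relationship matrix restricted to the
genotyped animals and ``G_b`` is ``G`` blended with a small proportion of
``A22`` to guarantee invertibility.

All matrices are dense; the intended scale is desk-size populations
(up to roughly 20K animals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RelationshipMatrix",
    "validate_pedigree",
    "truncate_pedigree",
    "inbreeding",
    "build_A",
    "build_A22",
    "build_G",
    "blend_G",
    "build_H_inverse",
    "h_inverse_single_step",
]

UNKNOWN = 0  # parent code for "unknown"


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix with an animal-id index.

    ``kind`` is one of ``{"A", "A22", "G", "G_blended", "Hinv", "Ainv",
    "A22inv", "Ginv"}``.
    """

    ids: pd.Index
    values: np.ndarray
    kind: str = "A"

    def __post_init__(self) -> None:
        self.ids = pd.Index(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, i, j) -> float:
        return float(self.values[self.ids.get_loc(i), self.ids.get_loc(j)])

    def subset(self, ids, kind: str | None = None) -> "RelationshipMatrix":
        """Restrict to ``ids`` (order preserved as given)."""
        idx = np.array([self.ids.get_loc(i) for i in ids])
        return RelationshipMatrix(
            pd.Index(ids), self.values[np.ix_(idx, idx)], kind or self.kind
        )

    def inverse(self, kind: str | None = None) -> "RelationshipMatrix":
        try:
            np.linalg.cholesky(self.values + 0.0)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"{self.kind} is not positive definite and cannot be inverted; "
                "if this is a raw G, blend it with A22 first (blend_G)"
            ) from exc
        inv = np.linalg.inv(self.values)
        return RelationshipMatrix(self.ids, (inv + inv.T) / 2.0, kind or f"{self.kind}inv")


def _as_pedigree_frame(pedigree: pd.DataFrame) -> pd.DataFrame:
    required = {"animal", "sire", "dam"}
    missing = required - set(pedigree.columns)
    if missing:
        raise ValueError(f"pedigree missing columns: {sorted(missing)}")
    return pedigree


def validate_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Check pedigree invariants: unique ids, parents precede offspring.

    Raises ``ValueError`` naming the first offending record.
    """
    ped = _as_pedigree_frame(pedigree)
    animals = ped["animal"].to_numpy()
    if len(set(animals)) != len(animals):
        dup = ped["animal"][ped["animal"].duplicated()].iloc[0]
        raise ValueError(f"duplicate animal id in pedigree: {dup}")
    seen: set = set()
    for rec in ped.itertuples(index=False):
        for parent in (rec.sire, rec.dam):
            if parent != UNKNOWN and parent not in seen:
                raise ValueError(
                    f"pedigree ordering violation: animal {rec.animal} listed "
                    f"before its parent {parent}"
                )
        if rec.animal in (rec.sire, rec.dam):
            raise ValueError(f"animal {rec.animal} is its own parent")
        seen.add(rec.animal)
    return ped


def truncate_pedigree(
    pedigree: pd.DataFrame,
    n_generations: int = 3,
    anchors: set | None = None,
) -> pd.DataFrame:
    """Keep anchors plus their ancestors up to ``n_generations`` back.

    Parents that fall outside the horizon are recoded unknown (0). With
    ``anchors = all animals`` and a horizon at least the pedigree depth
    this is the identity. Default horizon of three ancestral generations
    follows routine-evaluation practice of trimming deep pedigrees.
    """
    ped = _as_pedigree_frame(pedigree)
    all_ids = set(ped["animal"])
    if anchors is None:
        anchors = all_ids
    anchors = set(anchors)
    absent = anchors - all_ids
    if absent:
        raise KeyError(
            f"anchors absent from pedigree: {sorted(absent)[:10]}"
            + ("..." if len(absent) > 10 else "")
        )
    parent_of = {
        rec.animal: (rec.sire, rec.dam) for rec in ped.itertuples(index=False)
    }
    keep = set(anchors)
    frontier = set(anchors)
    for _ in range(n_generations):
        nxt: set = set()
        for a in frontier:
            for p in parent_of.get(a, (UNKNOWN, UNKNOWN)):
                if p != UNKNOWN and p not in keep:
                    nxt.add(p)
        keep |= nxt
        frontier = nxt
        if not frontier:
            break
    out = ped[ped["animal"].isin(keep)].copy()
    out["sire"] = out["sire"].where(out["sire"].isin(keep), UNKNOWN)
    out["dam"] = out["dam"].where(out["dam"].isin(keep), UNKNOWN)
    return out.reset_index(drop=True)


def build_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    Handles inbreeding: ``diag(A) = 1 + F``. Requires parents listed
    before offspring (``validate_pedigree``).
    """
    ped = validate_pedigree(pedigree)
    ids = pd.Index(ped["animal"])
    pos = {a: k for k, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = [pos.get(s, -1) if s != UNKNOWN else -1 for s in ped["sire"]]
    dams = [pos.get(d, -1) if d != UNKNOWN else -1 for d in ped["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
            row = 0.5 * (A[s, :i] + A[d, :i])
        elif s >= 0:
            A[i, i] = 1.0
            row = 0.5 * A[s, :i]
        elif d >= 0:
            A[i, i] = 1.0
            row = 0.5 * A[d, :i]
        else:
            A[i, i] = 1.0
            row = np.zeros(i)
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(ids, A, "A")


def inbreeding(pedigree: pd.DataFrame) -> pd.Series:
    """Per-animal inbreeding coefficients F = diag(A) - 1."""
    A = build_A(pedigree)
    return pd.Series(np.diag(A.values) - 1.0, index=A.ids, name="F")


def build_A22(A: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """Pedigree relationships among the genotyped animals."""
    return A.subset(genotyped_ids, kind="A22")


def build_G(genotypes, freq_source: str = "observed", freqs=None) -> RelationshipMatrix:
    """Genomic relationship matrix G = ZZ' / (2 Σ p_i (1 - p_i)).

    ``Z = M - P`` where ``M`` holds gene contents 0/1/2 and ``P`` carries
    twice the allele frequencies. Frequencies are observed among the
    genotyped animals unless ``freq_source="supplied"`` with ``freqs``.

    Raises if all SNPs are fixed (zero denominator).
    """
    M = np.asarray(genotypes.matrix, dtype=float)
    if np.isnan(M).any():
        raise ValueError("genotype matrix has missing entries; run genotype_qc first")
    if freq_source == "observed":
        p = M.mean(axis=0) / 2.0
    elif freq_source == "supplied":
        if freqs is None:
            raise ValueError("freq_source='supplied' requires freqs")
        p = np.asarray(freqs, dtype=float)
    else:
        raise ValueError(f"unknown freq_source: {freq_source!r}")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all SNPs fixed: denominator 2*sum(p(1-p)) is zero")
    Z = M - 2.0 * p
    G = Z @ Z.T / denom
    return RelationshipMatrix(pd.Index(genotypes.ids), (G + G.T) / 2.0, "G")


def blend_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, weight: float = 0.95
) -> RelationshipMatrix:
    """G_b = weight * G + (1 - weight) * A22 (default 0.95/0.05).

    Blending guarantees a positive-definite, invertible genomic matrix.
    """
    if not G.ids.equals(A22.ids):
        raise ValueError("G and A22 must be indexed by the same animals in the same order")
    return RelationshipMatrix(
        G.ids, weight * G.values + (1.0 - weight) * A22.values, "G_blended"
    )


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix,
    G_inv: RelationshipMatrix,
    genotyped_ids,
) -> RelationshipMatrix:
    """Assemble H^-1 = A^-1 + block(G^-1 - A22^-1) on the genotyped animals."""
    genotyped_ids = list(genotyped_ids)
    if not (list(G_inv.ids) == genotyped_ids and list(A22_inv.ids) == genotyped_ids):
        raise ValueError("G_inv and A22_inv must be indexed by genotyped_ids, in order")
    missing = set(genotyped_ids) - set(A_inv.ids)
    if missing:
        raise ValueError(f"genotyped ids absent from A: {sorted(missing)[:10]}")
    H = A_inv.values.copy()
    idx = np.array([A_inv.ids.get_loc(i) for i in genotyped_ids], dtype=int)
    if idx.size:
        H[np.ix_(idx, idx)] += G_inv.values - A22_inv.values
    return RelationshipMatrix(A_inv.ids, (H + H.T) / 2.0, "Hinv")


def h_inverse_single_step(
    A: RelationshipMatrix,
    G: RelationshipMatrix | None,
    blend_weight: float = 0.95,
) -> RelationshipMatrix:
    """Convenience: H^-1 from A and (optionally) G in one call.

    With ``G=None`` (no genotyped animals) this is exactly A^-1.
    """
    A_inv = A.inverse("Ainv")
    if G is None or G.n == 0:
        return RelationshipMatrix(A.ids, A_inv.values, "Hinv")
    genotyped_ids = list(G.ids)
    A22 = build_A22(A, genotyped_ids)
    Gb = blend_G(G, A22, blend_weight) if blend_weight < 1.0 else G
    return build_H_inverse(A_inv, A22.inverse("A22inv"), Gb.inverse("Ginv"), genotyped_ids)
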