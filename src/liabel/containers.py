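"""Shared in-memory containers.

Tabular data travel as pandas objects; the two containers defined here
add the small amount of metadata that a bare DataFrame cannot carry
(SNP allele frequencies, the scale a set of breeding values lives on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "GEBVTable"]


@dataclass
class GenotypeMatrix:
    """Animals x SNPs gene-content matrix, coded 0/1/2 (NaN = missing).

    After mean imputation entries may be fractional, so the container
    only enforces the [0, 2] dosage range; the file reader enforces the
    strict 0/1/2 coding on input.
    """

    ids: list
    snp_ids: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype matrix shape {self.matrix.shape} does not match "
                f"{len(self.ids)} animals x {len(self.snp_ids)} SNPs"
            )
        with np.errstate(invalid="ignore"):
            valid = np.isnan(self.matrix) | (
                (self.matrix >= 0.0) & (self.matrix <= 2.0)
            )
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid gene content {self.matrix[i, j]!r} for animal "
                f"{self.ids[i]} at SNP {self.snp_ids[j]} (expected dosage in [0, 2])"
            )

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted allele per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0) / 2.0

    def call_rate_snp(self) -> np.ndarray:
        return 1.0 - np.isnan(self.matrix).mean(axis=0)

    def subset_animals(self, ids) -> "GenotypeMatrix":
        pos = {a: k for k, a in enumerate(self.ids)}
        idx = [pos[a] for a in ids]
        return GenotypeMatrix(list(ids), list(self.snp_ids), self.matrix[idx, :])

    def subset_snps(self, keep_mask: np.ndarray) -> "GenotypeMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return GenotypeMatrix(
            list(self.ids),
            [s for s, k in zip(self.snp_ids, keep_mask) if k],
            self.matrix[:, keep_mask],
        )


@dataclass
class GEBVTable:
    """Per-animal breeding values tagged with the scale they live on.

    ``scale`` is one of ``{"observed", "liability", "probability"}`` and
    ``model`` one of ``{"linear", "threshold"}``. ``meta`` records the
    quantities used by scale transitions (alpha, h2_o, h2_l, reference
    mean, residual SD, method), so every table carries its provenance.
    """

    values: pd.Series
    scale: str = "observed"
    model: str = "linear"
    meta: dict = field(default_factory=dict)

    _SCALES = ("observed", "liability", "probability")
    _MODELS = ("linear", "threshold")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.model not in self._MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        self.values = pd.Series(self.values, dtype=float)
        if self.scale == "probability":
            v = self.values.to_numpy()
            if ((v <= 0.0) | (v >= 1.0)).any():
                raise ValueError("probability-scale values must lie strictly in (0, 1)")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def ids(self) -> pd.Index:
        return self.values.index

    def with_values(self, values, scale: str, **meta) -> "GEBVTable":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return GEBVTable(
            pd.Series(np.asarray(values, dtype=float), index=self.values.index),
            scale=scale,
            model=self.model,
            meta=new_meta,
        )
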