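"""Core in-memory containers: marker map, genotype matrix, haplotype panel.

Genotypes are stored as ``int8`` allele-dosage codes 0/1/2 with ``-1`` for
missing. Haplotypes are 0/1 alleles in an ``(n_individuals, 2, n_markers)``
array. The marker map distinguishes the low-density subpanel (markers typed
on both arrays) from markers private to the medium-density array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

PANEL_BOTH = "both"     # marker present on the low- and medium-density arrays
PANEL_HD_ONLY = "50k"   # marker private to the medium-density array


class SNPMap:
    """Marker coordinates and panel membership for a nested panel pair.

    Parameters
    ----------
    table : DataFrame with columns ``snp_id``, ``chrom``, ``pos_bp``,
        ``pos_cm``, ``panel``; ``panel`` is ``"both"`` for markers on the
        nested low-density subpanel and ``"50k"`` otherwise.
    """

    REQUIRED = ("snp_id", "chrom", "pos_bp", "pos_cm", "panel")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"SNP map missing columns: {missing}")
        table = table.reset_index(drop=True)
        for chrom, sub in table.groupby("chrom", sort=False):
            bp = sub["pos_bp"].to_numpy()
            cm = sub["pos_cm"].to_numpy(dtype=float)
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"pos_bp not strictly increasing on chrom {chrom}")
            if not np.all(np.diff(cm) >= 0):
                raise ValueError(f"pos_cm not non-decreasing on chrom {chrom}")
        bad = set(table["panel"]) - {PANEL_BOTH, PANEL_HD_ONLY}
        if bad:
            raise ValueError(f"unknown panel labels: {bad}")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    @property
    def low_density_index(self) -> np.ndarray:
        """Column indices of the nested low-density subpanel."""
        return np.flatnonzero((self.table["panel"] == PANEL_BOTH).to_numpy())

    @property
    def hd_only_index(self) -> np.ndarray:
        """Column indices of markers private to the medium-density panel."""
        return np.flatnonzero((self.table["panel"] == PANEL_HD_ONLY).to_numpy())

    def chrom_index(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def pos_cm(self) -> np.ndarray:
        return self.table["pos_cm"].to_numpy(dtype=float)

    def subset(self, index: np.ndarray) -> "SNPMap":
        return SNPMap(self.table.iloc[np.asarray(index)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele dosages in {0,1,2}, -1 = missing."""

    ids: list
    snp_ids: np.ndarray
    values: np.ndarray  # (n, m) int8

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.snp_ids = np.asarray(self.snp_ids)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        if self.values.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} markers"
            )
        vals = self.values[self.values != MISSING]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("genotype codes must be in {0,1,2} or -1")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix([self.ids[i] for i in idx], self.snp_ids, self.values[idx])

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(list(self.ids), self.snp_ids[idx], self.values[:, idx])

    def select_ids(self, ids) -> "GenotypeMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        try:
            idx = [pos[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"id not in genotype matrix: {e}")
        return self.take_individuals(np.asarray(idx, dtype=int))

    def filled(self, dtype=np.float64) -> np.ndarray:
        """Values with per-marker mean imputation of missing cells."""
        out = self.values.astype(dtype)
        miss = self.values == MISSING
        if miss.any():
            masked = np.where(miss, np.nan, out)
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(masked, axis=0)
            col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
            out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
        return out


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes, shape (n_individuals, 2, n_markers)."""

    ids: list
    snp_ids: np.ndarray
    values: np.ndarray  # (n, 2, m) int8

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids)
        if self.values.shape != (len(self.ids), 2, len(self.snp_ids)):
            raise ValueError("haplotype panel shape mismatch")

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.ids)

    def as_matrix(self) -> np.ndarray:
        """All haplotypes stacked, shape (2n, m)."""
        n, _, m = self.values.shape
        return self.values.reshape(2 * n, m)

    def genotypes(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            list(self.ids), self.snp_ids, self.values.sum(axis=1).astype(np.int8)
        )

    def take_markers(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(list(self.ids), self.snp_ids[idx], self.values[:, :, idx])

    def select_ids(self, ids) -> "HaplotypePanel":
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.asarray([pos[i] for i in ids], dtype=int)
        return HaplotypePanel(list(ids), self.snp_ids, self.values[idx])
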