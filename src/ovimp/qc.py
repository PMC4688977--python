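"""SNP-array genotype quality control.

The filter cascade mirrors standard array QC for livestock panels and is
applied in a fixed, documented order:

1. per-genotype call-confidence (GC) score — low-confidence cells are set
   missing;
2. marker call rate;
3. marker heterozygosity outliers (beyond ``het_sd_limit`` SDs of the
   panel mean heterozygote frequency);
4. minor allele frequency strictly below ``min_maf``;
5. excluded chromosomes (sex chromosomes by default);
6. Hardy-Weinberg equilibrium (chi-square, one degree of freedom);
7. duplicate samples (pairwise genotype correlation above
   ``duplicate_r_ceiling``; the later-indexed member is dropped).

The order is part of the contract: e.g. heterozygosity statistics are
computed on markers surviving the call-rate filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import MISSING, GenotypeMatrix, SNPMap

__all__ = ["QCThresholds", "QCReport", "hwe_test", "detect_duplicates", "apply_qc"]


@dataclass
class QCThresholds:
    """Cut-offs for the QC cascade (defaults follow common ovine-array practice)."""

    min_call_rate: float = 0.90
    min_gc_score: float = 0.6
    het_sd_limit: float = 3.0
    min_maf: float = 0.01
    hwe_p_floor: float = 1e-15
    duplicate_r_ceiling: float = 0.98
    excluded_chromosomes: set = field(default_factory=lambda: {"X", "Y"})

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.het_sd_limit <= 0:
            raise ValueError("het_sd_limit must be > 0")
        if not (0.0 < self.hwe_p_floor < 1.0):
            raise ValueError("hwe_p_floor must be in (0, 1)")


@dataclass
class QCReport:
    """Per-filter removal counts; reconciles against the input dimensions."""

    n_markers_in: int
    n_samples_in: int
    removed_markers: dict = field(default_factory=dict)   # filter -> list of snp ids
    removed_samples: dict = field(default_factory=dict)   # sample id -> reason
    n_cells_set_missing: int = 0
    skipped_filters: list = field(default_factory=list)

    @property
    def n_markers_removed(self) -> int:
        return sum(len(v) for v in self.removed_markers.values())

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - self.n_markers_removed

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - len(self.removed_samples)

    def to_dict(self) -> dict:
        return {
            "n_markers_in": self.n_markers_in,
            "n_samples_in": self.n_samples_in,
            "n_markers_out": self.n_markers_out,
            "n_samples_out": self.n_samples_out,
            "removed_markers": {k: list(map(str, v)) for k, v in self.removed_markers.items()},
            "removed_samples": dict(self.removed_samples),
            "n_cells_set_missing": self.n_cells_set_missing,
            "skipped_filters": list(self.skipped_filters),
        }


def hwe_test(genotype_counts: tuple) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit p-value.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa) where A is the reference
    allele. Monomorphic markers return p = 1.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("HWE test undefined for zero total count")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(values: np.ndarray) -> np.ndarray:
    """Vectorised HWE chi-square p-values per marker (missing ignored)."""
    n_aa = (values == 0).sum(axis=0).astype(float)
    n_ab = (values == 1).sum(axis=0).astype(float)
    n_bb = (values == 2).sum(axis=0).astype(float)
    n = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_aa + n_ab) / (2 * n)
        q = 1.0 - p
        e_aa, e_ab, e_bb = n * p * p, 2 * n * p * q, n * q * q
        chi2 = (n_aa - e_aa) ** 2 / e_aa + (n_ab - e_ab) ** 2 / e_ab + (n_bb - e_bb) ** 2 / e_bb
    pvals = stats.chi2.sf(chi2, df=1)
    mono = (p <= 0.0) | (p >= 1.0) | (n == 0)
    pvals = np.where(mono, 1.0, pvals)
    return pvals


def detect_duplicates(genotypes: GenotypeMatrix, r_ceiling: float = 0.98) -> list:
    """Sample pairs whose genotype correlation exceeds ``r_ceiling``.

    Correlation is Pearson r on 0/1/2 codes over markers non-missing in
    both samples. Returns (kept_id, dropped_id) pairs; the later-indexed
    member of each pair is the one marked for removal. Pairs with fewer
    than two shared polymorphic markers are skipped with a warning.
    """
    n = genotypes.n_individuals
    if n < 2:
        raise ValueError("duplicate detection needs at least two samples")
    vals = genotypes.values.astype(float)
    vals[genotypes.values == MISSING] = np.nan
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            a, b = vals[i, both], vals[j, both]
            if both.sum() < 2 or a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"pair ({genotypes.ids[i]}, {genotypes.ids[j]}) has too few shared "
                    "polymorphic markers; skipped"
                )
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r > r_ceiling:
                flagged.append((genotypes.ids[i], genotypes.ids[j]))
    return flagged


def apply_qc(
    genotypes: GenotypeMatrix,
    snp_map: SNPMap,
    thresholds: QCThresholds,
    gc_scores: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full QC cascade; returns the filtered matrix and a report.

    ``gc_scores`` is an array aligned to the genotype cells; if absent the
    GC filter is skipped and logged in the report.
    """
    report = QCReport(n_markers_in=genotypes.n_markers, n_samples_in=genotypes.n_individuals)
    values = genotypes.values.copy()
    snp_ids = np.asarray(genotypes.snp_ids)
    if len(snp_map) != genotypes.n_markers or not np.array_equal(snp_map.snp_ids, snp_ids):
        raise ValueError("snp_map does not match genotype columns")
    chroms = snp_map.table["chrom"].to_numpy()

    # 1. per-genotype GC score
    if gc_scores is None:
        report.skipped_filters.append("gc_score")
    else:
        gc_scores = np.asarray(gc_scores)
        if gc_scores.shape != values.shape:
            raise ValueError("gc_scores shape does not match genotypes")
        low = (gc_scores < thresholds.min_gc_score) & (values != MISSING)
        values[low] = MISSING
        report.n_cells_set_missing = int(low.sum())

    keep = np.ones(len(snp_ids), dtype=bool)

    def drop(mask: np.ndarray, reason: str):
        idx = np.flatnonzero(keep & mask)
        if idx.size:
            report.removed_markers[reason] = [snp_ids[i] for i in idx]
            keep[idx] = False
        else:
            report.removed_markers[reason] = []
        if not keep.any():
            raise RuntimeError(f"all markers removed; last filter applied: {reason}")

    n_samples = values.shape[0]
    # 2. call rate
    call_rate = (values != MISSING).sum(axis=0) / n_samples
    drop(call_rate < thresholds.min_call_rate, "call_rate")

    # 3. heterozygosity outliers among surviving markers
    het = np.full(len(snp_ids), np.nan)
    called = (values != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = (values == 1).sum(axis=0) / np.maximum(called, 1)
    surv = np.flatnonzero(keep)
    mu, sd = het[surv].mean(), het[surv].std()
    if sd > 0:
        drop(np.abs(het - mu) > thresholds.het_sd_limit * sd, "heterozygosity")
    else:
        report.removed_markers["heterozygosity"] = []

    # 4. minor allele frequency (strictly below the floor is removed)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(values == MISSING, 0, values).sum(axis=0)
        p = alt / np.maximum(2 * called, 1)
    maf = np.minimum(p, 1.0 - p)
    drop(maf < thresholds.min_maf, "maf")

    # 5. excluded chromosomes
    excluded = np.isin(chroms.astype(str), [str(c) for c in thresholds.excluded_chromosomes])
    drop(excluded, "chromosome")

    # 6. HWE
    masked_vals = np.where(keep[None, :], values, MISSING)
    pvals = _hwe_pvalues(masked_vals)
    drop(pvals < thresholds.hwe_p_floor, "hwe")

    filtered = GenotypeMatrix(list(genotypes.ids), snp_ids[keep], values[:, keep])

    # 7. duplicate samples
    if filtered.n_individuals >= 2:
        pairs = detect_duplicates(filtered, thresholds.duplicate_r_ceiling)
        to_drop = []
        for kept_id, dropped_id in pairs:
            if dropped_id not in report.removed_samples:
                report.removed_samples[dropped_id] = f"duplicate_of:{kept_id}"
                to_drop.append(dropped_id)
        if to_drop:
            keep_rows = [i for i, ident in enumerate(filtered.ids) if ident not in to_drop]
            filtered = filtered.take_individuals(np.asarray(keep_rows))
    return filtered, report
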