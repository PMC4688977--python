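"""Genomic relationship matrices (VanRaden method 1).

G = Mc Mc' / (2 * sum_j p_j (1 - p_j)), where Mc is the genotype matrix
centered by twice the allele frequencies. Allele frequencies default to
the sample being analysed (for the rectangular test x candidate block
they come from the pooled set, so the block equals the corresponding
block of the full stacked-matrix G).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix

__all__ = ["GRM", "CrossGRM", "compute_grm", "compute_cross_grm", "allele_frequencies"]


@dataclass
class GRM:
    ids: list
    values: np.ndarray
    allele_freqs_used: np.ndarray
    scaling_denominator: float

    def __post_init__(self):
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("GRM dimension does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        if self.scaling_denominator <= 0:
            raise ValueError("scaling denominator must be positive")

    def align(self, ids) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.asarray([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]


@dataclass
class CrossGRM:
    test_ids: list
    candidate_ids: list
    values: np.ndarray
    allele_freqs_used: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.test_ids), len(self.candidate_ids)):
            raise ValueError("CrossGRM dimensions do not match id lists")


def allele_frequencies(values: np.ndarray) -> np.ndarray:
    """Alternate-allele frequencies per marker from a dosage matrix."""
    return np.asarray(values, dtype=float).mean(axis=0) / 2.0


def _vanraden(values: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, float]:
    p = np.asarray(p, dtype=float)
    poly = (p > 0.0) & (p < 1.0)
    denom = float(2.0 * np.sum(p[poly] * (1.0 - p[poly])))
    if denom <= 0.0:
        raise ZeroDivisionError("all markers monomorphic: VanRaden denominator is zero")
    mc = np.asarray(values, dtype=float)[:, poly] - 2.0 * p[poly]
    return mc @ mc.T / denom, denom


def compute_grm(
    genotypes: GenotypeMatrix | np.ndarray, freqs: np.ndarray | None = None, ids=None
) -> GRM:
    """VanRaden method-1 G from a complete dosage matrix.

    Missing genotypes must be filled first (``GenotypeMatrix.filled`` does
    per-marker mean imputation). ``freqs`` defaults to sample allele
    frequencies of the matrix itself. Monomorphic markers (p of 0 or 1)
    contribute to neither numerator nor denominator.
    """
    if isinstance(genotypes, GenotypeMatrix):
        if genotypes.missing_mask().any():
            raise ValueError("missing genotypes present; fill them before computing G")
        values = genotypes.values.astype(float)
        ids = list(genotypes.ids)
    else:
        values = np.asarray(genotypes, dtype=float)
        ids = list(ids) if ids is not None else list(range(values.shape[0]))
    p = allele_frequencies(values) if freqs is None else np.asarray(freqs, dtype=float)
    g, denom = _vanraden(values, p)
    g = (g + g.T) / 2.0  # enforce exact symmetry against fp round-off
    return GRM(ids, g, p, denom)


def compute_cross_grm(
    test_genotypes: GenotypeMatrix, candidate_genotypes: GenotypeMatrix
) -> CrossGRM:
    """Rectangular test x candidate relationship block on shared markers.

    Both matrices must already be restricted to the shared (low-density)
    panel in the same marker order. Frequencies are estimated from the
    pooled test + candidate set, so the result equals the off-diagonal
    block of ``compute_grm`` on the stacked matrix.
    """
    if not np.array_equal(test_genotypes.snp_ids, candidate_genotypes.snp_ids):
        raise ValueError("test and candidate matrices must share the same marker set/order")
    stacked = np.vstack(
        [test_genotypes.values.astype(float), candidate_genotypes.values.astype(float)]
    )
    p = allele_frequencies(stacked)
    g, _ = _vanraden(stacked, p)
    n_test = test_genotypes.n_individuals
    return CrossGRM(
        list(test_genotypes.ids),
        list(candidate_genotypes.ids),
        g[:n_test, n_test:],
        p,
    )
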