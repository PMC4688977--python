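"""Population-based genotype imputation from a low- to a medium-density panel.

The workflow mirrors modern pre-phasing imputation practice: the
reference panel is phased by iterative conditional Viterbi re-phasing
against the current panel, targets are pre-phased on their typed
(low-density) scaffold by a diploid Viterbi against the reference, and
each target haplotype is then imputed by a haploid Li-Stephens
forward-backward pass. The imputed dosage at an untyped marker is the
sum of the two haploid allele posteriors; typed markers pass through
unchanged.

`LiStephensModel` holds the reference genotypes and parameters; `fit`
phases the reference and returns a `PhasedReferenceResults` whose
`impute` method processes a low-density test set.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from ._random import substream
from .containers import MISSING, GenotypeMatrix, HaplotypePanel, SNPMap
from .hmm import (
    diploid_sample,
    diploid_viterbi,
    haploid_forward_backward,
    switch_probabilities,
)

__all__ = [
    "LiStephensParams",
    "ImputationResult",
    "LiStephensModel",
    "PhasedReferenceResults",
    "phase_panel",
    "impute_individual",
    "impute_set",
]


@dataclass
class LiStephensParams:
    """Tuning parameters of the copying model.

    n_iterations : phasing iterations over the panel (default 10).
    error_rate : per-allele miscopy probability eps.
    recomb_scale : effective-size parameter Ne_eff in
        rho = 1 - exp(-4 * Ne_eff * d / H).
    n_surrogates : reference haplotypes used per individual in the
        quadratic-cost diploid Viterbi steps (closest by allele sharing).
    per_chromosome : impute chromosome by chromosome (equivalent to a
        single chain that restarts at chromosome boundaries).
    """

    n_iterations: int = 10
    error_rate: float = 0.003
    recomb_scale: float = 100.0
    n_surrogates: int = 30
    per_chromosome: bool = True

    def __post_init__(self):
        if not (0.0 < self.error_rate < 0.5):
            raise ValueError("error_rate must be in (0, 0.5)")
        if self.recomb_scale <= 0:
            raise ValueError("recomb_scale must be > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_surrogates < 2:
            raise ValueError("n_surrogates must be >= 2")


@dataclass
class ImputationResult:
    """Posterior dosages and best-guess genotypes for a test set."""

    ids: list
    snp_ids: np.ndarray
    dosages: np.ndarray        # (n, m) float64 in [0, 2]
    best_guess: np.ndarray     # (n, m) int8
    observed_mask: np.ndarray  # (m,) bool, True where typed at low density
    posterior_max: np.ndarray  # (n, m) max posterior genotype probability

    def __post_init__(self):
        if np.any((self.dosages < -1e-9) | (self.dosages > 2 + 1e-9)):
            raise ValueError("dosages outside [0, 2]")


def _chrom_starts(snp_map: SNPMap) -> np.ndarray:
    chroms = snp_map.table["chrom"].to_numpy()
    starts = np.zeros(len(chroms), dtype=bool)
    starts[0] = True
    starts[1:] = chroms[1:] != chroms[:-1]
    return starts


def _surrogate_index(
    ref_haps: np.ndarray, genotype: np.ndarray, k: int, exclude: tuple = ()
) -> np.ndarray:
    """Indices of the k reference haplotypes sharing the most alleles with
    the target genotype (ties resolved by lower index)."""
    g = np.where(genotype == MISSING, 1, genotype).astype(np.float32)
    r = ref_haps.astype(np.float32)
    score = r @ (2.0 * g - 2.0) + (2.0 - g).sum()  # = r@g + (1-r)@(2-g)
    for i in exclude:
        score[i] = -np.inf
    k = min(k, ref_haps.shape[0] - len(exclude))
    idx = np.argsort(-score, kind="stable")[:k]
    return np.sort(idx)


def _assemble_phase(genotype: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Haplotype pair consistent with the genotype, given the copied
    reference alleles (a, b) along the Viterbi path pair.

    Homozygous sites are forced; missing sites take the copied alleles;
    heterozygous sites orient by the copied alleles, carrying the previous
    orientation across sites where both copies agree (deterministic)."""
    m = len(genotype)
    het = genotype == 1
    info = het & (a != b)
    pos = np.where(info, np.arange(m), -1)
    last = np.maximum.accumulate(pos)
    orient_at = np.where(a == 1, 0, 1)  # orientation chosen at informative hets
    orient = np.where(last >= 0, orient_at[np.maximum(last, 0)], 0)
    hap = np.empty((2, m), dtype=np.int8)
    hap[0] = np.where(genotype == 2, 1, 0)
    hap[1] = hap[0]
    hap[0, het] = 1 - orient[het]
    hap[1, het] = orient[het]
    miss = genotype == MISSING
    hap[0, miss] = a[miss]
    hap[1, miss] = b[miss]
    return hap


def _phase_with_viterbi(
    genotype: np.ndarray,
    ref_haps: np.ndarray,
    rho: np.ndarray,
    eps: float,
    n_surrogates: int,
    exclude: tuple = (),
    rng=None,
) -> np.ndarray:
    """Phase one individual against a reference panel.

    With ``rng`` the path pair is sampled from the joint posterior
    (stochastic burn-in iteration); without it the Viterbi pair is used
    (final, deterministic iteration)."""
    sub = _surrogate_index(ref_haps, genotype, n_surrogates, exclude)
    ref = np.ascontiguousarray(ref_haps[sub])
    gt = genotype.astype(np.int8)
    if rng is None:
        p1, p2 = diploid_viterbi(gt, ref, rho, eps)
    else:
        p1, p2 = diploid_sample(gt, ref, rho, eps, rng.random(len(gt)))
    cols = np.arange(len(genotype))
    return _assemble_phase(genotype, ref[p1, cols], ref[p2, cols])


class LiStephensModel:
    """Li-Stephens imputation model built from a medium-density reference.

    Parameters
    ----------
    reference : GenotypeMatrix on the full (medium-density) panel.
    snp_map : SNPMap covering the reference columns.
    params : LiStephensParams, optional.
    """

    def __init__(
        self,
        reference: GenotypeMatrix,
        snp_map: SNPMap,
        params: LiStephensParams | None = None,
    ):
        if len(snp_map) != reference.n_markers or not np.array_equal(
            snp_map.snp_ids, reference.snp_ids
        ):
            raise ValueError("snp_map does not match reference markers")
        self.reference = reference
        self.snp_map = snp_map
        self.params = params or LiStephensParams()
        self._chrom_starts = _chrom_starts(snp_map)
        self._pos_cm = snp_map.pos_cm()

    def _chrom_blocks(self):
        starts = np.flatnonzero(self._chrom_starts)
        bounds = list(starts) + [len(self._chrom_starts)]
        if self.params.per_chromosome:
            return [slice(bounds[i], bounds[i + 1]) for i in range(len(starts))]
        return [slice(0, len(self._chrom_starts))]

    def fit(self, seed: int = 0) -> "PhasedReferenceResults":
        """Phase the reference panel by iterative conditional re-phasing.

        Heterozygote phases start at random (seeded); each iteration
        re-phases every individual by diploid Viterbi against the current
        haplotypes of all other individuals.
        """
        geno = self.reference.values
        n, m = geno.shape
        if n < 1:
            raise ValueError("empty reference panel")
        rng = substream(seed, "phase-init")
        haps = np.empty((n, 2, m), dtype=np.int8)
        flip = rng.random((n, m)) < 0.5
        for i in range(n):
            g = geno[i]
            filled = np.where(g == MISSING, (rng.random(m) < 0.5).astype(np.int8) * 2, g)
            h0 = np.where(filled == 2, 1, 0).astype(np.int8)
            h1 = h0.copy()
            het = filled == 1
            h0[het & ~flip[i]] = 1
            h1[het & flip[i]] = 1
            haps[i, 0] = h0
            haps[i, 1] = h1
        if n == 1:
            warnings.warn("single-individual panel: phase is arbitrary")
            return PhasedReferenceResults(
                self, HaplotypePanel(list(self.reference.ids), self.reference.snp_ids, haps)
            )

        p = self.params
        for block in self._chrom_blocks():
            sub_cm = self._pos_cm[block]
            sub_starts = self._chrom_starts[block].copy()
            sub_starts[0] = True
            rho = switch_probabilities(sub_cm, sub_starts, p.recomb_scale, 2 * (n - 1))
            g_block = np.ascontiguousarray(geno[:, block])
            flat = np.ascontiguousarray(haps[:, :, block].reshape(2 * n, -1))
            iter_rng = substream(seed, "phase-iter", str(block.start))
            for it in range(p.n_iterations):
                final = it == p.n_iterations - 1
                for i in range(n):
                    pair = _phase_with_viterbi(
                        g_block[i], flat, rho, p.error_rate, p.n_surrogates,
                        exclude=(2 * i, 2 * i + 1),
                        rng=None if final else iter_rng,
                    )
                    flat[2 * i] = pair[0]
                    flat[2 * i + 1] = pair[1]
            haps[:, :, block] = flat.reshape(n, 2, -1)
        return PhasedReferenceResults(
            self, HaplotypePanel(list(self.reference.ids), self.reference.snp_ids, haps)
        )


@dataclass
class PhasedReferenceResults:
    """A fitted (phased) reference panel; exposes imputation of test sets."""

    model: LiStephensModel
    panel: HaplotypePanel

    def impute(self, test: GenotypeMatrix) -> ImputationResult:
        """Impute a low-density test set up to the full reference panel.

        ``test`` columns must be the low-density subpanel of the model's
        SNP map (sporadic missing allowed)."""
        snp_map = self.model.snp_map
        ld_idx = snp_map.low_density_index
        ld_ids = snp_map.snp_ids[ld_idx]
        if not np.array_equal(test.snp_ids, ld_ids):
            raise ValueError("test markers must equal the low-density subpanel, in order")
        p = self.model.params
        m = len(snp_map)
        n = test.n_individuals
        observed_mask = np.zeros(m, dtype=bool)
        observed_mask[ld_idx] = True

        dosages = np.empty((n, m))
        post_max = np.empty((n, m))
        ref_all = self.panel.as_matrix()
        typed_of_block: dict = {}
        for i in range(n):
            full_geno = np.full(m, MISSING, dtype=np.int8)
            full_geno[ld_idx] = test.values[i]
            d_row, pm_row = self._impute_one(full_geno, ref_all, typed_of_block)
            dosages[i] = d_row
            post_max[i] = pm_row

        # typed, non-missing markers pass through unchanged
        for i in range(n):
            obs = test.values[i]
            ok = obs != MISSING
            dosages[i, ld_idx[ok]] = obs[ok]
            post_max[i, ld_idx[ok]] = 1.0
        best = np.rint(dosages).astype(np.int8)  # ties to nearest even
        return ImputationResult(
            list(test.ids), snp_map.snp_ids, dosages, best, observed_mask, post_max
        )

    def _impute_one(self, full_geno, ref_all, typed_cache):
        model = self.model
        p = model.params
        m = ref_all.shape[1]
        dosage = np.empty(m)
        post_max = np.empty(m)
        H = ref_all.shape[0]
        for block in model._chrom_blocks():
            cm = model._pos_cm[block]
            starts = model._chrom_starts[block].copy()
            starts[0] = True
            key = (block.start, block.stop)
            if key not in typed_cache:
                typed_cache[key] = {
                    "rho_full": switch_probabilities(cm, starts, p.recomb_scale, H),
                }
            rho_full = typed_cache[key]["rho_full"]
            g = full_geno[block]
            ref = np.ascontiguousarray(ref_all[:, block])
            typed = np.flatnonzero(g != MISSING)
            if typed.size:
                # pre-phase on the typed scaffold
                rho_typed = switch_probabilities(cm[typed], starts[typed], p.recomb_scale, H)
                rho_typed[0] = 1.0
                sub = _surrogate_index(ref[:, typed], g[typed], p.n_surrogates)
                ref_typed = np.ascontiguousarray(ref[np.ix_(sub, typed)])
                path1, path2 = diploid_viterbi(
                    g[typed].astype(np.int8), ref_typed, rho_typed, p.error_rate
                )
                scaffold = np.full((2, len(g)), MISSING, dtype=np.int8)
                cols = np.arange(len(typed))
                a = ref_typed[path1, cols]
                b = ref_typed[path2, cols]
                orient = 0
                for t, j in enumerate(typed):
                    gj = g[j]
                    if gj == 0:
                        scaffold[:, j] = 0
                    elif gj == 2:
                        scaffold[:, j] = 1
                    else:
                        if a[t] != b[t]:
                            orient = 0 if a[t] == 1 else 1
                        scaffold[0, j] = 1 - orient
                        scaffold[1, j] = orient
            else:
                scaffold = np.full((2, len(g)), MISSING, dtype=np.int8)
            _, p1a, _ = haploid_forward_backward(
                scaffold[0], ref, rho_full, p.error_rate
            )
            _, p1b, _ = haploid_forward_backward(
                scaffold[1], ref, rho_full, p.error_rate
            )
            dosage[block] = p1a + p1b
            g0 = (1 - p1a) * (1 - p1b)
            g1 = p1a * (1 - p1b) + (1 - p1a) * p1b
            g2 = p1a * p1b
            post_max[block] = np.maximum(np.maximum(g0, g1), g2)
        return dosage, post_max


# ---------------------------------------------------------------------------
# functional wrappers

def phase_panel(
    genotypes: GenotypeMatrix,
    snp_map: SNPMap,
    params: LiStephensParams | None = None,
    seed: int = 0,
) -> HaplotypePanel:
    """Phase a genotype panel (see ``LiStephensModel.fit``)."""
    return LiStephensModel(genotypes, snp_map, params).fit(seed).panel


def impute_individual(
    low_density_row: np.ndarray,
    reference: HaplotypePanel,
    snp_map: SNPMap,
    params: LiStephensParams | None = None,
    sample_id: str = "target",
) -> ImputationResult:
    """Impute a single low-density-typed individual against a phased reference."""
    if not np.array_equal(reference.snp_ids, snp_map.snp_ids):
        raise ValueError("reference panel markers do not match the SNP map")
    params = params or LiStephensParams()
    test = GenotypeMatrix(
        [sample_id],
        snp_map.snp_ids[snp_map.low_density_index],
        np.asarray(low_density_row, dtype=np.int8).reshape(1, -1),
    )
    ref_geno = reference.genotypes()
    model = LiStephensModel(ref_geno, snp_map, params)
    return PhasedReferenceResults(model, reference).impute(test)


def impute_set(
    test: GenotypeMatrix,
    reference: GenotypeMatrix,
    snp_map: SNPMap,
    params: LiStephensParams | None = None,
    seed: int = 0,
) -> ImputationResult:
    """Phase the reference, then impute every test individual.

    ``test`` is typed on the low-density subpanel; ``reference`` on the
    full panel. Deterministic under ``seed``."""
    params = params or LiStephensParams()
    results = LiStephensModel(reference, snp_map, params).fit(seed)
    if test.n_individuals == 0:
        m = len(snp_map)
        obs = np.zeros(m, dtype=bool)
        obs[snp_map.low_density_index] = True
        return ImputationResult(
            [], snp_map.snp_ids, np.empty((0, m)), np.empty((0, m), dtype=np.int8),
            obs, np.empty((0, m)),
        )
    return results.impute(test)
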