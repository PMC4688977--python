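"""Relatedness-based selection of an imputation reference set.

For each target (test) animal the k most genomically related candidates
are taken; the union is deduplicated. If the union falls short of the
requested reference size, k is escalated until it suffices (or the
candidate pool is exhausted); if it overshoots, candidates with the
lowest average relationship to the whole test set are pruned. The whole
procedure is deterministic: ties break on higher relationship, then on
lexicographically smaller candidate id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grm import CrossGRM

__all__ = ["SelectionConfig", "select_reference"]


@dataclass
class SelectionConfig:
    k_init: int = 20
    n_target: int = 2000
    k_stride: int = 1
    diversity_ceiling: float | None = None  # optional within-set relationship cap

    def __post_init__(self):
        if self.k_init < 1 or self.n_target < 1 or self.k_stride < 1:
            raise ValueError("k_init, n_target and k_stride must be >= 1")


def _top_k_union(values: np.ndarray, cand_ids: list, k: int) -> set:
    """Union over test animals of each one's k most-related candidates.

    Ties at the k-th rank break toward the lexicographically smaller id.
    """
    chosen: set = set()
    for row in values:
        # sort candidates by (-relationship, id): stable deterministic ranking
        rel_sorted = sorted(
            range(len(cand_ids)), key=lambda j: (-row[j], str(cand_ids[j]))
        )
        chosen.update(cand_ids[j] for j in rel_sorted[:k])
    return chosen


def select_reference(cross_grm: CrossGRM, config: SelectionConfig) -> list:
    """Select a reference set of exactly ``n_target`` candidates (or the
    whole pool if smaller). Returns candidate ids sorted lexicographically.
    """
    cand_ids = list(cross_grm.candidate_ids)
    if len(cand_ids) == 0:
        raise ValueError("candidate pool is empty")
    overlap = set(cand_ids) & set(cross_grm.test_ids)
    if overlap:
        raise ValueError(f"candidates overlap the test set: {sorted(overlap)[:5]}")
    values = np.asarray(cross_grm.values, dtype=float)
    pool = len(cand_ids)

    if config.n_target >= pool:
        if config.n_target > pool:
            warnings.warn(
                f"requested {config.n_target} reference animals but pool has {pool}; "
                "returning the full pool"
            )
        return sorted(cand_ids, key=str)

    k = config.k_init
    chosen = _top_k_union(values, cand_ids, k)
    while len(chosen) < config.n_target and k < pool:
        k += config.k_stride
        chosen = _top_k_union(values, cand_ids, k)

    if len(chosen) > config.n_target:
        # prune candidates with the lowest mean relationship to the test set;
        # mean relationships are fixed, so pruning is a single rank-and-cut
        mean_rel = values.mean(axis=0)
        rel_of = {cid: mean_rel[j] for j, cid in enumerate(cand_ids)}
        ranked = sorted(chosen, key=lambda c: (rel_of[c], str(c)))
        n_remove = len(chosen) - config.n_target
        chosen -= set(ranked[:n_remove])

    if config.diversity_ceiling is not None:
        chosen = _enforce_diversity(chosen, values, cand_ids, config)

    return sorted(chosen, key=str)


def _enforce_diversity(
    chosen: set, values: np.ndarray, cand_ids: list, config: SelectionConfig
) -> set:
    """Optional post-filter: greedily drop one member of any candidate pair
    related above the ceiling, backfilling with the next-ranked candidate.

    Requires candidate-candidate relationships, which the rectangular
    test x candidate block does not carry; approximated here by similarity
    of candidate relationship profiles to the test set. Default OFF; kept
    because set diversity had little practical effect on half-sib data.
    """
    mean_rel = values.mean(axis=0)
    rel_of = {cid: mean_rel[j] for j, cid in enumerate(cand_ids)}
    profile = {cid: values[:, j] for j, cid in enumerate(cand_ids)}
    backfill = sorted(
        (c for c in cand_ids if c not in chosen), key=lambda c: (-rel_of[c], str(c))
    )
    members = sorted(chosen, key=lambda c: (-rel_of[c], str(c)))
    kept: list = []
    for c in members:
        sim_ok = all(
            float(np.corrcoef(profile[c], profile[k])[0, 1]) <= config.diversity_ceiling
            for k in kept
            if np.std(profile[k]) > 0 and np.std(profile[c]) > 0
        )
        if sim_ok:
            kept.append(c)
    for c in backfill:
        if len(kept) >= len(members):
            break
        kept.append(c)
    return set(kept)
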