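"""Hand-designed 12-marker QC fixture with exactly one violation per filter.

81 samples: s0..s79 plus ``dup``, an exact copy of s0. Markers:

    m_cr   : call rate 68/81 = 0.84 (< 0.90)           -> call_rate
    m_het  : all samples heterozygous                  -> heterozygosity
    m_maf  : one Aa among 81 (MAF 1/162 ~ 0.006)       -> maf
    m_chrX : clean statistics, mapped to chromosome X  -> chromosome
    m_hwe  : (60, 10, 11), chi-square p ~ 4e-8         -> hwe
    n1..n7 : clean markers that survive every filter

The seven surviving columns are drawn from near-HWE genotype
probabilities and greedily filtered so that no pair of base samples has
|r| >= 0.95 over them — the planted (s0, dup) pair is therefore the only
duplicate. Designed for QCThresholds(het_sd_limit=2.0, hwe_p_floor=1e-4)
with the remaining thresholds at their defaults; the build asserts its
own design invariants.
"""

import numpy as np
import pandas as pd
from scipy import stats

from ovimp.containers import MISSING, GenotypeMatrix, SNPMap
from ovimp.qc import QCThresholds

N_BASE = 80  # + the duplicate
N_SURVIVORS = 7

PLANTED = ["m_cr", "m_het", "m_maf", "m_chrX", "m_hwe"]
SURVIVORS = [f"n{i}" for i in range(1, N_SURVIVORS + 1)]

EXPECTED_REMOVED = {
    "call_rate": ["m_cr"],
    "heterozygosity": ["m_het"],
    "maf": ["m_maf"],
    "chromosome": ["m_chrX"],
    "hwe": ["m_hwe"],
}

FIXTURE_THRESHOLDS = QCThresholds(het_sd_limit=2.0, hwe_p_floor=1e-4)


def _sample_rows(rng):
    """80 distinct base rows over the 7 surviving markers, pairwise
    |r| < 0.95, genotypes near HWE with heterozygosity ~ 0.38."""
    probs = np.array([0.533, 0.38, 0.087])
    rows = []
    while len(rows) < N_BASE:
        cand = rng.choice(3, size=N_SURVIVORS, p=probs).astype(np.int8)
        if cand.std() == 0:
            continue
        ok = True
        for r in rows:
            if r.std() == 0:
                continue
            if abs(np.corrcoef(cand, r)[0, 1]) >= 0.95:
                ok = False
                break
        if ok:
            rows.append(cand)
    return np.array(rows)


def _hwe_p(col):
    col = col[col != MISSING]
    n_aa, n_ab, n_bb = (col == 0).sum(), (col == 1).sum(), (col == 2).sum()
    n = len(col)
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    e = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    chi2 = (((np.array([n_aa, n_ab, n_bb]) - e) ** 2) / e).sum()
    return stats.chi2.sf(chi2, 1)


def build_qc_fixture():
    """Return (GenotypeMatrix of 81 samples x 12 markers, SNPMap)."""
    rng = np.random.default_rng(20240901)
    base = _sample_rows(rng)  # (80, 7)

    # planted columns: genotype of s0, then counts over the other 79 samples
    planted_cols = {
        "m_cr": (0, (51, 15, 0), 13),   # 13 missing cells
        "m_het": (1, (0, 79, 0), 0),
        "m_maf": (0, (78, 1, 0), 0),
        "m_chrX": (0, (56, 18, 5), 0),
        "m_hwe": (0, (58, 10, 11), 0),
    }
    cols = {}
    for name, (g0, (aa, ab, bb), n_missing) in planted_cols.items():
        others = np.array(
            [0] * aa + [1] * ab + [2] * bb + [MISSING] * n_missing, dtype=np.int8
        )
        assert len(others) == N_BASE - 1, name
        rng.shuffle(others)
        cols[name] = np.concatenate([[g0], others, [g0]]).astype(np.int8)
    for j, name in enumerate(SURVIVORS):
        col = base[:, j]
        cols[name] = np.concatenate([col, [col[0]]]).astype(np.int8)

    order = ["m_cr", "m_het", "m_maf", "m_chrX", "m_hwe"] + SURVIVORS
    values = np.column_stack([cols[n] for n in order])
    ids = [f"s{i}" for i in range(N_BASE)] + ["dup"]
    geno = GenotypeMatrix(ids, np.array(order), values)

    rows = []
    for j, name in enumerate(order):
        rows.append(
            {
                "snp_id": name,
                "chrom": "X" if name == "m_chrX" else "1",
                "pos_bp": (j + 1) * 1000,
                "pos_cm": float(j + 1),
                "panel": "both" if j % 2 == 0 else "50k",
            }
        )
    snp_map = SNPMap(pd.DataFrame(rows))

    # design invariants: survivors pass every marker filter comfortably
    for name in SURVIVORS:
        col = cols[name]
        p = col.mean() / 2
        assert min(p, 1 - p) >= 0.01, name
        assert _hwe_p(col) >= 1e-3, name
    hets = np.array(
        [
            (cols[n][cols[n] != MISSING] == 1).mean()
            for n in order
            if n != "m_cr"  # removed before the heterozygosity stage
        ]
    )
    z = np.abs(hets - hets.mean()) / hets.std()
    flagged = [n for n, zz in zip([n for n in order if n != "m_cr"], z) if zz > 2.0]
    assert flagged == ["m_het"], flagged
    return geno, snp_map
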