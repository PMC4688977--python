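"""Imputation-accuracy statistics.

Accuracy is the Pearson correlation between observed and imputed
genotypes, computed per test individual over the withheld (masked)
markers only — the markers typed at low density are always excluded —
and, optionally, per SNP across test individuals. Dosages are the
default imputed quantity; best-guess genotypes are available as a
variant. Correlations that are undefined because the observed vector is
constant are flagged and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .imputation import ImputationResult

__all__ = ["AccuracyTable", "individual_accuracy", "snp_accuracy", "summarize", "evaluate"]

HIST_BINS = np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 10)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; NaN when either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class AccuracyTable:
    per_individual: pd.Series       # id -> r (NaN = undefined)
    per_snp: pd.Series | None = None  # snp_id -> r
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = self.per_individual.dropna()
        if ((vals < -1 - 1e-12) | (vals > 1 + 1e-12)).any():
            raise ValueError("correlations outside [-1, 1]")
        if not self.summary:
            self.summary = summarize(self.per_individual.to_numpy())


def individual_accuracy(
    observed_row: np.ndarray, imputed_row: np.ndarray, mask: np.ndarray
) -> float:
    """Per-individual Pearson r over the withheld markers.

    ``mask`` indexes the markers withheld from the low-density panel;
    NaN is returned (undefined) when the observed masked vector is
    constant for this individual."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("mask of withheld markers is empty")
    obs = np.asarray(observed_row, dtype=float)[mask]
    imp = np.asarray(imputed_row, dtype=float)[mask]
    if np.isnan(obs).any():
        raise ValueError("observed genotypes incomplete on the masked markers")
    return _pearson(obs, imp)


def snp_accuracy(observed_col: np.ndarray, imputed_col: np.ndarray) -> float:
    """Per-SNP Pearson r across test individuals at one withheld marker."""
    obs = np.asarray(observed_col, dtype=float)
    if obs.size < 2:
        raise ValueError("per-SNP accuracy needs at least two test individuals")
    return _pearson(obs, np.asarray(imputed_col, dtype=float))


def summarize(accuracies: np.ndarray) -> dict:
    """Mean/SD/min/max over the defined values plus fixed-width histogram
    counts (bin width 0.02 on [0, 1]; values below 0 are clipped into the
    first bin for plotting)."""
    acc = np.asarray(accuracies, dtype=float)
    defined = acc[~np.isnan(acc)]
    if defined.size == 0:
        raise ValueError("no defined accuracy values to summarise")
    hist, _ = np.histogram(np.clip(defined, 0.0, 1.0), bins=HIST_BINS)
    return {
        "n": int(defined.size),
        "n_undefined": int(np.isnan(acc).sum()),
        "mean": float(defined.mean()),
        "sd": float(defined.std(ddof=0)),
        "min": float(defined.min()),
        "max": float(defined.max()),
        "hist_counts": hist.tolist(),
        "hist_edges": HIST_BINS.tolist(),
    }


def evaluate(
    observed: GenotypeMatrix,
    result: ImputationResult,
    mask: np.ndarray,
    use_best_guess: bool = False,
    per_snp: bool = True,
) -> AccuracyTable:
    """Full accuracy table for a test set.

    ``observed`` carries the true medium-density genotypes of the test
    individuals (same id order as the imputation result); ``mask`` is the
    index of withheld markers."""
    if list(observed.ids) != list(result.ids):
        raise ValueError("observed and imputed id lists differ")
    imp = result.best_guess if use_best_guess else result.dosages
    mask = np.asarray(mask)
    rows = [
        individual_accuracy(observed.values[i], imp[i], mask)
        for i in range(observed.n_individuals)
    ]
    per_ind = pd.Series(rows, index=list(observed.ids), name="accuracy")
    per_snp_series = None
    if per_snp and observed.n_individuals >= 2:
        cols = [
            snp_accuracy(observed.values[:, j], imp[:, j]) for j in mask
        ]
        per_snp_series = pd.Series(cols, index=list(result.snp_ids[mask]), name="accuracy")
    return AccuracyTable(per_ind, per_snp_series)
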