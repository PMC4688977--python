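"""Synthetic multi-breed sheep population generator.

Emulates the statistical structure of a multi-breed resource flock:
several diverged breeds (e.g. Merino, Border Leicester, Poll Dorset,
White Suffolk), F1 crosses of non-Merino sires over Merino ewes, large
half-sib families descending from a moderate number of sires, flocks
connected through shared AI (artificial insemination) sires, a nested
low/medium-density SNP panel pair, and phenotypes carrying additive,
maternal, breed and fixed effects.

Breed divergence follows the Balding-Nichols model: per-breed allele
frequencies are Beta-distributed around an ancestral frequency with
spread controlled by Fst. Meiosis uses a Haldane map (Poisson crossover
counts, uniform crossover placement on the cM map, no interference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._random import substream
from .containers import MISSING, PANEL_BOTH, PANEL_HD_ONLY, GenotypeMatrix, HaplotypePanel, SNPMap

__all__ = [
    "BreedModel",
    "MatingDesign",
    "TraitModel",
    "PedigreeRecord",
    "EBVRecord",
    "make_snp_map",
    "simulate_founder_frequencies",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_progeny_test_ebv",
    "simulate_gc_scores",
    "inject_missing",
    "mask_to_low_density",
    "pedigree_frame",
]


@dataclass
class BreedModel:
    """Breed set and between-breed differentiation (Balding-Nichols Fst).

    ``n_ancestral_haplotypes`` controls within-breed linkage
    disequilibrium: founder haplotypes are recombinant mosaics of a
    finite per-breed pool of ancestral haplotypes, emulating the
    bottlenecked haplotype diversity of livestock breeds. Set to 0 to
    draw founder alleles marker-independently (no within-breed LD).
    """

    breed_names: list
    fst: float = 0.1
    ancestral_freq_range: tuple = (0.1, 0.9)
    n_ancestral_haplotypes: int = 30

    def __post_init__(self):
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must satisfy 0 < low < high < 1")
        if len(self.breed_names) < 1:
            raise ValueError("at least one breed required")
        if self.n_ancestral_haplotypes < 0:
            raise ValueError("n_ancestral_haplotypes must be >= 0")


@dataclass
class MatingDesign:
    """Counts of founders and progeny and the flock/AI-sire structure.

    ``purebred_progeny`` maps breed -> number of purebred progeny;
    ``cross_progeny`` maps (sire_breed, dam_breed) -> number of F1 progeny.
    A fraction ``ai_sire_fraction`` of matings use a shared pool of AI
    sires that service every flock; the remaining sires are local to one
    flock. Progeny come in half-sib families of ~``progeny_per_sire``.
    """

    n_founder_sires: dict
    n_founder_dams: dict
    purebred_progeny: dict = field(default_factory=dict)
    cross_progeny: dict = field(default_factory=dict)
    n_flocks: int = 3
    ai_sire_fraction: float = 0.5
    progeny_per_sire: int = 10
    birth_years: tuple = (1, 2)

    def validate(self):
        if self.n_flocks < 1:
            raise ValueError("n_flocks must be >= 1")
        if not (0.0 <= self.ai_sire_fraction <= 1.0):
            raise ValueError("ai_sire_fraction must be in [0, 1]")
        used_sire_breeds = set(self.purebred_progeny) | {b for b, _ in self.cross_progeny}
        used_dam_breeds = set(self.purebred_progeny) | {b for _, b in self.cross_progeny}
        for b in used_sire_breeds:
            if self.n_founder_sires.get(b, 0) < 1:
                raise ValueError(f"design needs sires of breed {b} but no founders configured")
        for b in used_dam_breeds:
            if self.n_founder_dams.get(b, 0) < self.n_flocks:
                raise ValueError(
                    f"design needs at least one {b} dam per flock "
                    f"({self.n_flocks} flocks, {self.n_founder_dams.get(b, 0)} dams)"
                )


@dataclass
class TraitModel:
    """Variance components and fixed-effect structure of a simulated trait.

    ``fixed_effect_levels`` maps factor name to a dict of level -> effect
    (for class factors: birth_type, rearing_type, sex, contemporary group)
    or ``{"slope": v}`` for the age/weight covariates. Factors absent from
    the mapping contribute nothing.
    """

    var_additive: float
    var_maternal: float = 0.0
    var_breed: float = 0.0
    var_residual: float = 1.0
    n_qtl: int = 100
    fixed_effect_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("var_additive", "var_maternal", "var_breed", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (self.var_additive + self.var_maternal + self.var_breed + self.var_residual) <= 0:
            raise ValueError("at least one variance component must be positive")


@dataclass
class PedigreeRecord:
    id: str
    sire_id: str | None
    dam_id: str | None
    sex: str
    breed_composition: dict
    flock: int
    birth_year: int

    def __post_init__(self):
        total = sum(self.breed_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"breed proportions of {self.id} sum to {total}, not 1")


@dataclass
class EBVRecord:
    id: str
    true_bv: float
    reported_ebv: float
    target_accuracy: float


def make_snp_map(
    n_chromosomes: int = 2,
    markers_per_chromosome: int = 500,
    chrom_length_cm: float = 100.0,
    low_density_every: int = 4,
) -> SNPMap:
    """Evenly spaced marker map with every ``low_density_every``-th marker
    on the nested low-density subpanel (the first marker included)."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        for j in range(markers_per_chromosome):
            cm = (j + 0.5) * chrom_length_cm / markers_per_chromosome
            rows.append(
                {
                    "snp_id": f"snp{c}_{j}",
                    "chrom": c,
                    "pos_bp": int((j + 1) * 1_000_000),
                    "pos_cm": cm,
                    "panel": PANEL_BOTH if j % low_density_every == 0 else PANEL_HD_ONLY,
                }
            )
    return SNPMap(pd.DataFrame(rows))


def simulate_founder_frequencies(
    n_snps: int, breed_model: BreedModel, seed: int
) -> pd.DataFrame:
    """Per-breed allele frequencies under the Balding-Nichols model.

    Each SNP has an ancestral frequency p ~ U(low, high); each breed draws
    p_b ~ Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst), so that across replicate
    SNPs Var(p_b) = Fst * p(1-p). Fst = 0 collapses to p_b = p exactly.
    Returns a DataFrame with column ``ancestral`` plus one per breed.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = substream(seed, "founder-freqs")
    lo, hi = breed_model.ancestral_freq_range
    p = rng.uniform(lo, hi, size=n_snps)
    out = {"ancestral": p}
    fst = breed_model.fst
    for breed in breed_model.breed_names:
        if fst == 0.0:
            pb = p.copy()
        else:
            scale = (1.0 - fst) / fst
            pb = rng.beta(p * scale, (1.0 - p) * scale)
            # keep frequencies away from exact fixation so founders stay polymorphic-ish
            pb = np.clip(pb, 1e-6, 1.0 - 1e-6)
        out[breed] = pb
    return pd.DataFrame(out)


def _meiosis(hap_pair: np.ndarray, chrom_slices, pos_cm: np.ndarray, rng) -> np.ndarray:
    """One gamete from a (2, m) haplotype pair; Haldane model per chromosome."""
    m = hap_pair.shape[1]
    gamete = np.empty(m, dtype=np.int8)
    for sl in chrom_slices:
        cm = pos_cm[sl]
        length_morgans = (cm[-1] - cm[0]) / 100.0 if len(cm) > 1 else 0.0
        start = rng.integers(0, 2)
        if length_morgans <= 0:
            gamete[sl] = hap_pair[start, sl]
            continue
        n_xo = rng.poisson(length_morgans)
        if n_xo == 0:
            gamete[sl] = hap_pair[start, sl]
            continue
        xo = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
        seg = (np.searchsorted(xo, cm, side="right") + start) % 2
        idx = np.arange(sl.start, sl.stop)
        gamete[sl] = hap_pair[seg, idx]
    return gamete


class _Population:
    """Mutable builder used internally by simulate_population."""

    def __init__(self, snp_ids):
        self.ids: list = []
        self.haps: list = []
        self.records: list = []
        self.snp_ids = snp_ids
        self._index: dict = {}

    def add(self, rec: PedigreeRecord, hap: np.ndarray):
        self._index[rec.id] = len(self.ids)
        self.ids.append(rec.id)
        self.haps.append(hap)
        self.records.append(rec)

    def hap_of(self, ident: str) -> np.ndarray:
        return self.haps[self._index[ident]]

    def record_of(self, ident: str) -> PedigreeRecord:
        return self.records[self._index[ident]]


def simulate_population(
    breed_model: BreedModel,
    snp_map: SNPMap,
    design: MatingDesign,
    seed: int,
) -> tuple[GenotypeMatrix, HaplotypePanel, list]:
    """Simulate founders and one progeny generation.

    Founder haplotypes are drawn marker-independently from breed allele
    frequencies; progeny gametes recombine on the cM map. Returns the
    genotypes and true haplotypes of all individuals (founders + progeny)
    and the pedigree records.
    """
    design.validate()
    freqs = simulate_founder_frequencies(len(snp_map), breed_model, seed)
    rng = substream(seed, "population")
    pos_cm = snp_map.pos_cm()
    chrom_slices = []
    for chrom in snp_map.chromosomes:
        idx = snp_map.chrom_index(chrom)
        chrom_slices.append(slice(int(idx[0]), int(idx[-1]) + 1))

    pop = _Population(snp_map.snp_ids)

    sires: dict = {}
    dams: dict = {}
    n_anc = breed_model.n_ancestral_haplotypes
    for breed in breed_model.breed_names:
        pb = freqs[breed].to_numpy()
        pool = None
        if n_anc >= 2:
            pool = (rng.random((n_anc, len(snp_map))) < pb).astype(np.int8)

        def founder_hap():
            if pool is None:
                return (rng.random(len(snp_map)) < pb).astype(np.int8)
            i, j = rng.choice(len(pool), 2, replace=False)
            return _meiosis(np.stack([pool[i], pool[j]]), chrom_slices, pos_cm, rng)

        for role, count, store, sex in (
            ("S", design.n_founder_sires.get(breed, 0), sires, "M"),
            ("D", design.n_founder_dams.get(breed, 0), dams, "F"),
        ):
            ids = []
            for i in range(count):
                ident = f"{breed}_{role}{i}"
                hap = np.stack([founder_hap(), founder_hap()])
                flock = i % design.n_flocks
                pop.add(
                    PedigreeRecord(ident, None, None, sex, {breed: 1.0}, flock, 0),
                    hap,
                )
                ids.append(ident)
            store[breed] = ids

    def mate(sire_breed, dam_breed, n_progeny, tag):
        sire_pool = sires[sire_breed]
        n_ai = max(1, int(round(design.ai_sire_fraction * len(sire_pool))))
        ai_sires = sire_pool[:n_ai]
        local_sires = sire_pool[n_ai:] or sire_pool
        dams_by_flock: dict = {}
        for d in dams[dam_breed]:
            dams_by_flock.setdefault(pop.record_of(d).flock, []).append(d)
        produced = 0
        child = 0
        while produced < n_progeny:
            use_ai = rng.random() < design.ai_sire_fraction
            if use_ai:
                sire = ai_sires[rng.integers(0, len(ai_sires))]
                flock = int(rng.integers(0, design.n_flocks))
            else:
                sire = local_sires[rng.integers(0, len(local_sires))]
                flock = pop.record_of(sire).flock
            if flock not in dams_by_flock:
                flock = sorted(dams_by_flock)[0]
            fam = min(design.progeny_per_sire, n_progeny - produced)
            for _ in range(fam):
                dam = dams_by_flock[flock][rng.integers(0, len(dams_by_flock[flock]))]
                g_s = _meiosis(pop.hap_of(sire), chrom_slices, pos_cm, rng)
                g_d = _meiosis(pop.hap_of(dam), chrom_slices, pos_cm, rng)
                sire_comp = pop.record_of(sire).breed_composition
                dam_comp = pop.record_of(dam).breed_composition
                comp: dict = {}
                for b, pr in sire_comp.items():
                    comp[b] = comp.get(b, 0.0) + pr / 2.0
                for b, pr in dam_comp.items():
                    comp[b] = comp.get(b, 0.0) + pr / 2.0
                ident = f"{tag}_{child}"
                sex = "M" if rng.random() < 0.5 else "F"
                year = design.birth_years[int(rng.integers(0, len(design.birth_years)))]
                pop.add(
                    PedigreeRecord(ident, sire, dam, sex, comp, flock, year),
                    np.stack([g_s, g_d]),
                )
                child += 1
                produced += 1

    for breed, n in design.purebred_progeny.items():
        mate(breed, breed, n, f"{breed}x{breed}")
    for (sb, db), n in design.cross_progeny.items():
        mate(sb, db, n, f"{sb}x{db}")

    panel = HaplotypePanel(pop.ids, snp_map.snp_ids, np.stack(pop.haps))
    return panel.genotypes(), panel, pop.records


def pedigree_frame(records: list) -> pd.DataFrame:
    """Pedigree records as a tidy table; breed proportions in wide columns."""
    breeds = sorted({b for r in records for b in r.breed_composition})
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "sire_id": r.sire_id,
            "dam_id": r.dam_id,
            "sex": r.sex,
            "flock": r.flock,
            "birth_year": r.birth_year,
        }
        for b in breeds:
            row[f"prop_{b}"] = r.breed_composition.get(b, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_phenotypes(
    records: list,
    haplotypes: HaplotypePanel,
    trait_model: TraitModel,
    seed: int,
    phenotyped_ids: list | None = None,
) -> pd.DataFrame:
    """Phenotypes y = fixed effects + g + w(dam) + q(breed) + e.

    Additive values g come from normal effects at ``n_qtl`` randomly placed
    markers of the medium-density panel, centered and rescaled so the
    realised variance equals ``var_additive`` exactly. Maternal effects are
    i.i.d. per dam; animals with unknown dam get a zero maternal
    contribution (with a warning). Breed effects are i.i.d. per breed and
    enter weighted by breed proportions. Returns a table with the
    phenotype, every fixed-effect column and the true breeding value.
    """
    rng = substream(seed, "phenotypes")
    ids = phenotyped_ids if phenotyped_ids is not None else list(haplotypes.ids)
    panel = haplotypes.select_ids(ids)
    geno = panel.genotypes().values.astype(float)
    n, m = geno.shape

    if trait_model.var_additive > 0:
        n_qtl = min(trait_model.n_qtl, m)
        qtl_idx = rng.choice(m, size=n_qtl, replace=False)
        effects = rng.normal(0.0, 1.0, size=n_qtl)
        g = geno[:, qtl_idx] @ effects
        g = g - g.mean()
        sd = g.std()
        if sd > 0:
            g = g * np.sqrt(trait_model.var_additive) / sd
    else:
        g = np.zeros(n)

    recs = {r.id: r for r in records}
    dam_ids = [recs[i].dam_id for i in ids]
    if trait_model.var_maternal > 0:
        unique_dams = sorted({d for d in dam_ids if d is not None})
        w_by_dam = dict(
            zip(unique_dams, rng.normal(0, np.sqrt(trait_model.var_maternal), len(unique_dams)))
        )
        if any(d is None for d in dam_ids):
            warnings.warn("animals with unknown dam receive zero maternal effect")
        w = np.array([w_by_dam.get(d, 0.0) for d in dam_ids])
    else:
        w = np.zeros(n)

    breeds = sorted({b for i in ids for b in recs[i].breed_composition})
    if trait_model.var_breed > 0:
        q_by_breed = dict(zip(breeds, rng.normal(0, np.sqrt(trait_model.var_breed), len(breeds))))
        q = np.array(
            [sum(pr * q_by_breed[b] for b, pr in recs[i].breed_composition.items()) for i in ids]
        )
    else:
        q = np.zeros(n)

    e = (
        rng.normal(0, np.sqrt(trait_model.var_residual), n)
        if trait_model.var_residual > 0
        else np.zeros(n)
    )

    fx = trait_model.fixed_effect_levels
    birth_type = rng.integers(1, 3, size=n)
    rearing_type = rng.integers(1, 3, size=n)
    sex = np.array([recs[i].sex for i in ids])
    age = rng.normal(300.0, 20.0, size=n)
    weight = rng.normal(45.0, 5.0, size=n)
    mgmt = rng.integers(1, 3, size=n)
    flock = np.array([recs[i].flock for i in ids])
    year = np.array([recs[i].birth_year for i in ids])
    cg = np.array([f"{f}_{y}_{g_}" for f, y, g_ in zip(flock, year, mgmt)])

    def class_effect(factor, levels):
        table = fx.get(factor, {})
        return np.array([table.get(lv, 0.0) for lv in levels])

    fixed = (
        class_effect("birth_type", birth_type)
        + class_effect("rearing_type", rearing_type)
        + class_effect("sex", sex)
        + class_effect("contemporary_group", cg)
        + fx.get("age", {}).get("slope", 0.0) * age
        + fx.get("weight", {}).get("slope", 0.0) * weight
    )

    y = fixed + g + w + q + e
    return pd.DataFrame(
        {
            "id": ids,
            "y": y,
            "true_bv": g,
            "birth_type": birth_type,
            "rearing_type": rearing_type,
            "sex": sex,
            "age": age,
            "weight": weight,
            "flock": flock,
            "birth_year": year,
            "mgmt_group": mgmt,
            "dam_id": dam_ids,
        }
    )


def simulate_progeny_test_ebv(
    true_bvs: pd.Series, accuracy_spec: dict, seed: int
) -> list:
    """Progeny-test EBVs with per-sire accuracy drawn in [min, max].

    The reported EBV is r * (standardised true BV) + sqrt(1 - r^2) * noise,
    mapped back to breeding-value units, so that over many sires at fixed r
    the correlation with the truth is r. Accuracies come from a scaled Beta
    with mean ``accuracy_spec['mean']``.
    """
    lo, mean, hi = accuracy_spec["min"], accuracy_spec["mean"], accuracy_spec["max"]
    if not (0.0 < lo <= mean <= hi <= 1.0):
        raise ValueError("accuracy spec must satisfy 0 < min <= mean <= max <= 1")
    rng = substream(seed, "ebv")
    ids = list(true_bvs.index)
    tv = true_bvs.to_numpy(dtype=float)
    sd = tv.std()
    center = tv.mean()
    z = (tv - center) / sd if sd > 0 else np.zeros_like(tv)
    if hi > lo:
        m = (mean - lo) / (hi - lo)
        conc = 10.0
        r = lo + (hi - lo) * rng.beta(m * conc, (1.0 - m) * conc, size=len(ids))
    else:
        r = np.full(len(ids), lo)
    noise = rng.normal(size=len(ids))
    reported = center + sd * (r * z + np.sqrt(1.0 - r**2) * noise)
    # r = 1 exactly reproduces the true value (no noise leakage)
    reported = np.where(r >= 1.0, tv, reported)
    return [
        EBVRecord(i, float(t), float(rep), float(acc))
        for i, t, rep, acc in zip(ids, tv, reported, r)
    ]


def simulate_gc_scores(
    shape: tuple, seed: int, low_fraction: float = 0.0, low_value: float = 0.3
) -> np.ndarray:
    """Per-cell genotype-call confidence scores in [0, 1].

    Scores are high (Beta(20, 2)) except for a ``low_fraction`` of cells
    set near ``low_value``, emulating poorly clustered calls.
    """
    rng = substream(seed, "gc-scores")
    gc = rng.beta(20, 2, size=shape)
    if low_fraction > 0:
        bad = rng.random(shape) < low_fraction
        gc[bad] = np.clip(rng.normal(low_value, 0.05, size=bad.sum()), 0.0, 0.59)
    return gc


def inject_missing(genotypes: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set a random ``rate`` fraction of genotype cells to missing."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = substream(seed, "missingness")
    vals = genotypes.values.copy()
    mask = rng.random(vals.shape) < rate
    vals[mask] = MISSING
    return GenotypeMatrix(list(genotypes.ids), genotypes.snp_ids, vals)


def mask_to_low_density(
    genotypes: GenotypeMatrix, snp_map: SNPMap
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Restrict to the low-density subpanel, as done when emulating
    low-density genotyping by masking the medium-density array.

    Returns the reduced matrix and the indices of the withheld columns.
    """
    if len(snp_map) != genotypes.n_markers or not np.array_equal(
        snp_map.snp_ids, genotypes.snp_ids
    ):
        raise ValueError("snp_map does not cover the genotype columns")
    keep = snp_map.low_density_index
    if keep.size == 0:
        raise ValueError("low-density subpanel is empty")
    withheld = snp_map.hd_only_index
    return genotypes.take_markers(keep), withheld
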