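"""Scenario orchestration: the imputation / genomic-prediction grid.

A `PopulationBundle` packages one simulated multi-breed population
(genotypes, truth haplotypes, pedigree, phenotypes, progeny-test EBVs).
`run_scenario` executes mask -> (reference selection) -> imputation ->
accuracy -> optional GBLUP for one scenario; `write_report` consolidates
run reports into tables and histogram data.

Default scenario sizes are desk-scale (about a tenth of a large resource
flock: ~100-animal test sets, 100-300-animal reference sets) so a full
grid runs in minutes; larger sizes remain valid configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._random import spawn_seed, substream
from .accuracy import evaluate, summarize
from .containers import GenotypeMatrix, HaplotypePanel, SNPMap
from .gblup import GenomicMixedModel, gebv_accuracy
from .grm import compute_cross_grm, compute_grm
from .imputation import LiStephensParams, impute_set
from .popsim import (
    BreedModel,
    MatingDesign,
    TraitModel,
    make_snp_map,
    mask_to_low_density,
    pedigree_frame,
    simulate_phenotypes,
    simulate_population,
    simulate_progeny_test_ebv,
)
from .refselect import SelectionConfig, select_reference

__all__ = [
    "PopulationBundle",
    "ScenarioConfig",
    "simulate_bundle",
    "run_scenario",
    "gblup_accuracy_for_genotypes",
    "write_report",
]

BREEDS = ["Merino", "BL", "PD", "WS"]


@dataclass
class PopulationBundle:
    snp_map: SNPMap
    genotypes: GenotypeMatrix      # observed medium-density genotypes
    haplotypes: HaplotypePanel     # truth haplotypes
    records: list                  # pedigree records
    phenotypes: pd.DataFrame
    ebvs: list                     # progeny-test EBV records for founder sires
    groups: dict                   # group name -> list of progeny ids

    def group(self, name: str) -> list:
        if name not in self.groups:
            raise KeyError(f"unknown group {name!r}; have {sorted(self.groups)}")
        return self.groups[name]


@dataclass
class ScenarioConfig:
    """One cell of the scenario grid.

    test_group / ref_group name population strata (e.g. ``merino``,
    ``mixed_cross``, ``cross_BLxM``, ``nonmerino_pure``); ref_mode is
    ``random`` or ``selected`` (relatedness-based choice from the whole
    non-test pool).
    """

    name: str
    test_group: str
    n_test: int
    ref_mode: str = "random"
    ref_group: str | None = None
    n_ref: int = 200
    params: LiStephensParams = field(default_factory=LiStephensParams)
    seed: int = 0
    run_gblup: bool = False

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _classify(records) -> dict:
    groups: dict = {
        "merino": [],
        "mixed_cross": [],
        "nonmerino_pure": [],
    }
    for r in records:
        if r.sire_id is None:  # founders are parents, not study animals
            continue
        comp = r.breed_composition
        if comp.get("Merino", 0.0) == 1.0:
            groups["merino"].append(r.id)
        elif len(comp) == 2 and abs(comp.get("Merino", 0.0) - 0.5) < 1e-9:
            other = next(b for b in comp if b != "Merino")
            groups.setdefault(f"cross_{other}xM", []).append(r.id)
            groups["mixed_cross"].append(r.id)
        elif len(comp) == 1:
            groups["nonmerino_pure"].append(r.id)
    return groups


def simulate_bundle(
    seed: int,
    n_chromosomes: int = 2,
    markers_per_chromosome: int = 400,
    chrom_length_cm: float = 100.0,
    low_density_every: int = 4,
    n_merino_progeny: int = 450,
    n_cross_progeny_each: int = 150,
    n_nonmerino_progeny_each: int = 40,
    fst: float = 0.10,
    trait: TraitModel | None = None,
) -> PopulationBundle:
    """Simulate the standard desk-scale multi-breed population.

    Four breeds (Merino + three sire breeds), purebred Merino progeny,
    three F1 cross types (non-Merino sire x Merino ewe), small non-Merino
    purebred groups, half-sib families with ~50% shared AI sires across
    flocks, a nested low-density panel, phenotypes (additive h2 ~ 0.3
    plus maternal, breed and fixed effects) and progeny-test EBVs for the
    founder sires (accuracy 0.70-0.99, mean 0.88).
    """
    snp_map = make_snp_map(
        n_chromosomes, markers_per_chromosome, chrom_length_cm, low_density_every
    )
    breed_model = BreedModel(BREEDS, fst=fst)
    design = MatingDesign(
        n_founder_sires={"Merino": 45, "BL": 14, "PD": 14, "WS": 14},
        n_founder_dams={"Merino": 150, "BL": 36, "PD": 36, "WS": 36},
        purebred_progeny={
            "Merino": n_merino_progeny,
            "BL": n_nonmerino_progeny_each,
            "PD": n_nonmerino_progeny_each,
            "WS": n_nonmerino_progeny_each,
        },
        cross_progeny={
            ("BL", "Merino"): n_cross_progeny_each,
            ("PD", "Merino"): n_cross_progeny_each,
            ("WS", "Merino"): n_cross_progeny_each,
        },
        n_flocks=3,
        ai_sire_fraction=0.5,
        progeny_per_sire=10,
    )
    genotypes, haplotypes, records = simulate_population(
        breed_model, snp_map, design, seed
    )
    trait = trait or TraitModel(
        var_additive=0.30,
        var_maternal=0.05,
        var_breed=0.05,
        var_residual=0.60,
        n_qtl=100,
        fixed_effect_levels={
            "sex": {"M": 0.3, "F": 0.0},
            "birth_type": {1: 0.0, 2: -0.2},
            "age": {"slope": 0.01},
        },
    )
    phenotypes = simulate_phenotypes(records, haplotypes, trait, seed)
    sire_ids = sorted({r.sire_id for r in records if r.sire_id is not None})
    true_bv = phenotypes.set_index("id")["true_bv"]
    ebvs = simulate_progeny_test_ebv(
        true_bv.loc[sire_ids], {"min": 0.70, "mean": 0.88, "max": 0.99}, seed
    )
    return PopulationBundle(
        snp_map, genotypes, haplotypes, records, phenotypes, ebvs, _classify(records)
    )


def _sample_ids(pool: list, n: int, rng, exclude: set | None = None) -> list:
    avail = [i for i in pool if not exclude or i not in exclude]
    if n > len(avail):
        raise ValueError(f"requested {n} animals but only {len(avail)} available")
    idx = rng.choice(len(avail), size=n, replace=False)
    return [avail[i] for i in sorted(idx)]


def run_scenario(config: ScenarioConfig, bundle: PopulationBundle) -> dict:
    """Execute one scenario end-to-end; returns a JSON-serialisable report."""
    rng = substream(config.seed, "scenario", config.name)
    test_ids = _sample_ids(bundle.group(config.test_group), config.n_test, rng)
    test_set = set(test_ids)

    ld_idx = bundle.snp_map.low_density_index
    observed = bundle.genotypes.select_ids(test_ids)
    masked, withheld = mask_to_low_density(observed, bundle.snp_map)

    if config.ref_mode == "random":
        pool = bundle.group(config.ref_group or config.test_group)
        ref_ids = _sample_ids(pool, config.n_ref, rng, exclude=test_set)
    elif config.ref_mode == "selected":
        pool = [i for ids in bundle.groups.values() for i in ids]
        pool = sorted(set(pool) - test_set, key=str)
        cand_ld = bundle.genotypes.select_ids(pool).take_markers(ld_idx)
        cross = compute_cross_grm(masked, cand_ld)
        ref_ids = select_reference(
            cross, SelectionConfig(k_init=20, n_target=config.n_ref)
        )
    else:
        raise ValueError(f"unknown ref_mode {config.ref_mode!r}")

    reference = bundle.genotypes.select_ids(ref_ids)
    result = impute_set(
        masked,
        reference,
        bundle.snp_map,
        config.params,
        seed=spawn_seed(config.seed, "impute", config.name),
    )
    table = evaluate(observed, result, withheld)

    report = {
        "name": config.name,
        "config": {**asdict(config), "params": asdict(config.params)},
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_test": len(test_ids),
        "n_reference": len(ref_ids),
        "test_ids": test_ids,
        "reference_ids": ref_ids,
        "individual_accuracy": table.summary,
        "snp_accuracy": summarize(table.per_snp.to_numpy())
        if table.per_snp is not None
        else None,
    }

    if config.run_gblup:
        report["gblup"] = gblup_accuracy_for_genotypes(
            bundle, test_ids, result.dosages, marker_idx=None, label=config.name
        )
    return report


def gblup_accuracy_for_genotypes(
    bundle: PopulationBundle,
    pred_ids: list,
    values: np.ndarray,
    marker_idx: np.ndarray | None = None,
    label: str = "",
    return_objects: bool = False,
):
    """GBLUP accuracy when the prediction reference carries ``values``.

    ``values`` are genotypes or dosages of ``pred_ids`` on the full panel
    (or on ``marker_idx`` columns). Validation animals are the founder
    sires of the prediction set, added to G with their observed genotypes
    on the same markers, and excluded from the phenotype records; their
    GEBVs are correlated with progeny-test EBVs.
    """
    recs = {r.id: r for r in bundle.records}
    sires = sorted({recs[i].sire_id for i in pred_ids if recs[i].sire_id is not None})
    with_ebv = {e.id for e in bundle.ebvs}
    sires = [s for s in sires if s in with_ebv]
    obs_sires = bundle.genotypes.select_ids(sires).values.astype(float)
    pred = np.asarray(values, dtype=float)
    if marker_idx is not None:
        obs_sires = obs_sires[:, marker_idx]
        if pred.shape[1] != len(marker_idx):
            pred = pred[:, marker_idx]
    stacked = np.vstack([pred, obs_sires])
    grm = compute_grm(stacked, ids=list(pred_ids) + sires)
    pheno = bundle.phenotypes[bundle.phenotypes["id"].isin(pred_ids)]
    ped = pedigree_frame(bundle.records)
    model = GenomicMixedModel.from_dataframes(pheno, grm, pedigree=ped)
    res = model.fit()
    r, n_val = gebv_accuracy(res.gebv, bundle.ebvs)
    out = {
        "label": label,
        "gebv_accuracy": r,
        "n_validation": n_val,
        "variance_components": res.varcomp.components,
        "converged": res.varcomp.converged,
    }
    if return_objects:
        return out, res, grm
    return out


def write_report(reports: list, outdir, make_plots: bool = True) -> dict:
    """Consolidate run reports: summary grid TSV, per-run JSON, histogram
    data TSV and (optionally) histogram PNGs."""
    if not reports:
        raise ValueError("no run reports to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "runs.json").write_text(json.dumps(reports, indent=2, default=str))

    rows = []
    for rep in reports:
        s = rep["individual_accuracy"]
        rows.append(
            {
                "scenario": rep["name"],
                "seed": rep["seed"],
                "n_test": rep["n_test"],
                "n_reference": rep["n_reference"],
                "mean_accuracy": s["mean"],
                "sd_accuracy": s["sd"],
                "min_accuracy": s["min"],
                "max_accuracy": s["max"],
                "gebv_accuracy": rep.get("gblup", {}).get("gebv_accuracy")
                if rep.get("gblup")
                else None,
            }
        )
    grid = pd.DataFrame(rows)
    grid.to_csv(outdir / "summary_grid.tsv", sep="\t", index=False)

    hist_rows = []
    for rep in reports:
        s = rep["individual_accuracy"]
        for lo, cnt in zip(s["hist_edges"][:-1], s["hist_counts"]):
            hist_rows.append({"scenario": rep["name"], "bin_low": lo, "count": cnt})
    pd.DataFrame(hist_rows).to_csv(outdir / "histograms.tsv", sep="\t", index=False)

    paths = {
        "runs": str(outdir / "runs.json"),
        "grid": str(outdir / "summary_grid.tsv"),
        "histograms": str(outdir / "histograms.tsv"),
    }
    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for rep in reports:
            s = rep["individual_accuracy"]
            edges = np.asarray(s["hist_edges"])
            ax.stairs(s["hist_counts"], edges, label=rep["name"])
        ax.set_xlabel("imputation accuracy (per-individual r)")
        ax.set_ylabel("count")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "accuracy_histograms.png", dpi=120)
        plt.close(fig)
        paths["plot"] = str(outdir / "accuracy_histograms.png")
    return paths
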