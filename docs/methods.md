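# Methods

This note records the models implemented in `ovimp`, the assumptions
behind them, the parameters that matter, and the design choices made
where the design was genuinely open.

## Population simulator

The simulator emulates a multi-breed sheep resource flock at desk scale.

**Breed divergence.** Each SNP has an ancestral allele frequency
p ~ U(0.1, 0.9); each breed draws its own frequency from the
Balding–Nichols distribution Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst), so
that across SNPs Var(p_b) = Fst·p(1−p). Default Fst = 0.10, a typical
magnitude for differentiation among commercial sheep breeds; Fst = 0 is
handled exactly (p_b = p).

**Within-breed linkage disequilibrium.** Founder haplotypes are not
drawn marker-independently: each breed first receives a pool of
`n_ancestral_haplotypes` (default 30) haplotypes drawn from its
frequencies, and every founder haplotype is a one-meiosis recombinant
mosaic of two pool members. This models the bottlenecked haplotype
diversity of livestock breeds and is what gives population-based phasing
and imputation their signal: unrelated animals of one breed share
ancestral haplotype segments. Setting the pool to 0 recovers the LD-free
(marker-independent) founder model, under which only family information
remains and phasing/imputation degrade sharply — a useful control, but
not a realistic breed.

**Meiosis.** Haldane model: crossover counts per chromosome are
Poisson(map length in Morgans), crossover positions uniform on the cM
map, no interference, random start haplotype.

**Mating design.** Founder sires and dams per breed; dams are assigned
round-robin to flocks; a configurable fraction of matings (default 0.5)
use a shared AI-sire pool that services every flock — this is what
connects flocks genetically — while the rest use flock-local sires.
Progeny arrive in half-sib families of ~`progeny_per_sire` (default 10).
F1 crosses mate non-Merino sires to Merino ewes and carry breed
composition {sire breed: 0.5, Merino: 0.5}. One progeny generation only;
multi-generation crossbreeding is out of scope.

**Phenotypes.** y = fixed effects + g + w(dam) + q(breed) + e. Additive
values g come from normal effects at `n_qtl` (default 100) random
medium-density markers, centred and rescaled so the realised variance
equals σ²g exactly — the exact rescaling makes variance-recovery tests
sharp. Maternal effects are i.i.d. per dam (unknown dam → zero
contribution, with a warning), breed effects i.i.d. per breed weighted
by breed proportions. Fixed effects (birth type, rearing type, sex, age
and weight covariates, contemporary group = flock × year × management
group) take user-specified level effects. Default bundle trait:
σ²g = 0.30, σ²w = 0.05, σ²q = 0.05, σ²e = 0.60 (h² ≈ 0.3, a realistic
value for sheep growth/fleece traits).

**Progeny-test EBVs.** Per-sire accuracy r is drawn from a Beta scaled
to [0.70, 0.99] with mean 0.88 (concentration 10); the reported EBV is
r·(standardised true BV) + √(1−r²)·noise mapped back to BV units, so
cor(reported, true) → r. r = 1 reproduces the true value exactly.

**What the simulator does not model.** Real ovine LD maps and genome
coordinates, selection history, genotyping error beyond the per-cell GC
score, Merino strain substructure, and multi-generation pedigrees.
Passing trend tests therefore demonstrate the *relative* behaviour of
reference designs under realistic population structure, not the absolute
accuracies of any particular array.

## Quality control

Filters run in a fixed, documented order (per-cell GC masking → marker
call rate → heterozygosity outliers → MAF → excluded chromosomes → HWE →
duplicate samples); heterozygosity statistics are computed over the
markers surviving the call-rate stage. The heterozygosity rule is
marker-level (the rule sits in a SNP list; a sample-level reading is
also defensible but was not chosen). HWE uses a 1-df chi-square rather
than an exact test: at the default floor (P < 1e-15) the distinction is
immaterial. Duplicate pairs are Pearson r on 0/1/2 codes over
pairwise-complete markers; the later-indexed member is dropped
(deterministic; the choice of member is otherwise arbitrary). Defaults:
call rate ≥ 0.90, GC ≥ 0.6, |het z| ≤ 3, MAF ≥ 0.01 (strictly-below
removed), HWE P ≥ 1e-15, duplicate r ≤ 0.98, chromosomes X/Y excluded.

## Genomic relationships

VanRaden method 1: G = McMc′/2Σp(1−p) with Mc = M − 2p. Allele
frequencies are estimated from the sample being analysed (pooled test +
candidates for the rectangular block, which therefore equals the
corresponding block of the stacked-matrix G); base-population frequencies
are not observable here. Monomorphic markers drop out of numerator and
denominator. Missing genotypes must be filled first (per-marker mean
imputation is provided); dosages are accepted directly, so G from
imputed data uses the information in fractional dosages.

## Reference selection

For each target, its k most related candidates (ties: higher
relationship, then lexicographic id); union; k grows by 1 (configurable
stride) until the union reaches the requested size; overshoot is pruned
by removing candidates with the lowest mean relationship to the whole
test set. Mean relationships do not change during pruning, so pruning is
a single rank-and-cut rather than an iterative recomputation — the
iteration granularity is unspecified in the underlying procedure and the
batch form is deterministic and cheaper. An optional diversity
post-filter (cap on within-set relationship, back-filled greedily) is
provided but off by default: on strongly half-sib-structured data it
barely changes the selected set.

## Imputation engine

A Li–Stephens copying HMM stands in for the localized
haplotype-cluster imputer used in large livestock evaluations; it is the
standard, verifiable population imputer, and every kernel here is tested
against exhaustive path enumeration. Parameters: copying error ε
(default 0.003), switch probability ρ_j = 1 − exp(−4·Ne·d_j/H) with
Ne = 100 and d_j the inter-marker distance in Morgans (co-located
markers get d = 1e-8 to keep the chain irreducible; chromosome starts
get ρ = 1, which makes chromosomes exactly independent, so the
per-chromosome flag changes chunking, never results).

**Phasing** (10 iterations by default): heterozygote phases start
random; each iteration re-phases every individual against the current
haplotypes of all others, restricted to its `n_surrogates` (default 30)
most allele-sharing haplotypes for the quadratic-cost diploid step.
Burn-in iterations *sample* the ordered pair of copying paths from the
joint posterior (forward filtering, backward sampling); the final
iteration takes the Viterbi pair. Sampling during burn-in matters:
deterministic Viterbi updates from a random start lock into
self-consistent but wrong phase configurations, and the sampled chain
escapes them. With the default population structure this reaches a mean
switch-error rate of ~3–5% on a 200-individual, 500-marker panel.
Heterozygous sites where both copied alleles agree are phase-ambiguous;
they inherit the previous orientation (deterministic).

**Imputation** follows modern pre-phasing practice: the target is phased
on its typed scaffold by diploid Viterbi against the reference, then
each scaffold haplotype runs a haploid forward–backward pass over all
markers; dosage = sum of the two haploid allele-1 posteriors; typed
non-missing markers pass through unchanged, and best-guess genotypes are
round-half-to-even of the dosage. This factorised architecture is O(H)
per state update rather than the O(H²) of the unphased pair HMM; the
two models agree closely when phase is well determined (tested), and the
dosage of the factorised model equals the ordered-pair path-enumeration
expectation under the phased emission model exactly (tested to 1e-8).
Accuracy statistics default to dosages (strictly more informative);
best-guess correlation is available as a switch.

## REML and GBLUP

Variance components by average-information REML: score and AI matrix
from P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹; components pushed out of the
parameter space by an update are pinned at a floor of 1e-8 × phenotypic
variance and flagged as boundary estimates; an EM-REML step substitutes
when the AI system is singular. (A pure reject-and-EM fallback was tried
first and converges geometrically slowly for null components.)
Convergence: max relative change < 1e-6, at most 200 rounds;
non-convergence is flagged, never silent. Models with a single genomic
term run in the eigenbasis of ZGZ′ — the identical REML objective at
O(n·p²) per iteration after one eigendecomposition — which is what makes
n = 2000 parameter-recovery replicates affordable; the dense and
spectral paths agree on shared instances (tested).

Solutions come from Henderson's mixed-model equations with λ_i =
σ̂²e/σ̂²_i; boundary terms are dropped (their GEBVs are the
complete-shrinkage limit, zero). The fixed design uses reference-level
coding with age and weight as centred covariates, reduced to full column
rank by pivoted QR; the breed term is fitted only when more than one
breed is represented (in single-breed data Z1Q is constant and
confounded with the intercept). Validation sires enter G with their
observed genotypes, carry no phenotype records, and their GEBVs are
correlated with progeny-test EBVs. GRM-vs-GRM correlations vectorise the
upper triangle including the diagonal (the diagonal carries real signal
about imputation-induced inbreeding distortion; excluding it is the
other defensible choice).

## Scenario grid and problem sizes

The pipeline's default desk-scale population holds ~1360 animals on two
100-cM chromosomes with 800 markers, of which every fourth is on the
low-density subpanel (the same 1:4 nesting as a 12k-in-50k pair): 450
purebred Merino progeny, 150 of each F1 cross, 40 of each non-Merino
purebred, founders on top. Scenario test sets are 50–120 animals and
reference sets 50–300 — about a tenth of the corresponding field-scale
study — chosen so the full grid, including five-replicate trend checks,
runs in minutes; all sizes remain ordinary configuration and scale up
unchanged. Trend checks compare replicate means: within-breed reference
size 50 → 100 → 200 (the unsaturated regime; with this much haplotype
sharing a 200-animal within-breed reference already imputes at r ≈
0.97), reference composition (own-breed > crossbred > other-breed),
selected vs random reference of equal size (higher mean, narrower
range), and the GBLUP genotype-source ordering (observed 50k ≥
high-accuracy imputed ≥ observed 12k ≥ low-accuracy imputed, with a 0.02
Monte-Carlo tolerance on the ≥ relations across five replicates).

## Determinism

Every stochastic operation draws from a named substream of one
user-facing integer seed (`numpy.random.SeedSequence` spawn keys hashed
from stable string tags), so adding draws to one stage never perturbs
another and identical seeds give bit-identical outputs end to end —
including the scenario runner and the acceptance script.

## Known limitations

- The phaser's switch-error rate degrades as within-breed LD weakens or
  the surrogate count is reduced; it is a population phaser and makes no
  use of pedigree information (family-based imputation is deliberately
  out of scope).
- Imputation accuracy at desk scale saturates quickly for within-breed
  references, so the size trend is only assessed in its unsaturated
  range.
- REML standard errors are not reported (the AI matrix would provide
  them; the pipeline's comparisons rest on replicate spread instead).
- The QC heterozygosity filter needs a reasonable number of markers to
  estimate its mean/SD; on toy panels the SD is dominated by the
  planted outliers themselves.
- Single-trait analyses only; Bayesian whole-genome regression and
  multi-trait REML are out of scope.
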