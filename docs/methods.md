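# Methods

This note documents the models, parameter choices and known limitations of
`binderqc`, in the order the pipeline runs them.

## Synthetic competition generator (`binderqc.simulate`)

The generator emulates a pooled CAR-T proliferation screen of designed
80-residue binders. Its purpose is mechanistic test coverage, not sequence
realism: every planted parameter must be recoverable by the downstream
analysis, with known ground truth.

**Design classes.** Four categories span the outcomes seen in large
design-library screens:

| class | K+E-helix target | helix target | Cys | planted log₂ effect | dropout |
|---|---|---|---|---|---|
| `functional_enriched` | 0.18 | 0.75 | 0 | +1.5 | no |
| `neutral` | 0.04 | 0.55 | 0 | 0 | no |
| `mpnn_ke_dropout` | 0.35 | 0.83 | 0 | — | yes |
| `cys_depleting` | 0.04 | 0.50 | 4 | −1.5 | no |

The K+E-helix targets are the observed category means in screened design
cohorts (≈35% of residues for non-recovered fixed-backbone-model designs,
15–18% for recovered/proliferating ones, ≈4% for designs with no
significant change), and the dropout class is ≈83% helical. Default class
counts (70/600/500/30, total 1,200) mirror the observed proportions:
roughly 42% of designs not recovered, ≈6% hits, a small depleted tail.

**Sequence construction is positional.** Helical residues are laid out in
1–3 contiguous blocks covering round(h·L) positions; round(k·L) of them
are filled with K or E (uniformly), the rest of the helix from a natural
background composition excluding C/K/E (so the planted K+E-helix ratio is
exact to rounding), and coil positions from a background excluding C.
Per-design targets are jittered uniformly ±0.04 around the class mean —
combined with rounding (1/160 at L=80) the realized values stay within
±0.05 of the class target, which the metrics module verifies in tests. A
class target of exactly 0 is honored exactly (no jitter). SS strings are
emitted as ground truth; no structure prediction is involved. Cysteines
are placed at coil positions.

**DNA.** Reverse translation samples codons uniformly over synonymous
codons of the standard genetic code. K (AAA/AAG) and E (GAA/GAG) are
A-rich, so K/E-rich proteins reproducibly yield adenosine-dinucleotide-rich,
lower-entropy DNA — the same coupling that makes DNA-level features
predictive in real libraries.

**Counts.** Input abundances are log-normal (σ = 0.7 on the natural-log
scale, a typical pooled-library spread). Post-selection relative abundance
multiplies in 2^(fitness), the condition-specific 2^(effect) (CD20+ only),
and 2^(−10) for dropout designs, which pins their expected per-replicate
counts well below the 25-read recovery threshold at the default depth.
Abundances are renormalized per condition — sequencing depth is fixed at
10⁶ expected reads per replicate — so strongly unbalanced planted effects
produce the usual compositional bias in fold-change estimates; validation
cohorts plant balanced up/down effects when unbiasedness is under test.
Replicate counts are gamma-Poisson (NB) with dispersion φ = 0.1, i.e.
variance μ(1+φμ), matching the parameterization the test assumes. An
optional jackpot mechanism multiplies a clone's replicate mean by
`jackpot_scale` with probability `jackpot_prob` (default off), emulating
stochastic clonal expansion. Screen depth and dispersion are not reported
quantities for real screens of this kind; they are explicit configuration,
and the defaults above are this package's choices.

All randomness flows from `SimConfig.seed` through spawned
`numpy.random.Generator` streams; identical configs give byte-identical
FASTA/TSV outputs. A test audits the package for unseeded RNG use.

**What the generator does not emulate:** PCR/sequencing error,
methotrexate selection dynamics, real secondary-structure diversity
(strands are never planted), within-team sequence redundancy, or any
binding-affinity structure. Passing tests therefore demonstrate that the
analysis recovers planted statistical structure, not that it is robust to
every artifact of real screens.

## Sequence features (`binderqc.seqfeats`)

Entropies are Shannon entropies in bits (log₂): the conventional DNA
entropy thresholds (1.85/1.9) sit just below the 2-bit maximum of the
4-symbol alphabet, which pins the base. "AA repeats" are overlapping AA
dinucleotide occurrences in the DNA and "EE repeats" overlapping EE
dipeptide occurrences in the protein; the alternative run-based semantics
(total E residues in runs ≥ 2) is computed alongside (`e_run_residues`)
and the filter can be switched to it, since published repeat counts do not
always state the convention. Ambiguity codes and `X` residues are rejected
at parse time; `coerce_x_residues` provides the vendor-style `X→L` escape
hatch. k-mer statistics default to k ∈ {1,2,3} entropies; the feature
schema is written as JSON next to every table and is extensible.

## Structure features (`binderqc.structfeats`)

Helix assignment from CA traces uses a P-SEA-style distance rule:
residue i is a helix candidate when d(i,i+3) ∈ [4.9, 5.6] Å and
d(i,i+4) ∈ [5.9, 6.7] Å, and candidate runs of ≥ 5 residues are labeled H
(extended to the i+4 window they certify). The shortest detectable helix
is therefore 9 residues; an ideal helix (rise 1.5 Å, twist 100°, radius
2.3 Å: d(i,i+3) ≈ 5.05 Å, d(i,i+4) ≈ 6.20 Å) is fully labeled, and an
extended chain (d(i,i+3) ≈ 11.4 Å) never is. Strand assignment is not
implemented; everything non-helical is C. Precomputed SS strings take
precedence over geometry, since screens typically consume external
predictors' structures.

The K+E-helix ratio is defined parameter-free as
(#residues that are K or E and labeled H) / chain length, matching the
0–0.35 observed range; the helix-level alternative ("residues in helices
whose own K+E content ≥ cutoff") is exposed as
`ke_helix_ratio_helixlevel` for comparison against released feature
tables. Disulfides pair cysteines greedily nearest-first at SG–SG ≤ 2.5 Å
(CB–CB ≤ 4.5 Å when SG is absent), each cysteine in at most one pair;
both cutoffs are conventional and configurable.

## Screen analysis (`binderqc.screen`)

Recovery: ≥ 25 reads in all six screen replicates (the input column is
excluded); failing designs leave the analysis and the FDR universe
entirely. Normalization is CPM by default with TMM factors optional.
log₂FC uses a 0.5-CPM pseudocount on condition means.

The significance engine replaces an external count-model package with an
exact conditional NB test: library sizes are equalized to their geometric
mean by linear scaling (rounding group sums to integers — an approximation
to quantile adjustment that is exact for equal library sizes), a common
dispersion is estimated by method-of-moments on equalized counts
(φ̂ = (s²−m)/m², averaged over designs with mean ≥ 1) and shrunk 80/20
toward the per-design estimates (weight configurable; 0 gives pure common
dispersion), and the double-tail conditional p-value is computed as
described in the README. The double tail uses a relative tie tolerance of
1e-4 so that exactly tied outcome probabilities (rational binomial ties in
the Poisson limit) are counted in the tail; this errs conservative.
Degenerate inputs: identical counts give p = 1 exactly; an all-zero design
total gives p = 1.

Hits: FDR < 0.05 and log₂FC ≥ 1 ("enriched"); symmetric for "depleted".
The rank score is −log₁₀(FDR)·log₂FC (negative for depleted designs);
selection considers only the enriched category, descends greedily and
skips candidates sharing ≥ 50% ungapped positional identity with an
already-selected design, ties broken by design id.

Compatibility caveat: against a likelihood-based reference implementation
of the same test, small p-value discrepancies are expected from the
moment-based dispersion and the linear library equalization; the
calibration that matters (type-I control, Poisson-limit exactness) is
tested directly.

## Filter cascade (`binderqc.filters`)

The GC/entropy conditions are conjoined within each stage (they describe a
single failure mode), the remaining recovery criteria are disjuncts; the
boolean structure is explicit in the serialized spec, so an
all-conjunctive variant is one configuration away. The cysteine rule is
off by default because it discards recovered designs along with the
depleting ones. The hit-rate denominator defaults to all retained designs,
with retained-and-recovered as the alternative convention — the choice is
exposed because cohort-level percentages depend on it.

## Predictive evaluation (`binderqc.predict`)

Single-feature logistic models (matching how per-feature AUCs are
reported), fit by IRLS with an unpenalized intercept and ridge 1e-6 on the
slope (tolerance 1e-8 on the penalized log-loss); ridge keeps weights
finite under perfect separation, which is flagged. Features are z-scored
within training folds only, to avoid leakage. Folds are stratified,
shuffled by the seed, and identical seeds reproduce identical folds and
AUCs. AUC is the normalized Mann–Whitney U with midrank tie handling.
Constant or NaN-containing features are skipped. Multi-feature fits are
supported by `fit_logistic` but the ranking is deliberately univariate.

## Validation problem sizes

The automated validation (tests and `scripts/acceptance.py`) uses: 1,000
random sequences for the scalar-metric oracles; enumerated count tables
≤ 50 per group for the Poisson-limit check; twenty 2,000-design null
screens at depth 10⁶ and φ = 0.1 for type-I error; five screens of a
1,000-design cohort planting balanced twofold effects (200 up, 400 down
at half magnitude, 400 null — balanced so per-condition renormalization
cancels and the estimator is tested against the clean planted value) for
bias and power; and the 1,200-design default cohort for mechanism
recovery. These sizes were chosen to make Monte-Carlo error small relative
to the tested tolerances while keeping a full run in the minutes range on
a single core.

## Known limitations

- The exact test's library equalization is linear scaling, not quantile
  adjustment; with strongly unequal library sizes the integer rounding of
  group sums is a coarser approximation.
- Method-of-moments dispersion is unbiased but noisy per design; the
  default 0.2 tagwise weight trades a little type-I conservatism for
  robustness to dispersion heterogeneity.
- The geometric helix rule cannot label helices shorter than 9 residues
  and assigns no strands.
- `reproduce_zenodo` expects the package's own TSV/FASTA schema for a
  local dataset copy; archives in other layouts need a one-off conversion.
- Published cohort-level percentages depend on denominator conventions
  (detected vs recovered vs retained); both conventions are computable,
  and dataset-level comparisons report deltas rather than asserting them.
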