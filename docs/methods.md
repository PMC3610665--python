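# Methods

## The copying model

A study individual's unordered genotype vector g ∈ {0,1,2,·}^M is modelled
as emitted by an ordered pair of template haplotypes copied, with error,
from a pool of K candidates (all other study individuals' current haplotypes
plus any fixed phased references; the individual's own pair is excluded, so
K = H − 2 for a study member).  The state space is the full ordered product
of K² pairs — the unordered-pair reduction used by some production tools is
an optimization we deliberately skip for clarity of the mirror map.

* **Emission.**  Each observed allele is an independent imperfect copy of
  its template: q(x|a) = 1−e if x = a else e; the dosage emission sums the
  two ordered observed-allele assignments consistent with g.  Missing
  genotypes emit 1 (the state evolves by transitions only).  This per-allele
  miscopy parameterization is the conventional choice; e absorbs genotyping
  error and mutation alike.
* **Transition.**  Per chromatid, the Li & Stephens jump process:
  stay with probability 1−θ_m, otherwise land on a uniformly drawn template
  (including the current one).  The pair transition is the product of the
  chromatid factors and is rank-1 per chromatid, so the forward recursion
  needs only row/column sums: O(M K²) total, not O(M K⁴).
* **Numerics.**  Forward slices are renormalized at every marker (natural
  space, no logs); the scale factors multiply back to the data likelihood
  exactly, which the tests verify against exhaustive path enumeration at
  relative tolerance 1e−10.  e = 0 is accepted but a genotype no template
  pair can emit then raises a degenerate-likelihood error naming the marker.

## Sampling and the mirror rule

Haplotypes are drawn by backward sampling: the last marker's state from
weights ∝ F[M−1], then each earlier state from F[m](j,k)·T(j→j_next)·T(k→k_next).

Mirror mode subtracts, at every marker, each pair's mirror mass **from the
forward slice before the transition factor is applied**:
w'(j,k) = max(F[m](j,k) − F[m](mate(j), mate(k)), ε).  The placement
matters, and we verified the alternative fails: subtracting on the complete
backward weight (forward × transition) leaves the loop intact, because once
the walk occupies a copy pair the stay-transition breaks the pair/mirror
symmetry — w(copy)·(1−θ)² dwarfs w(mirror)·(θ/K)² and nothing cancels
(measured twin-copy sampling frequency 0.99 versus 5·10⁻⁵ for the
forward-slice placement).  On the forward probabilities themselves the
symmetry of a double-sharing competitor holds at every marker, so the
feedback loop is cancelled wherever the walk is.  The full-weight variant is
retained as `mirror_full_weight` for comparison.

ε is relative: ε_abs = epsilon_rel × (sum of the unadjusted weights),
default 1e−10 — scale-free under per-marker renormalization.  No state is
ever excluded logically, only numerically, so the sampler remains ergodic.
When a whole slice is mirror-symmetric (every pair cancels), the adjusted
weights are uniform at the floor: with no usable phase information the
sampler explores freely, which is the correct behavior.  Mates are defined
for reference haplotypes too and mirrored by default
(`mirror_on_reference=False` exempts them); with an empty mate map mirror
mode reproduces original mode draw-for-draw under a shared stream.

Sampled paths become haplotypes site by site: homozygous sites are forced,
heterozygous sites follow the ordered template alleles when they differ and
a fair coin (one stream draw per site, counted as a template mismatch) when
they agree, missing sites copy the templates.  hap1 + hap2 = dosage at every
typed site is asserted after every write-back.

## The MCMC driver

Random genotype-consistent initialization (missing sites drawn from the
observed allele frequency); each iteration visits the study individuals in a
fresh seeded permutation.  Parameter re-estimation uses only the current
iteration's sampled paths, with Jeffreys-like half counts:
θ_m = clamp((c_m + ½)/(n_transits + 1), 1e−6, 0.5) where c_m counts template
changes in interval m over both chromatids of everyone updated, and
e = clamp((mismatches + ½)/(comparisons + 1), 1e−4, 0.05) over per-allele
template-vs-output comparisons at typed sites.  A warning is logged when
any θ_m hits its ceiling, since downstream imputation from such estimates is
known to behave poorly.  Defaults: 60 iterations (near-asymptotic at desk
scale; the demonstrations below use 25 and are already asymptotic at their
size), θ init 0.01, e init 0.005.  The default output is the final sample —
the quantity the evaluation protocol scores; a consensus rule
(majority-vote orientations over the last `keep_last` samples, each aligned
to the first by wholesale flip) is available for stability studies.

## Imputation

Pre-phased study haplotypes are treated as error-free and run one at a time
through the haploid version of the same chain over a fixed phased panel
(panel members only; study haplotypes are never added).  The alternate-
allele posterior at a masked site is Σ_j post_m(j)·(a_j(1−e) + (1−a_j)e);
hard calls threshold at 0.5 with exact ties deterministically called 0.
Genotype calls are the sum of the two haplotype calls.

## The simulator

Founder haplotypes are mosaics of a small ancestral pool
(`ancestral_pool_size` i.i.d. frequency-0.5 haplotypes, default 8), jumping
to a uniformly drawn ancestor with probability `mosaic_switch_rate` per
interval.  The default rate 0.005 with the default 0.01 cM marker spacing
gives template tracts of expected length 1/(r(1−1/P)) ≈ 230 markers
(≈ 2 cM) — long single-haplotype sharing of the kind that makes copy-model
phasing of "unrelated" dense-chip cohorts work in practice, and the regime
where the lock-in contrast is meaningful: with much shorter tracts even a
perfectly mixing chain phases poorly and the comparison measures noise.

The four study designs: `parents_only` (founder couples);
`with_children` (one Haldane-recombinant child per couple — 30 parents give
45 individuals); `sibling_twins_half` (a monozygotic duplicate of each of
the first half of the parents, 45 individuals at 30 parents — duplicating
half the cohort brackets the sibling scenario's severity between the
children and full-twin designs, and is exposed as `n_twins`);
`twins_all` (a duplicate per parent, 60 individuals).  Twins are duplicated
at the **genotype** level after error injection, so twin pairs are exactly
identical by state — the double-sharing condition as it arises when real
genotype records are duplicated.  Genotyping error flips each true allele
independently before dosage formation.  `mask_every_second` clears the
odd-indexed markers for imputation testing, keeping the truth aside.
`n_reference` draws extra founder individuals from the same ancestral pool
as a phased imputation panel.

What the generator does **not** emulate: allele-frequency spectra (all
ancestors are frequency-0.5), recombination-rate variation, genotype-calling
biases correlated with allele or site, population growth or admixture.
Passing tests therefore demonstrate the mixing pathology and its remedy
under controlled sharing structure, not calibrated error rates for any real
panel.

## Scoring conventions

Switch errors follow the Marchini convention: scored sites are heterozygous
in truth and genotype-concordant in the inference; the error count is the
number of orientation flips between consecutive scored sites; a wholesale
swap of the pair is no error.  Discordant sites are excluded and reported
separately (`skipped_sites`).  Evaluation of masked scenarios additionally
restricts scoring to the typed markers: a marker cleared in *every*
individual is unconstrained by the data, so its phase is noise by
construction and scoring it would swamp the signal.  Switches are attributed
to the right-hand site of the disagreeing pair for per-marker localization.

Sharing runs: *double* = identical dosages, *single* = no opposing
homozygotes (the IBS ≥ 1-compatible condition; the literature uses the term
informally and this is our operationalization).  Missing genotypes match by
default (missingness should not break a true sharing tract);
`missing_matches=False` / `--strict-runs` breaks runs instead.

Error-map block structure is summarized as the longest run of markers with
error rate above the **pooled** median of all methods being compared; a
per-method median is degenerate for a method whose markers are mostly
error-free.

Cross-validation: phase k random subsets each omitting a fraction of
individuals, count switch disagreements between runs for individuals common
to both, binned into marker windows.  High-flip windows flag phase resting
on too few informative individuals — usable without truth.

## Demonstration scale and observed behavior

The acceptance tests and `scripts/acceptance.py` run the full chain at 16
parents, 300 markers, 25 iterations, 10 (tests) or 5 (script) seeds per
scenario and mode, chosen so the whole battery completes in minutes on one
CPU while every effect is far from its decision threshold.  At this scale
the twins design yields a ~6–7× switch-error ratio between original and
mirror modes (the chain stays at the random-phase level in original mode),
the sibling design a consistent mirror win, the unrelated design a modest
mirror improvement, and mirror pre-phasing roughly quarters the imputed-
allele errors.  Parameter recovery is checked at 30 parents and 500 markers:
an injected 1% allele error is re-estimated to ~0.01, and the mean θ̂ is
compared against the identifiable truth — the pairwise template-tract
boundary hazard 2r(1−1/P) (either the copier's or the template's founder
tract ending forces a switch), not the raw per-haplotype mosaic rate, which
the copying process cannot observe.

## Known limitations

* O(M K²) per individual update and an M × K² forward array in memory: fine
  for cohort-scale K (≤ a few hundred haplotypes), not engineered for
  thousand-haplotype panels (no state-space compression).
* Biallelic SNPs only; no genotype likelihoods; single chromosome per run.
* The consensus output rule aligns samples by a single wholesale flip, which
  is coarse for chromosomes with many true switch ambiguities.
* Twin duplication models the identical-by-state condition exactly but not
  partially overlapping sharing among more than two individuals, although
  the mirror rule itself handles those cases (any mated competitor is
  subtracted).
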