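# Methods

## Population model

A clonal F1 is the full-sib progeny of two heterozygous parents.  At a
polymorphic locus the female parent carries alleles A/B and the male parent
C/D; a progeny receives one allele from each.  Marker categories encode how
much of this is observable:

| category | parents              | progeny codes | Mendelian ratio |
|----------|----------------------|---------------|-----------------|
| I        | A≠B and C≠D, all distinguishable | AC, AD, BC, BD | 1:1:1:1 |
| II       | A=B (female monomorphic)         | XC, XD         | 1:1     |
| III      | C=D (male monomorphic)           | AX, BX         | 1:1     |
| IV       | co-dominant, A=C and B=D         | AA, AB, BB     | 1:2:1   |
| V        | co-dominant, A=D and B=C         | AA, AB, BB     | 1:2:1   |

Category V exists only in a phase-known double cross, where the founder
genotypes make the two co-dominant matchings distinguishable.  `XX` denotes
a missing genotype; marker pairs use pairwise deletion.  Categories are
taken from the input, not inferred from segregation ratios: with realistic
missingness and distortion, a null-allele cross type cannot be separated
reliably from a one-parent-monomorphic marker, so both are treated as the
corresponding category II/III.

## Two-locus likelihoods and estimators

Ordering the two categories canonically (lower category first), 14 category
pairings admit estimation of at least one of r_F, r_M, r; a II×III pair is
uninformative (all four joint classes have frequency 1/4) and is excluded.
For each scenario the identifiable joint genotype classes have frequencies
that are polynomials in the recombination parameters, and
log L = C + Σ n_i log p_i.

Closed forms: the fully informative 16-class scenario gives r̂_F and r̂_M as
recombinant fractions; one-parent scenarios give the analogous binomial
fractions (for the one-parent × co-dominant scenarios, only the four
classes with a homozygous co-dominant locus are informative — the
double heterozygote has frequency 1/4 regardless of r).  The confounded
co-dominant × co-dominant scenario has a closed form only under the
mixed phases (r̂ = (1 − √(1 − 2s))/2, s the corner-plus-double-heterozygote
frequency, clamped to the boundary 0.5 when the root argument is negative);
the coupling/repulsion phases are maximized numerically, as is the
combined-r likelihood of the informative × co-dominant scenario.

Phase logic.  Parental estimates are kept on their raw [0, 1] scale: a
value above 0.5 means the two loci sit in repulsion in that parent, and the
four phase cases fold the combined estimate into [0, 0.5].  Where no
parental estimate exists (both loci co-dominant), the four phase
likelihoods are each maximized over (0, 1) and the phase attaining the
lowest r̂ is selected; the mirror identity argmax L_IV = 1 − argmax L_I
(the phase-IV class frequencies are the phase-I ones at 1 − r) supplies the
phase-IV maximizer exactly.  Phases II and III are genetically equivalent
for such pairs; the tie is resolved deterministically to II (and a tie at
r̂ = 0.5 leaves the phase unassigned) so runs are reproducible.  The
phase-implied parental values (r̂ or 1 − r̂) are recorded even for these
confounded pairs because the parental maps and the haploid chains consume
them.

Double-cross scenarios 10–14 reuse the clonal models with the male
substitution r_M → 1 − r_M wherever a category-V locus relabels the male
alleles; phases are known, so no phase search is run.

Numerics.  Newton–Raphson on the polynomial log-likelihood, initialized at
the argmax of a 401-point grid (rather than a fixed interior point — the
mixed-phase likelihoods can be bimodal over (0, 1), and grid initialization
lands the polish in the global basin), with damped, interval-clamped steps,
convergence at |Δr| < 1e-10, at most 100 iterations, and a bounded scalar
search as fallback.  Zero-count classes contribute 0·log 0 = 0.  Boundary
estimates (r̂ = 0 or 0.5) are reported as-is.  The test suite checks every
estimator against a 1e-5-step grid search of hand-coded class frequencies
within 1e-4, and exactness on expected counts within 1e-6.

LOD = log10 L(r̂) − log10 L(0.5) under the selected phase's combined-r
model; for the fully informative scenario this parameterization (r_F = r_M
= r at the alternative) is chosen deliberately so the test addresses the
combined linkage claim, matching H0: r = 0.5.

## Grouping, ordering, maps

Grouping is single-linkage transitive closure over estimable pairs with
r̂ below the threshold (default 0.3); markers linked to nothing are
reported as unlinked and excluded.  No LOD threshold is applied by default.

Ordering solves an open-path TSP per group: nearest-neighbour tours from
every start, the best improved by Two-opt reversals until 2-optimal.  The
objective is the sum of adjacent r̂ (inestimable adjacencies contribute a
fixed 0.5): monotone in map length for linked neighbours while remaining
finite at r̂ = 0.5, where Haldane distance diverges.  The two reversals of
a path are equivalent; the orientation whose first marker appears earlier
in the input is returned.

Maps: Haldane d = −50 ln(1 − 2r) (no interference, matching the simulator)
or Kosambi d = 25 ln((1+2r)/(1−2r)).  The combined map uses adjacent
combined r̂ directly (not an interpolation of the parental maps — the
parental maps are reported separately).  The female map is the combined
order without category-II markers, the male map without category-III; their
interval distances come from the direct r̂_F / r̂_M between the retained
neighbours, reflected to 1 − value when above 0.5 (repulsion encodes phase,
not distance).  An interval whose estimate is missing or at the 0.5
boundary borrows the nearest estimable flanking interval's value and is
flagged in the output.  Positions are printed at 2 decimal places; full
precision is kept internally.

## Haploid building and double-cross equivalence

Per parental map: the first locus anchors allele A to HapA (C to HapC);
each later locus keeps its predecessor's orientation when the raw chain
estimate is below 0.5 and flips when above, flips composing along the
chain.  A chain estimate exactly at 0.5 (or missing) keeps the orientation
and flags the locus phase-ambiguous instead of randomizing, so builds are
reproducible.  Chains use consecutive-pair estimates only; long-range pairs
do not vote on flips.  For co-dominant markers the male labels follow the
convention C = the male copy of the A pattern, which makes the category
update purely local: a IV marker whose HapA pattern aligns with HapC stays
IV, one aligning with HapD becomes V.

Canonicalization exchanges allele labels at every locus where HapA carries
B (progeny codes relabelled: first letter for category I, AX↔BX, AA↔BB) or
HapC carries D (second letter for category I, XC↔XD; co-dominant codes are
pattern-based and unchanged), after which the population is emitted as a
phase-known double cross.  The operation is idempotent, and re-estimating
the canonicalized population yields coupling-phase (≤ 0.5) parental
estimates for all adjacent pairs.

## Simulator

Gametes are Markov walks (uniform start strand, switch probability r_i per
interval, no interference); a progeny is one female × one male gamete,
collapsed to category codes.  Unknown phases are induced by swapping the
parental allele labels at designated markers before gamete draw.
Missingness is independent uniform per cell (default 0 in the reference
design; 0.065 is a realistic rate for SSR data when enabled).  Distortion
uses per-locus genotype viability weights with rejection sampling.  The
`demo20` preset fixes the study design used throughout the tests:
20 markers, adjacent r = 0.05 (5.27 cM Haldane, 100.09 cM total),
categories I = {8, 11, 14, 17, 19}, II = {1, 2, 13, 15, 20},
III = {4, 5, 7, 9, 18}, co-dominant A=C,B=D at {10, 12} and A=D,B=C at
{3, 6, 16}, female swaps at {5, 8, 12, 16, 18}, male swaps at
{8, 12, 14, 15, 16, 20}, n = 200 progenies.

What the simulator does not emulate: crossover interference, genotyping
error, linked viability selection, multi-allelic mutation, or realistic
marker ascertainment.  Passing tests therefore demonstrate correctness of
the estimators and pipeline under the stated genetic model, not robustness
to assay artefacts.

## Problem sizes and defaults

Tests and the acceptance script use the reference design (20 markers ×
200 progenies), 100 replicates for map-length summaries, 200 random count
vectors per scenario for the grid-oracle comparison, 500 samples per
scenario for parameter-recovery means, and 40–50 seeds for the haploid
round trip — sizes at which the sampling error of the summaries is well
below the tolerances being checked.  Defaults: grouping threshold 0.3,
Haldane mapping function, distortion screen at α = 0.05 (markers are
flagged, not dropped: distortion mainly biases segregation ratios, and
dropping markers would also be wrong for the many distorted markers seen
in real data that still carry linkage information).

## Known limitations

* Phase II/III of the co-dominant × co-dominant scenario is genuinely
  unidentifiable; the deterministic II choice can propagate a wrong flip
  through a haploid chain when such a pair is chain-adjacent in repulsion.
* Two-opt guarantees 2-optimality, not global optimality; on tested
  instances up to 9 markers it attains the exhaustive minimum, and on the
  reference design it recovers the generating order in at least 95% of
  seeds in the replicated checks.
* Parental-map interval estimates between distant retained neighbours use
  the direct pairwise estimate, which has larger variance than a sum over
  the removed markers would.
* Single-chromosome phasing only: haploids are anchored per linkage group,
  with no attempt to phase across groups.
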