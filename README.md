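# clonalmap

Linkage analysis and genetic map construction for **clonal F1** populations
(full-sib progenies of two heterozygous, vegetatively propagated parents)
and **double crosses** (four-way crosses of inbred lines), where each locus
may carry up to four alleles and the parental linkage phases are unknown
before analysis.

Most mapping software handles such populations by recoding them into
pseudo-testcrosses, discarding the less informative markers.  `clonalmap`
instead keeps every polymorphic marker by classifying each locus into one
of five categories — I (ABCD, fully informative), II (A=B, segregating only
in the male parent), III (C=D, female only), IV (AB=CD, co-dominant), and V
(A=D, B=C, the double-cross variant of IV) — and estimating, for each of
the 14 estimable category pairings ("scenarios"), the female, male, and
combined recombination frequencies *r*<sub>F</sub>, *r*<sub>M</sub>, *r*
by maximum likelihood.

## Method at a glance

For a marker pair with observed genotype-class counts *n*<sub>1</sub>…*n*<sub>k</sub>
and class probabilities *p*<sub>i</sub>(*r*) (polynomials determined by the
scenario and the linkage phase),

  log *L* = *C* + Σ *n*<sub>i</sub> log *p*<sub>i</sub>(*r*).

* Closed-form MLEs exist for most scenarios (e.g. fully informative pairs:
  *r̂*<sub>F</sub> is the female-recombinant fraction); the confounded
  co-dominant scenarios use Newton–Raphson on the polynomial likelihood.
* **Phase determination.**  A parental estimate above 0.5 signals repulsion
  phase in that parent; the combined *r̂* is folded into [0, 0.5] by the
  phase-cased estimator.  In the fully confounded co-dominant × co-dominant
  scenario all four phase likelihoods are maximized and the phase with the
  lowest *r̂* is taken as true.
* **LOD.**  LOD = log₁₀ *L*(*r̂*) − log₁₀ *L*(0.5) tests linkage against free
  recombination.
* **Grouping and ordering.**  Single-linkage grouping at *r̂* < 0.3, then
  open-path TSP ordering per group (nearest-neighbour construction from
  every start, Two-opt refinement) minimizing the sum of adjacent *r̂*.
* **Maps.**  Combined, female, and male maps per group; the female map
  omits category-II markers, the male map category-III markers, with
  interval distances from the direct parental estimates between retained
  neighbours, converted by Haldane (−50 ln(1−2r)) or Kosambi
  (25 ln((1+2r)/(1−2r))).
* **Haploid building.**  Walking each parental map, alleles are assigned to
  the parent's two haploids (HapA/HapB female, HapC/HapD male): the first
  locus anchors the labels and each consecutive raw estimate above 0.5
  flips the orientation.  Co-dominant markers are then split into
  double-cross categories IV/V, and relabelling every locus so HapA carries
  A and HapC carries C turns the clonal F1 into a phase-known double cross.

A seeded simulator (Markov gamete walk, no crossover interference) generates
populations with known truth, including a 20-marker reference design
(`demo20`: adjacent r = 0.05, five markers per category, a fixed pattern of
parental allele swaps, 200 progenies).

## Worked example

```sh
clonalmap simulate --preset demo20 --n 200 --seed 17 --out pop.tsv
clonalmap all pop.tsv --out-dir run17
```

prints `wrote 10 artifact(s) to run17`, and `run17/maps.tsv` begins

```
group  map       marker  category  position_cM  flagged
1      combined  M1      II        0.00         0
1      combined  M2      II        3.63         0
1      combined  M3      IV        6.89         0
1      combined  M4      III       9.04         0
```

For this seed all 20 markers form one group in the generating order; the
combined map is 96.98 cM long (true length 100.09 cM = 19 Haldane intervals
of 5.27 cM), the female map 86.17 cM over the 15 non-category-II markers,
and the male map 95.21 cM over the 15 non-category-III markers.
`run17/haploids.tsv` reports the reconstructed parental haploids, e.g.

```
marker  group  category  hap_a  hap_b  hap_c  hap_d  updated_category
M3      1      IV        A      B      D      C      V
```

marker M3's male alleles sit in flipped orientation relative to M1/M2
(HapC carries D), so its co-dominant pattern is cross-matched and the
marker is relabelled category V — exactly the configuration the simulator
planted.  `run17/double_cross_genotypes.tsv` holds the relabelled,
phase-known double-cross population.

The library mirrors the CLI: `simulate_population`, `estimate_all_pairs`,
`group_markers`, `order_markers`, `build_maps`, `build_haploids`,
`canonicalize_to_double_cross`, `run_pipeline`.

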