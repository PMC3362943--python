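# Methods

This note documents the models, algorithms and numerical choices behind
`clovermap`, and what the synthetic-data experiments do and do not show.

## The mapping model

Each parent of an outcrossing full-sib F1 family is treated as a haploid
("testcross") population: a locus heterozygous in that parent transmits
one of two alleles to each progeny with probability 1/2, and the allele
labels per locus are arbitrary.  All pairwise statistics therefore
minimise over phase: with n doubly informative progeny and m mismatching
calls, the recombinant count is R = min(m, n−m), r̂ = R/n ∈ [0, 0.5], and

    LOD = R·log10(2r̂) + (n−R)·log10(2(1−r̂)),

with the r̂ = 0 limit n·log10 2 and LOD = 0 exactly at r̂ = 0.5.  Pairs
with fewer than `pair_min_n` (default 20) informative progeny are ignored;
loci informative in fewer than 20 % of progeny are excluded from mapping
before any pairwise work (both thresholds configurable).

Distances use Kosambi's map function d = 25·ln((1+2r)/(1−2r)) cM and its
inverse r = ½·tanh(d/50), clamped to [0, 0.5); the round trip is exact to
well below 1e−12 across (0, 0.5).

**Grouping** is single linkage: connected components of the graph with an
edge wherever LOD ≥ 10 and r̂ ≤ 0.4.  Single linkage matches the behaviour
of threshold-based grouping modules in standard mapping software and makes
the over-merge pathology (below) reproducible.

**Ordering** is incremental.  The two loci with the highest LOD seed the
order; remaining loci are added in decreasing summed LOD to the placed
set, each inserted at the slot minimising the misfit, followed by an
exhaustive ripple over every window of three.  The misfit of a candidate
order is the LOD-weighted mean of squared *standardised* residuals over
used pairs (LOD ≥ 1, r̂ ≤ 0.4):

    misfit = Σ w_ij ((d_map − d_ij) / se_ij)² / Σ w_ij,   w_ij = LOD_ij,

where d_map comes from the adjacent-chain positions of the candidate
order, d_ij is the pairwise Kosambi distance, and se_ij is the
delta-method standard error of d_ij, se = 100/(1−4r̂²)·√(r̂(1−r̂)/n) with
r̂ floored at 0.5/n.  On this dimensionless, chi-square-like scale a
correct order sits near 1, and the removal rule — set a locus aside when
its best insertion raises the misfit by more than `jump` = 5.0, retry all
set-aside loci once after the main pass — behaves like a goodness-of-fit
jump threshold.  A locus with no usable pair to any placed locus cannot be
positioned and is set aside directly.  We standardise the residuals
because a raw squared-cM misfit is dominated by long pairs, whose
two-point Kosambi distances are systematically *sub-additive* under
Markov meiosis (see below); on the raw scale the jump rule fired
constantly and maps shrank by ~20 %.

**Positions** come from nonnegative weighted least squares on the interval
lengths of the final order (weights = LOD), restricted to pairs within
three rank positions of each other.  Short-range two-point distances are
additive to good approximation, whereas long-range ones undershoot the
summed map distance and would shrink the map; nonnegativity keeps the
positions monotone by construction.  Orientation is fixed by placing the
lexicographically smaller terminal locus at 0 cM.  On simulated 100-cM,
20-marker chromosomes at n = 188 the median estimated length is within
100 ± 15 cM and 10-locus orders are recovered (or exactly reversed) in
≥ 95 % of seeds.

**Disassembly.**  Strong gametic disequilibrium between chromosomes can
fuse several true linkage groups into one component at LOD 10.  A group
holding more than 25 % of a channel's loci is flagged (the pathological
group in the emulated study held 32.4 %); a mosaicism score (mean
adjacent-locus phase-switch rate) is also available.  Each locus of the
suspect group is labelled by, in order of precedence: (1) the partner-map
group carrying the same marker; (2) the reference chromosome of its best
homolog hit, translated to a partner-group label by majority vote over
loci carrying both kinds of evidence; (3) the labelled subgroup with the
highest mean LOD linkage.  Labelled subgroups are re-validated by the
grouping step; conflicts are logged, and partner-map evidence always wins
over reference evidence.  With both evidence sources available the
simulated three-chromosome over-merge resolves into subgroups of purity
1.0 in 20/20 seeds.

## Integration

Corresponding parental groups are matched greedily by shared bi-parental
anchor counts.  With ≥ 3 shared anchors the P2 axis is flipped if the
anchor orders disagree (negative correlation), both maps are transformed
by monotone piecewise-linear interpolation through the anchor mean
positions (order conflicts collapse onto the running maximum of the
means), anchors are emitted once at their mean, and the merged group is
shifted to start at 0.  Mean-anchor interpolation is an explicit
approximation chosen over joint re-estimation; it preserves both parental
anchor orders whenever they agree and tracks simulated truth at Spearman
ρ ≥ 0.99.  With fewer than 3 anchors the group is not integrated and the
fallback statistics are reported instead: n = n₁ + n₂ − shared and
length = mean of the two parental lengths (with 24 and 22 loci, lengths
97.6 and 120.5 cM and 2 shared anchors this gives 44 loci and 109.05 cM).
Three is the smallest defensible bound because integration is known to
fail with exactly two.

Map statistics follow the printed-table conventions: density =
length / n loci (cM per locus), totals sum lengths and counts with density
and distortion re-derived from the totals, and each bi-parental locus
counts once on the integrated map.  Percentages are rounded half-up at the
printed precision; stored values are exact.

## LD scan

Loci are thinned per group to the nearest locus to each 5-cM grid point
(deterministic; ties to the lower position; duplicates dropped).  For a
pair of haploid call vectors the gametic r² over doubly informative
progeny is

    r² = (f11·f00 − f10·f01)² / (p1·p0·q1·q0),

the squared Pearson correlation of the 0/1 codes, invariant to allele
relabelling; pairs with a monomorphic margin or fewer than 30 informative
progeny are skipped and logged.  Haplotype rather than genotype r² is
correct here because the testcross coding makes each parental channel
phase-known gametic data.  Cross-group pairs with r² > 0.5 are reported,
binned into 5-cM regions, and the full matrix is written for heatmap
rendering.  The scan reports cross-group LD; it does not attempt to
explain its biological mechanism.

## Synteny

Markers keep one best hit (max bitscore, then min E-value, then
lexicographic subject id) after the E ≤ 1e−10 filter.  Within each
(linkage group, chromosome) cell, anchors sorted by map position chain
into maximal runs whose consecutive anchors differ by ≤ 10 cM and
≤ 500 kb; runs of ≥ 3 anchors are blocks.  The gap-bound chaining is a
deterministic, order-free reading of the windowed block definition and
reduces to it when anchors are dense; blocks are not stitched across
intervening foreign-chromosome anchors, and anchor monotonicity is
recorded as an orientation (sign of the cM-vs-bp Spearman correlation,
"mixed" below |ρ| = 0.5) but not enforced.

## SSR mining

A tract qualifies when some phase of a primitive 2–4-nt repeat unit
matches it with ≤ k substitutions (k ∈ {0, 1, 2}, no indels), its length
is ≥ 15 nt, and both ends land on matching bases (no dangling
mismatches, which would otherwise allow unbounded extension).  `N` never
matches.  Motifs are collapsed to the lexicographic minimum over rotations
of the unit and of its reverse complement, so `ATG`, `TGA` and `CAT` all
report as class `ATC`; primitivity excludes composite units such as
`ATAT`.  Overlapping candidates are resolved greedily — longest tract,
then fewest mismatches, then leftmost — so a perfect core nested in a
longer 1-mismatch tract is reported once, as the longer tract.  The
implementation enumerates per-unit maximal windows via mismatch-position
bookkeeping and is checked, per mismatch class, against a brute-force
all-substrings oracle on short sequences.  Counts are of tracts, not of
motif-positions.  A tract is design-feasible when ≥ 20 non-repeat bases
flank it on both sides and a 90–300 bp amplicon covering it fits in the
sequence.

## The synthetic-data generator

The generator's defaults are the emulated study's conditions: 188
progeny; 424 / 789 / 584 bi-parental / female-specific / male-specific
loci; 8 homeologous chromosome pairs giving 16 linkage groups.  Meiosis is
a Markov chain over the ordered loci of each group with adjacent-interval
recombination probability r = kosambi_inverse(Δcm) — self-consistent with
the map function used downstream at short range.  No further chiasma
interference is modelled, which has one important consequence: composite
recombination over several intervals follows Haldane-style (independent)
composition, so the Kosambi distance of a *distant* pair under-states the
summed map distance (≈ 15 % at 30 cM).  The ordering and position choices
above are designed around this, and the map-length property test bounds
the residual effect.

Multi-locus markers duplicate a marker onto its homeolog partner group at
the same position index (suffixes 'a'/'b', band_count 2), emulating one
primer pair amplifying both subgenomes.  Segregation distortion is
gametic viability selection: progeny are resampled with replacement with
weight (1−s) per selected-against allele carried — the simplest mechanism
producing the χ² signal the distortion test looks for.  Call errors flip
symmetrically; missing data are missing-at-random.  Cross-group LD is
planted at anchor loci whose joint allele distribution has a specified
coupling D′ (P(equal) = (1+D′)/2, so anchor r² ≈ D′²); chains and stars of
planted pairs are supported by sequential conditioning, and chromosome
walks proceed conditionally outward from each anchor.  Anchors must
coincide with marker positions; off-grid anchors are an error.

Simulated transcripts are uniform-random sequence with planted SSR tracts
at a configured per-kb rate (default one per 4.7 kb), flanks forced to
break the repeat so planted tracts are maximal.  The synthetic reference
genome places one gene per marker colinearly at a configured bp-per-cM
scale (default 50 kb/cM, which makes the 10-cM and 500-kb chain bounds
congruent), with optional translocations/inversions, wrong-chromosome
decoy hits at lower bitscore, and markers with no hit.

**What passing tests show — and don't.**  The generator produces fully
informative, cleanly scorable testcross loci; real gel-scored
allotetraploid data also contain partially informative band patterns
(e.g. ab×ab configurations) whose pre-coding is not modelled here, dosage
ambiguity, genotyping artefacts that are not missing-at-random, and real
interference.  Accuracy numbers on synthetic data (Rand index, order
recovery, LD detection power, disassembly purity, anchor coverage) are
therefore upper bounds on real-data performance, not estimates of it.

## Reported problem sizes

The bundled experiments use 16-group genomes with 10–14 markers per
group at n = 188 (grouping/ordering, LD, disassembly), 1000 replicate
pairs for estimator bias, 100 + 100 seeds for LD power and null, and
20-anchor cells for the chaining oracle.  These sizes were chosen to make
the Monte-Carlo bands in the property tests tight (binomial standard
errors well inside the asserted bounds) while keeping the whole suite
fast to run routinely.

## Known limitations

* Two-point regression ordering only; no multipoint hidden-Markov
  likelihood, no sex-averaged maps, no interference estimation.
* Ordering equivalence with any proprietary mapping program is not
  claimed — only with the objective stated above.
* The LD scan estimates neither D′ nor haplotype blocks; it thresholds
  and reports.
* Progenitor-subgenome assignment of the homeologous groups is out of
  scope; homeolog pairing is inferred from shared marker names only.
* The fallback integration path reports statistics, not locus positions,
  for non-integrable groups.
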