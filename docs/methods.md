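# Methods

`lodemap` reconstructs gene-based genetic linkage maps from SNP-array
genotypes of grandparent-traced full-sib families, and extends them with
LODE (locus ordering by disequilibrium) placement of markers that linkage
alone cannot position. This note records the models, estimators, defaults
and design choices, and what the synthetic test-bench does and does not
demonstrate.

## Study design assumed by the pipeline

The pipeline expects a three-generation design: genotyped grandparents,
their offspring used as parents of full-sib families, and the families'
progeny. Grandparents anchor phase: when a parent is heterozygous at a
marker and exactly one assignment of its two alleles to grandsire/granddam
is consistent with the grandparent genotypes, the grandparental origin of
every allele the parent transmits becomes deducible. A transmission whose
origin is deduced is an *informative meiosis*; all two-point estimation
counts recombinant vs non-recombinant informative meioses.

## Phasing channels

Two phasing channels serve different estimators, because informativeness
and bias trade off:

* **Strict (testcross) channel.** A meiosis is informative at a marker only
  when the mate is homozygous there, so every progeny genotype reveals the
  transmitted allele. Informativeness is then a property of the
  parent-marker pair, not of the individual progeny, which makes
  recombinant counting free of selection bias. (The tempting alternative —
  also reading transmissions off homozygous progeny when both parents are
  heterozygous — selects progeny whose *other* parent transmitted a
  matching allele; because the mate's gametes are themselves linked, this
  couples the two parents' recombination events and deflates recombination
  fractions by up to half. We measured exactly this against simulation
  truth before adopting the testcross rule.) Distances, sex-specific maps
  and the heterogeneity statistics all use this channel.
* **Augmented channel.** For grouping and ordering, raw informativeness
  matters more than exact unbiasedness. This channel additionally reads
  both transmitted alleles off homozygous progeny, resolves the remaining
  double-heterozygous slots by linkage context (the slot adopts the
  meiosis's origin at its two most tightly linked resolved markers, only
  if they agree), and, once a provisional order exists, (a) re-resolves
  those slots using the nearest resolved markers on *both* sides along the
  order and (b) recovers parent phase at markers where both grandparents
  are heterozygous by majority vote of the progeny against flanking
  phased markers. On the reference simulation this brings informativeness
  from ~110 to ~290 meioses per marker at an origin error rate of ~0.3%.
  Long-range recombination fractions are slightly attenuated by the
  context resolution, which is why this channel is never used for final
  distances (with one deliberate exception, the genome-wide female:male
  scale fit, where the attenuation cancels in the ratio and the extra
  meioses cut its variance roughly in half).

Before either channel runs, progeny genotypes that are Mendelian-impossible
given their parents are masked (`mask_mendelian_errors`); isolated
genotyping errors otherwise masquerade as double crossovers and inflate
every interval.

## Two-point estimation and map construction

For a marker pair with N co-informative meioses and R recombinants, the
recombination fraction is the phase-known MLE θ̂ = min(R/N, 1/2) and support
is the standard two-point LOD, Z = R log₁₀θ̂ + (N−R) log₁₀(1−θ̂) + N log₁₀2.
All cM arithmetic uses the Kosambi mapping function,
d = 25 ln((1+2θ)/(1−2θ)) cM, θ = ½ tanh(2d/100).

**Grouping.** Single-linkage closure over pairs with LOD ≥ 10 and Kosambi
distance ≤ 30 cM; components of fewer than three markers go to the orphan
pool.

**Order criterion.** Orders are scored by an all-pairs composite
likelihood: plug-in adjacent fractions (shrunk toward a prior mean of 0.01
with five pseudo-meioses, so an adjacency with no data reads as "close"
rather than "half a map away") are composed along the candidate order with
Trow's product formula, 1−2θᵢⱼ = Π(1−2θₖ), and *every* co-informative pair
contributes its binomial log-likelihood at the implied fraction. Scoring
only adjacent pairs — the textbook complete-data factorisation — is exact
when every meiosis is informative at every marker, but with partial
informativeness it lets the search chain lucky zero-recombinant pairs and
produces confidently wrong orders; scoring all pairs removes that freedom.

**Search.** Hierarchical tiered insertion: seed with the highest-LOD pair;
insert each remaining marker at its best gap only while the likelihood
margin of best over second-best position meets the current tier
(3, then 2, then 0 log₁₀ units); after each tier, local search to a fixed
point (at most 20 sweeps) by exhaustive permutation of every sliding
6-marker window plus remove-and-reinsert polishing. Ties at the final tier
go to the lower coordinate and are recorded as co-localised. The insertion
sequence is restarted (informativeness order plus seeded shuffles, three
starts) keeping the best likelihood, and the winner is refined by
coordinate ascent: interval lengths refit by composite MLE, the objective
geometry rebuilt from the fitted positions, local search repeated until
stable. The whole build runs twice — the first, cheaper pass only provides
the provisional order for the second-round phasing described above.

**Distances.** With the order locked, interval lengths are refit by
maximising the same all-pairs composite likelihood over the interval
vector, with one shared false-recombinant nuisance rate ε ∈ [0, 0.05]
(observed θ = ε + (1−2ε)·θ_implied) absorbing residual genotyping
artifacts. Plug-in adjacent estimates are kept for reporting θ̂ per
interval; intervals with no informative meioses are flagged undefined and
counted as 0 cM in cumulative positions.

**Sex maps, orphans, merges.** Female and male maps re-estimate interval
distances from each sex's strict-channel meioses under the locked
sex-average order (never re-ordered; N=0 intervals reported missing, not
imputed). Orphans re-enter by two-point support ≥ LOD 3 to exactly one
group (ties stay orphaned), inserted at the most likely gap. Group-merge
candidates are screened by the maximum two-point LOD among the 5×5 distal
marker pairs of every group-pair end orientation.

**Genome-wide F:M ratio.** Besides per-interval/per-group/genome ratio
tables (both ratio-of-totals and mean-of-group-ratios are reported, since
either aggregation is defensible), `fit_sex_expansion` fits one
multiplicative scale per sex to the locked interval profile by composite
MLE over all of that sex's pairs. Dividing two sums of noisy per-interval
estimates has a coefficient of variation of ~8% at the reference study
size — too noisy to read a 1.3× dimorphism — while the one-parameter fit
recovers it to within ~4%.

## QC and ledgers

Per-marker statistics: call rate, MAF, heterozygote frequency, exact
conditional Hardy–Weinberg test (computed on parents only; default
α = 10⁻⁴), and Mendelian agreement = 1 − errors/loci-tested, where an error
is a progeny genotype impossible given the available parent genotypes.
The exclusion pipeline applies, in order: sample call rate < 0.90 (samples
dropped), no-amplify, ambiguous-cluster annotation, monomorphic, HWE
failure, gross Mendelian failure (agreement < 0.95), residual Mendelian
failure (< 0.99), MAF < 0.01, duplicate markers (genotype concordance
≥ 0.995; the later-listed member is dropped), marker call rate < 0.90, and
two-cluster annotation. Every step is recorded in a ledger whose derived
rates use array-validation conventions: conversion = genotyped/total;
validation, minimal-error and final rates all divide by the genotyped
count. Cluster-shape annotations (no-amplify, ambiguous, two-cluster) are
consumed as upstream flags, never computed — they require raw array
intensities.

The in-silico candidate-SNP filter applies, in order: composite quality
(MAF ≥ 0.25, depth ≥ 10, ≥ 2 minor-allele reads, SNP and flanking quality
≥ 25), multi-allelic, Infinium type-I chemistry (A/T, C/G), repeat-masked,
ADT score < 0.7 (consumed as input; the scoring tool is proprietary),
non-unique probe, and flanking-SNP proximity < 50 bp. The proximity rule
drops *both* members of a close pair by default; a keep-better dialect
(deeper read depth wins) is provided as a switch.

Unknown-parent reconstruction is a per-locus ML over the three candidate
genotypes given the mate's genotype (marginalised uniformly if missing)
and the progeny genotype counts under Mendelian transmission — declaredly
a stand-in that uses no linkage information. Loci where all three
candidates have zero likelihood are flagged incompatible, never silently
called. With both parents heterozygous, 10–12 clean progeny still miscall
~2% of loci simply because the ML is close; ≥ 99% recovery needs ~20
progeny.

## LD and LODE

Two-locus haplotype frequencies come from the standard EM for unphased
diploids (double heterozygotes are the only ambiguous class), initialised
at linkage equilibrium, tolerance 10⁻¹⁰, at most 1,000 iterations, with a
monotone-likelihood assertion on every step; the implementation is
vectorised over marker pairs. D, |D′| and r² follow the usual definitions.
The default LD sample is the non-progeny generations: full-sib progeny
share long parental haplotypes and inflate LD (an `all` mode exists for
study designs where that is wanted).

LODE places an orphan in two steps. Assignment: count mapped partners per
linkage group with r² ≥ 0.1; the orphan joins the group with the most
qualifying partners if it has at least three and strictly beats every
other group on (count, then maximum r²) — any tie leaves it unassigned.
Position: the r²-weighted mean cM of the qualifying partners, with the
maximum-r² partner's position reported alongside. Weighted-mean precision
is set by the width of the LD decay around the orphan, so position error
tracks the founder LD decay length, not the marker spacing.

## Heterogeneity and distortion statistics

Sex heterogeneity per interval: Χ² = 2 ln10 [Z_m(θ̂_m) + Z_f(θ̂_f) −
Z(θ̂ pooled)] on 1 df. Family M-test: Χ² = 2 ln10 [Σᵢ Zᵢ(θ̂ᵢ) − Z(θ̂ pooled)]
on (contributing families − 1) df, families with no informative meioses
dropped from both terms; over exactly two groups it reduces to the sex
test. Segregation distortion: the log-likelihood-ratio G-test against 1:1
transmission (heterozygous parent × homozygous mate) or 1:2:1 genotype
classes (both parents heterozygous), each informative parent tested
separately. p-values are asymptotic χ²; Benjamini–Hochberg FDR is applied
within each test family (all intervals of one scan, all markers of one
distortion scan).

## The synthetic test-bench

The generator emulates the study design end to end: a true map per
chromosome; founder haplotypes drawn as mosaics of a small ancestral panel
(template switches per cM make pairwise r² decay with map distance);
grandparents → parents → progeny by per-interval meiosis where each
interval recombines independently with probability inverse-Kosambi(d)
(no crossover interference — chosen so rebuilt Kosambi distances are
consistent with truth on adjacent intervals by construction); female
intervals scaled by a map-expansion factor; viability-selection distortion
with fitness 1 − s·(disfavoured-allele copies)/2, so s = 1 is a recessive
lethal that also halves carrier survival; genotyping error (uniform
mis-call), missingness, held-out "orphan" markers and masked sires. Every
draw descends from one mandatory seed; identical configs are bit-identical.

Reference defaults: 5 linkage groups × 40 markers × 100 cM, 20 families ×
16 progeny with all four grandparents genotyped, 4 ancestral haplotypes at
a mosaic switch rate of 0.12/cM, genotyping error 10⁻³, missingness 10⁻².
The group length matches the ~103 cM average of dense penaeid maps; the
2.56 cM marker interval matches the spacing such maps actually resolve
once co-localised markers are collapsed; and the mosaic parameters are
calibrated so mean adjacent-marker r² in the founder generation sits near
the ~0.18 reported for commercial shrimp lines. At this scale the pipeline
recovers 100% linkage-group assignment, per-group order Kendall τ-b of
0.96–0.98 against truth, total length within ±8%, and a 1.3× female
expansion to 1.26–1.35.

What passing these tests does **not** show about real data: the generator
has no crossover interference, no genotyping-batch structure, no
population stratification in the founders (LD comes from one homogeneous
mosaic process), no array-intensity artifacts (cluster-shape QC flags are
exercised only as pass-through annotations), and pedigrees are always
correct (parentage validation is reduced to a Mendelian-exclusion check).
Orphan markers arise by deliberate holdout rather than by the low
informativeness that creates them in real studies.

## Numerical choices and degenerate inputs

* θ̂ = 0.5 maps to infinite Kosambi distance; reported adjacent intervals
  cap θ̂ at 0.49 (~65 cM) to keep cumulative positions finite.
* The order objective floors implied pair fractions at 10⁻³ (the
  genotyping-error scale) so co-localised pairs with a stray recombinant
  are penalised, not −∞.
* EM haplotype frequencies for monomorphic pairs are flagged undefined;
  LD statistics propagate the flag instead of dividing by zero.
* The interval refit is bounded (each interval ∈ [0, 60] cM, ε ∈ [0, 0.05])
  and starts from the plug-in solution; L-BFGS-B with analytic gradients.
* A distortion configuration whose cross cannot produce surviving progeny
  (e.g. both parents homozygous for a lethal) raises a configuration error
  after bounded resampling rather than looping forever.
* All randomised algorithms (restart shuffles) use fixed internal seeds;
  pipeline outputs are deterministic given the study.

## Known limitations

* Order resolution below the informativeness limit is reported as
  co-localisation; with ~300 informative meioses per marker, markers
  closer than ~0.5 cM are routinely tied.
* The composite likelihood treats marker pairs as independent although
  they share meioses; its absolute value is not a calibrated model
  likelihood and is only used for comparing orders on identical data.
* The context-resolution step biases long-range recombination fractions
  slightly downward; anything quantitative derived from distances uses the
  strict channel instead.
* Parent reconstruction ignores linkage between loci.
* The sex-heterogeneity and M-tests rely on asymptotic χ²; with very few
  informative meioses per sex or family their size is only approximate
  (the test suite verifies calibration at N = 200 per group).
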