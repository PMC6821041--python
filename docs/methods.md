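# Methods

This note records the model, the simulator, the numerical conventions
and the design choices behind `lowbiom`, at the level of detail a
maintainer or reviewer needs to assess what the package's tests do and
do not demonstrate.

## Contamination model

The working assumption is that reagent/handling contamination enters
each DNA extraction as an absolute copy load that does not scale with
the sample's own bacterial density. If an extraction receives a member
load M = D·v (sample density D in 16S copies/ml times extracted volume
v in ml) and a background load C, the expected contaminant share of
reads is C/(C + M): near zero for dense samples, near one as D → 0.
Two observable consequences define the method:

* **Feature 1.** Across samples spanning a density range, a
  contaminant OTU's *relative* abundance is negatively rank-correlated
  with measured input density. We use Spearman's ρ with average-rank
  tie handling and the two-sided t-approximation on n−2 degrees of
  freedom, the standard approximation for the sample sizes involved
  (n ≥ ~10). An OTU is flagged when ρ < 0, p ≤ α and its prevalence
  passes a configurable floor. Zero-variance OTUs have undefined ρ and
  are never flagged.
* **Feature 2.** Low-mean contaminants drop in and out of parallel
  extractions of the same material. An OTU is a replicate singleton in
  a group when it is "present" in exactly one member; for groups larger
  than two, "exactly one" is the direct generalisation of the pairwise
  definition. "Present" defaults to ≥ 1 read; a relative-abundance
  alternative (e.g. ≥ 10⁻³) is available because reproducibility in
  real data stratifies sharply around that level.

Filter semantics: F1 zeroes flagged OTUs in all samples; F2 zeroes an
OTU only inside the groups where it is irreproducible (the conservative
reading — a taxon reproducibly present in dense samples is not punished
for flickering in sparse ones); F3 applies F1 and then *recomputes*
Feature 2 on the filtered table before applying F2. Filtered cells are
zeroed rather than dropped so tables stay shape-stable across
comparisons; writers can drop empty rows on request. Reads are never
added and unflagged cells are never altered; after one F1+F2 pass the
flag set is stable under recomputation for F2 (F1 correlations are not
re-evaluated within a single application — removing rows does not
change other rows' relative abundances' *ranks* against density only
when depths change uniformly, so F1 flags may in principle shift if the
model is refitted on filtered output).

### Default thresholds

| parameter | default | rationale |
| --- | --- | --- |
| α (Feature-1 significance) | 0.05, two-sided | conventional level; raw p-values by default since per-OTU correlation screens in this setting are customarily reported uncorrected; Benjamini–Hochberg available as an option |
| min. prevalence for Feature 1 | 0 | every OTU is tested; a 50% prevalence floor is offered because density-correlation is better powered for prevalent OTUs |
| presence threshold (Feature 2) | 1 read | the literal definition of detected; 10⁻³ relative abundance offered as the empirically motivated alternative |
| control handling | excluded from correlation, still filtered | controls have no meaningful input density but should not escape cleaning |
| ties in density | average ranks | replicates share a nominal density; average ranks make Feature 1 invariant to any monotone transform of density (log-density gives bit-identical results, property-tested) |

## Evaluation framework

*Accuracy* is Bray-Curtis dissimilarity BC(x, y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)
between a sample's observed composition and its known expected
composition. The observed vector is aggregated to the expected taxa —
an expected label matches any OTU carrying that exact rank-prefixed
label in its lineage — plus a single pooled bin holding all unmatched
abundance; comparing at OTU level would be ill-defined against 2-, 3-
and 5-taxon expectations. For unit-sum vectors BC = 1 − Σ min(xᵢ, yᵢ),
from which a useful theorem follows: zeroing only non-expected taxa and
renormalising can never increase the accuracy BC (property-tested over
random compositions, and the reason F3 is safe where its flags are
correct). *Precision* is BC between full OTU-level profiles of
technical replicates — no aggregation, since it measures whole-profile
concordance; groups above two yield all pairwise values plus their
mean.

Observed richness counts distinct taxa at a rank (default genus) with
≥ 1 read; OTUs unresolved at that rank count as their own units, since
they are evidence of distinct organisms. The z-score matrix keeps the
top-n (default 20) taxa by mean relative abundance and standardises
each row with the n−1 standard deviation (the denominator is a
convention choice; constant rows become all-zero rows). Treatment
comparisons use the Wilcoxon signed-rank test (zeros dropped, exact
null for ≤ 25 informative untied pairs, tie-corrected normal
approximation otherwise; an all-zero difference vector is reported as
degenerate rather than an error) and the Mann-Whitney U test (exact
for small untied samples). These standard statistics are delegated to
scipy; the test suite checks them against independent brute-force
oracles — explicit rank-then-Pearson, exhaustive sign enumeration
(2ⁿ), exhaustive rank-assignment enumeration (C(n+m, n)) — to 10⁻⁹.

## qPCR density module

Ct values are converted through an OLS standard curve
Ct = slope·log₁₀(copies) + intercept (slope must be negative), and
copies per reaction scale to copies/ml as
`copies_rxn × (elution/template) / input_ml` with defaults of 60 µl
elution, 1.5 µl template and 250 µl of sample extracted. The volume
algebra is the package's own convention (the natural dimensional
analysis of the workflow); all three volumes are configurable. Standard
copy numbers from dsDNA mass use the usual 650 Da/bp formula. No PCR
efficiency correction is applied beyond the fitted slope.

## Simulator

Per sample (community c, nominal density D, replicate r):

1. member copy load = D·v·f(c, t) for member taxon t (deterministic;
   v = 0.25 ml);
2. background copy load per pool taxon drawn independently per
   extraction from a lognormal with mean λ_t and dispersion σ = 1.0
   (parameterised so E[load] = λ_t); the background never scales
   with D;
3. reads = multinomial(depth = 20 000, loads normalised); every sample
   has exactly `depth` reads;
4. concentrated samples multiply D by 10 before step 1 (metadata keeps
   the nominal density, which is the axis treated samples are compared
   on); no-template controls set the member load to zero.

Defaults mirror the benchmark design: three communities (equimolar
3-species; 50/50; 55/24/15/5.5/0.5%), eight tenfold densities
8E+02 … 8E+09 copies/ml, duplicate extractions, four duplicate NTC
pairs. A BALF-like mode draws per-subject densities log-uniformly over
1E+05–4.2E+08 copies/ml and per-subject compositions from a flat
Dirichlet over eight airway commensal genera, for exercising the
workflow on heterogeneous cohorts without a known expectation.

**Background pool calibration.** The default pool has 600 OTUs with
log-uniform mean loads spanning three decades, summing to
B = 2×10⁵ copies per extraction. Three considerations fix these
numbers: (i) B/v places the density at which contaminant and member
loads balance at 8E+05 copies/ml, inside the 8E+04–8E+06 window where
low-biomass dilution series show contaminants taking over; (ii)
several hundred distinct contaminant OTUs is the realistic richness
scale for reagent background observed in deeply sequenced dilution
series; (iii) the closed-form description of the simulator's mean
behaviour — contaminant read fraction B/(B + D·v) — holds only when
the *total* background load has modest dispersion; with σ = 1 per
taxon, a pool this size keeps the Jensen gap between E[C/(C+M)] and
B/(B+M) well inside Monte-Carlo noise at 200 replicates, whereas a
pool of a few dozen taxa would bias the mean several standard errors
low at low densities. The trade-off is skew: in real data a handful of
genera can carry ~80% of contaminant reads, while this pool's top
three carry only ~3%; the simulator therefore under-represents
dominance by single contaminants. The dominant pool loads carry the
genus names most often reported as reagent contaminants
(*Acinetobacter*, *Pseudomonas*, *Rhizobium*, …), including a
genus-level *Pseudomonas* distinct from the member *P. aeruginosa* OTU
so the member/contaminant ambiguity of shared genera is representable.

The optional Dirichlet perturbation of multinomial probabilities
(`pcr_dirichlet`) is a robustness knob emulating amplification bias;
it is off by default and makes no claim about any particular dataset.

### What the simulator does and does not emulate

Emulated: density-independent background, stochastic dropout of
low-mean contaminants (Feature 2), fixed-depth compositional
sampling, technical-replicate structure, concentration as a density
multiplier, member/contaminant label ambiguity across communities.
Not emulated: taxonomic misclassification, chimera/denoising
artifacts, PCR efficiency differences between taxa, 16S copy-number
variation between genomes (loads are in copy units throughout),
between-run batch effects, and contaminant dominance skew (above).
Consequently, passing tests demonstrate that the *method* behaves as
designed under the stated mechanism — they do not certify performance
on any particular real dataset, where Feature-1 power is lower
(messier density estimates, fewer samples) and contaminants can be
more concentrated in a few taxa.

## Problem sizes and numerical conventions

The default study design (3 × 8 × 2 plus controls, 608 OTUs, depth
20 000) keeps a full simulate-fit-filter-evaluate cycle under a second,
so the test suite runs the complete workflow many times rather than a
reduced one. Mean-behaviour checks use 200 replicate extractions per
density and a 3-standard-error band; oracle-equivalence checks use
1000 random instances per statistic with exhaustive enumeration kept
to n ≤ 12 (4096 sign patterns, ≤ 924 rank assignments). Spearman p at
|ρ| = 1 is reported as 0 (the t statistic diverges). Relative
abundances of zero-depth samples are all-zero columns with a warning,
never NaNs. Filters preserve dtype int64 and never drop rows.

## Known limitations

* Feature 1 cannot separate a taxon that is both a genuine member and
  a frequent contaminant within the same dataset; such taxa need
  per-community truth (the simulator's labels provide it; real data
  usually cannot).
* The F1 correlation assumes densities span enough range to order
  samples meaningfully; with ≤ 3 distinct densities the test is
  essentially powerless though still defined.
* Aggregated accuracy hides within-taxon substitutions (a wrong OTU of
  the right genus scores as correct at genus-level expectations).
* The volume algebra in the density module is a stated convention, not
  a reconstruction of any particular laboratory's arithmetic.
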