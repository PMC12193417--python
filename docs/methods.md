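# Methods

This note documents the statistical procedures, default parameters and
design decisions of `echinodiv`, and what the synthetic-data tests do and do
not demonstrate about real field data.

## Trait diversity and clustering

Each quantitative trait (M1 leaf length … M9 plant height; M7 is the
dimensionless first-glume/spikelet ratio, constrained to (0, 1]) is
summarized by range, max, min, mean X̄, sample standard deviation *s*
(n − 1 denominator, matching the SPSS/Excel convention of the survey
workflows this package mirrors) and CV = 100·*s*/X̄.

Diversity uses the Shannon–Wiener index H′ = −Σ Pᵢ ln Pᵢ (natural log,
nats) over **ten trait levels**: level 1 collects values below X̄ − 2*s*,
level 10 values at or above X̄ + 2*s*, and the eight inner levels are
half-open intervals of width 0.5*s*, [X̄ − 2s + (k−2)·0.5s,
X̄ − 2s + (k−1)·0.5s) for k = 2…9.  Ties at any edge fall in the upper bin
(consistent with "≥" defining level 10 and "<" defining level 1).  H′ is
bounded by ln 10 ≈ 2.3026 and attains the bound only for the uniform level
distribution.  A trait with *s* = 0 cannot be binned and raises an error;
callers may drop such a trait explicitly rather than have bins invented.

Clustering standardizes each trait to mean 0 / sample SD 1 and applies
Ward's minimum-variance method over Euclidean distances
(`scipy.cluster.hierarchy.linkage` supplies the agglomeration; merge
heights are reported on the squared-Euclidean Lance–Williams scale).  An
optional **SPSS-style rescaling** maps heights proportionally onto [0, 25]
(h → 25·h/h_max).  SPSS does not publish the exact rescaling of its
agglomeration schedule; any monotone map preserves cut semantics, and the
proportional form is zero-preserving, so a duplicate-sample merge still
sits at 0.  Published cut values quoted on a 0–25 dendrogram axis (e.g.
15.0) should be applied with rescaling enabled — the pipeline default.

Cutting keeps merges **strictly below** the threshold and labels the
resulting groups 1…k by first appearance in input row order, making
assignments deterministic and reproducible.

## Herbicide resistance

Fresh-weight inhibition is 100·(1 − treated/control), clamped below at 0
when a treated plant outgrew its control.  A population is **resistant** to
a herbicide iff inhibition < 78 % (strict inequality at the boundary).
Multi-resistance is the number of *distinct sites of action* (SOAs) with at
least one resistant call; the default map covers the six assay herbicides
(metamifop and cyhalofop-butyl → ACCase; penoxsulam and pyribenzoxim → ALS;
propanil → PSII; quinclorac → synthetic auxin), giving four SOA classes.
The map is configuration, not code — surveys using other panels override
it.  The herbicide count (`n_resistant`) is reported alongside the SOA
count; correlation analyses default to the SOA count.

Trait–resistance association uses Pearson r with two-sided p-values from
the t distribution on n − 2 df, flagged at 0.05 and 0.01.  Zero-variance
vectors yield missing entries rather than errors or silent drops.

## DNA barcodes

A site is **variable** when at least two distinct unambiguous bases
(A/C/G/T) occur among the samples at that column; gaps, N and IUPAC
ambiguity codes are ignored per column.  Samples with identical states
across all variable sites form a **haplotype group**; these groups are the
barcode classification (labels 1…k by first appearance), with the NJ tree
serving as visualization.  When a reference accession is attached,
positions are reported in the reference's ungapped 1-based coordinates
(GenBank style); otherwise in alignment columns.

K2P distances use **pairwise deletion**: transition proportion P and
transversion proportion Q are computed over sites where both sequences
carry unambiguous bases.  Pairwise deletion preserves per-pair information
in short barcodes (complete deletion could discard most of a short
amplicon over a single gappy sample).  When a logarithm argument is ≤ 0
the distance is **flagged undefined (saturated)** rather than clamped to a
large value; tree building refuses matrices containing undefined pairs so
saturation is never papered over.

Neighbor joining follows Saitou–Nei with the Q-criterion; among tied
minimal pairs the lexicographically smallest (i, j) by node-creation index
is joined, so output is deterministic.  Negative branch-length estimates
are clamped to 0 with the deficit moved to the sibling edge (the pair's
summed length is preserved).  The tree is returned unrooted, represented
with a trifurcating root.  On additive matrices NJ is exact; the test
suite verifies exact recovery of topology and all path lengths on random
4- and 5-leaf additive matrices and cross-checks topology against an
independent NJ implementation.

Bootstrap supports resample alignment columns with replacement; replicate
r draws from the substream `default_rng([seed, r])`, so runs are
reproducible and extending the replicate count never changes earlier
replicates.  Support for each internal bipartition of the *original* NJ
topology is the percentage of replicate trees containing it (the original
topology is annotated; no consensus tree is built).  Replicates whose
resampled K2P matrix contains a saturated pair are skipped, and the
denominator reduced; under realistic barcode divergence this is rare.
Alignments with fewer than four samples have no non-trivial bipartitions
and are returned without supports.  In the pipeline, tree building first
collapses samples to one representative per haplotype: identical sequences
carry no topological information and NJ on 46 near-duplicate rows would be
needlessly slow and fragile.

Concatenation requires identical sample sets across loci and records
locus boundaries.  Haplotype partitions can only *refine* as loci are
added: the combined partition is nested within each single-locus
partition.

## Dominant (SCoT) markers

A band locus is polymorphic iff both 0 and 1 occur in its column; rates
are 100·(polymorphic/total), overall and per primer.  PIC treats the two
observable classes of a dominant locus — band presence (frequency p) and
absence (1 − p) — as the allele classes: PIC = 1 − p² − (1 − p)², maximum
0.5 at p = 0.5.  No Hardy–Weinberg back-estimation of a recessive allele
frequency is attempted; a dominant band cannot distinguish heterozygotes,
and the two-class form is the direct reading of 1 − Σ pᵢ² for such data.
Per-primer PIC averages over polymorphic loci only (monomorphic loci have
PIC 0 and would dilute the average); `include_monomorphic=True` switches
to all-locus averaging.  Published per-primer PIC values from band data we
do not possess are not reproducible either way; only column aggregates are
used for validation.

Simple Matching similarity counts agreement at *all* scored loci,
including shared absences and monomorphic loci; 1 − SM is a scaled Hamming
distance (it satisfies the triangle inequality, and the suite checks
this).  Clustering is UPGMA (average-linkage SAHN) on 1 − SM — the linkage
of the NTSYS-style workflow this stage mirrors — cut at a dissimilarity
threshold in [0, 1].  Because scipy's linkage supplies the agglomeration,
merge tie-breaks among exactly equal candidate heights are scipy's
internal (deterministic) order; heights are unaffected, and the oracle
tests use continuous random data where ties do not arise.

## Cross-marker concordance

Each method's cluster labels are encoded in one shared sample order; all
pairs of methods get Pearson r and two-sided t-distribution p-values.
Pearson-on-labels depends on the arbitrary numbering of clusters — this is
a property of the procedure being replicated, not a defect to fix — so the
module also reports the maximum r over all permutations of one method's
label values (exhaustive, ≤ 8 classes) as a robustness diagnostic.  The
raw first-appearance-order value remains the primary statistic.

## Synthetic studies

The generator emulates the structure of a 46-population regional survey
with five population groups (sizes 12/13/9/3/9):

* **Traits** are drawn per population from group archetype normals.  The
  archetype means encode the five field morphotypes (tall/long-leaved
  awnless; short-leaved slender; compact thick-stemmed long-awned; tall
  long-awned; diminutive awnless); within-group SDs are set so pooled
  columns are approximately normal (Shapiro–Wilk at α = 0.01 passes in
  ≥ 95 % of seeds) — matching the observed normality of real trait data —
  while the overall means and SDs land near the published aggregates.
  Awn length is the deliberate exception: awnless archetypes produce a
  zero-inflated column, mirroring the non-normal awn lengths of real
  surveys.  Values are clipped at 0 (and the glume ratio into (0, 1]).
* **Barcodes**: each locus has a random reference sequence (planted
  positions forced to 'A' so substitutions to C/G/T always vary) and
  per-group substitutions: *ITS* 588 bp with five haplotypes over five
  variable positions, *psbA* 337 bp (two positions) and *matK* 1312 bp
  (one position) both splitting groups {1,2,3} vs {4,5}, *trnL-F* 954 bp
  invariant.  Within-group sequences are identical by default — groups
  *are* haplotype classes — with an optional within-group mutation rate
  for stress tests.
* **Bands**: 72 loci over six primers with the published per-primer
  polymorphic counts (11/12/7/14/10/8); total band counts are published
  only for SCoT12 (9) and SCoT20 (15), so the remaining allocation
  (12/13/12/11) is invented consistent with the published total of 72.
  Group 0/1 profiles for polymorphic loci are drawn once at config-build
  time from a fixed internal seed (they are part of the *plan*, not of the
  study randomness), redrawing any all-equal column.  Sample rows XOR the
  group profile with Bernoulli(0.02) flip noise at plan-polymorphic loci;
  invariant loci model bands scored identically in every sample and stay
  invariant, keeping the observed polymorphism rate at the planned 62/72.
* **Resistance**: the distinct-SOA count is Binomial(4, σ(β₀ + β·z̄)) with
  z̄ the mean z-score of the coupled traits (leaf length M1 and spikelet
  length M6 by default, coupling β = 1.2, intercept 0) — a single
  interpretable knob that produces the positive trait–resistance
  correlation seen in the field.  The resistant SOA classes are sampled
  uniformly; member herbicides get inhibition U(35, 70) (resistant) or
  U(85, 99.5) (susceptible), converted to treated/control fresh weights
  with controls U(8, 12) g.

One master seed feeds four substreams (traits, sequences, bands,
resistance) spawned in fixed order from `numpy.random.SeedSequence`;
identical config + seed reproduce byte-identical files.

**What passing tests show — and do not.**  Synthetic recovery tests show
the *pipeline* is correct: exact haplotype recovery, ≥ 95 % pairwise
co-clustering of band groups at 2 % flip noise, refinement under
concatenation, calibrated null p-values.  They do not show that real
46-population surveys are recoverable: real barcode groups can be
paraphyletic, real band noise is not symmetric or independent, and real
trait clusters need not align with haplotype classes.  Published
cross-marker correlations and per-cluster trait profiles depend on the
unpublished raw data and are deliberately not validation targets.

## Numerical choices and problem sizes

* Sample SD everywhere (n − 1); CV errors on zero mean with positive SD.
* Level-frequency vectors must sum to 1 within 1e-12; H′ treats zero
  frequencies as contributing 0.
* Distance matrices are validated symmetric within 1e-12 with zero
  diagonals; Newick branch lengths are written to six decimals and leaf
  names containing metacharacters are single-quoted.
* Validation-suite problem sizes: oracle equivalence uses 40 random
  additive trees per leaf count (4, 5), Lance–Williams checks at n ≤ 8,
  30 random 200-bp K2P pairs; group recovery runs 20 seeded studies; null
  calibration uses 500 replicates at n = 50.  These sizes make the checks
  exhaustive in the regimes where the algorithms' behaviour is provable
  while keeping the default suite quick to run.

## Known limitations

* No multiple-sequence alignment, chromatogram QC or GenBank retrieval —
  alignments must arrive aligned.
* The SCoT stage scores matrices, not gels; band calling is upstream.
* Pearson-on-labels concordance inherits the label-numbering sensitivity
  of the procedure it replicates; use the relabeling diagnostic (or an
  adjusted Rand index, deliberately not offered as a primary statistic)
  when comparing across studies.
* The synthetic generator models neither linkage among bands, coalescent
  sequence variation, nor genotype-by-environment interaction.
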