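# Methods

## Model and assumptions

The package detects microsatellite instability (MSI) as a shift in the
distribution of repeat tract lengths observed in RNA-seq reads, relative
to a normal reference. The underlying assumptions are:

* At a stable locus, observed lengths scatter tightly around a single
  modal length; the scatter is dominated by polymerase/PCR *stutter*
  (slippage during library preparation and sequencing), which affects
  tumor and normal alike.
* At an MSI-driven locus, a tumor carries a somatically shifted allele in
  a substantial fraction of its reads, so the tumor length distribution
  differs from the normal one in a way stutter alone does not produce.
* RNA-seq adds two complications relative to DNA: per-gene expression
  differences change per-locus depth (and can change which allele is
  expressed), and matched normals are frequently unavailable. Both are
  handled by restricting analysis to *invariable* loci selected from a
  normal cohort and by synthesizing a *reference normal* from that
  cohort, rather than by modelling expression directly.

## Tract-length measurement

A read contributes a length at a locus `[start, end)` only when its
aligned (non-soft-clipped) span covers `[start − f, end + f)` with
`f = flank_len = 2`, each flank reference base is aligned to a read base,
the flank read bases are contiguous (no insertion inside a flank) and
identical to the reference flank (case-insensitive; `N` rejects), and the
two anchor positions `start − 1` and `end` are both aligned (a deletion or
splice across a flank/tract boundary rejects the read). The measured
length is the number of read bases strictly between the anchors, which
equals reference tract length + insertions − deletions inside the tract.
An insertion abutting the tract boundary is counted as tract sequence —
the placement of a boundary insertion is inherently ambiguous, and
counting it is the reading consistent with "bases between the flanks".

Design choices where practice was open:

* **Minimum length 5** is interpreted in *bases*, not motif units
  (configurable). For mononucleotides — the dominant unstable class — the
  two readings coincide; bases is the more conservative reading for
  longer motifs.
* **MAPQ ≥ 20** and duplicate/secondary/supplementary/QC-fail exclusion
  are standard-practice defaults, configurable down to MAPQ 0 for
  permissive operation. Base qualities are not filtered.
* Spliced alignments (`N` operations) crossing the measurement window are
  rejected as non-spanning: a splice cannot provide contiguous tract
  evidence.

Rejections are tallied per locus by reason (`filtered_flag`, `low_mapq`,
`not_spanning`, `boundary_indel`, `flank_mismatch`, `short_tract`);
accepted + rejected equals the overlapping read count, which the tests
assert.

## Invariable loci and the reference normal

A normal sample is *informative* at a locus when it has ≥ `min_reads = 5`
lengths there. A locus is *invariable* when at least `min_normals = 10`
normals are informative and strictly more than `agreement_threshold =
0.95` of them share the same modal length (19/20 = 0.95 exactly does
**not** qualify). The denominator is informative samples only: counting
low-coverage normals as disagreement would conflate coverage with
instability. `min_normals = 10` is this package's floor for a meaningful
agreement fraction; there is no established convention.

The reference normal repeats each invariable locus's consensus modal
length `ref_count` times, where `ref_count` is the per-locus median of
each informative normal's modal-length read count, rounded half-up and
floored at `min_reads` so the locus stays testable. The median is
per-locus (preserving locus-specific depth); a global-median mode exists
behind a flag for sensitivity analysis. Modal ties break toward the
smaller length, a deterministic and conservative rule.

## Instability calling

Per tumor and locus with ≥ 5 reads on both sides, the two-sample KS
statistic is the supremum of the absolute ECDF difference on the merged
discrete support; the p-value uses the asymptotic Kolmogorov distribution
with effective size `n_t·n_n/(n_t+n_n)` (an exact small-sample mode and a
seeded permutation p-value are available). With heavy ties the asymptotic
p is conservative, which errs toward fewer unstable calls. Extreme
statistics can underflow the asymptotic tail; p-values are floored at the
smallest positive normal float so downstream multiplicity correction
stays in-domain.

Benjamini–Hochberg correction is applied **per sample across the tested
loci of the analysis locus set** (per-region sets are corrected within
themselves when region models are built); a locus is unstable at
q < `fdr_alpha = 0.05`. BH is the default procedure;
Benjamini–Yekutieli-style robustness can be had via the permutation
p-values. Reference-normal comparisons use the degenerate repeated-modal
multiset exactly as constructed — no variance inflation is invented, and
the resulting conservatism is accepted.

Group differences in per-sample unstable counts use the two-sided
Wilcoxon rank-sum test, exact for ≤ 8 per group without ties, otherwise
the tie-corrected normal approximation without continuity correction (so
identical groups give p = 1 exactly).

## Classification

The default feature is the scalar unstable-locus count in one region
stratum; repeat-class-stratified counts are opt-in. A scalar-fed forest
reduces to a threshold ensemble — faithful to the count-based design, and
documented as such. Training uses balanced resampling: ⌊0.8 · n_MSI-H⌋
MSI-H samples plus an equal number of MSS samples without replacement;
the remainder is the test set. "Cross-validation" is implemented as 10
independent resampling repetitions (not 10-fold), because the balanced
80 %-of-the-minority split rule is a resampling scheme, not a partition.
The random-forest MSI-H probability is the fraction of trees voting
MSI-H (not the averaged leaf probabilities); ensembles are scikit-learn's
random forest or XGBoost with 100 trees and library-default
hyperparameters, seeds frozen in the model artifact.

## Synthetic data

The simulator emulates the generative assumptions above: contigs of
`flank(60) + motif^u + flank(60)` segments (u uniform in 5–15 units;
flank boundary bases chosen so they cannot extend the tract), region mix
CDS 0.400 / 3′UTR 0.469 / 5′UTR 0.131 and class mix mono 0.292 / di
0.164 / tri 0.342 / tetra 0.202 matching the composition of the
exome-wide locus catalog the method targets; Poisson(30) spanning reads
per locus of length 100; stutter with probability 0.02 per read, slip
size 1·Geometric(0.8) motif units, symmetric by default with an optional
deletion bias; MSI-H samples destabilize a fraction 0.3 of loci with a
fixed ±1–3-unit shift expressed in 70 % of reads (tumor purity). Reads
are single-end, primary, MAPQ 60, unclipped, with exact CIGARs; alignment
pathologies are exercised by dedicated test fixtures instead.

What the simulator does *not* model: expression-level variation across
genes and samples, allele-specific expression, alignment and mapping
errors, paired-end structure, and sequence-context-dependent stutter.
Passing tests therefore demonstrate correctness of the measurement,
selection, testing and classification machinery under the stated
generative model — not performance on real tumors, where the invariable
filter must absorb expression effects the simulator never generates.

## Problem sizes and numerics

The acceptance script and end-to-end tests use 30 normals + 30 MSS +
30 MSI-H over 500 loci — large enough that binomial fluctuations in
sensitivity and false-call rates are small against the thresholds being
demonstrated, and the balanced classifier has 24 + 24 training samples
per repeat. Oracle comparisons (KS vs brute-force ECDF supremum, BH vs
hand step-up, AUC vs pairwise concordance) use tolerance 1e-12. All
randomness flows from explicit seeds: cohort samples draw from
`SeedSequence([master_seed, sample_index])`, cross-validation repeats
from affine transforms of the training seed kept below 2³¹.

## Known limitations

* The degenerate reference normal understates normal-side variance,
  making calls at loci with appreciable stutter conservative.
* The asymptotic KS p-value is approximate at depth near the 5-read
  floor; the exact mode is available but slower.
* Region labels are catalog input; no annotation is performed.
* MSI-L is out of scope: classification is binary MSI-H vs MSS.
* LiftOver, QC tooling, and cohort download utilities are out of scope;
  the catalog is consumed as provided (pre-lifted), in BED4+2 dialect
  with a converter hook for other column orders
  (`catalog.read_catalog` + custom pre-processing).
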