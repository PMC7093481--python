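# Methods

## The assay model

The package analyzes clone (Sanger-style) bisulfite sequencing of a
single PCR amplicon spanning a CpG island shore, in a diploid cell
population heterozygous for a null allele.  Key assumptions:

* **One assayed strand.** Bisulfite PCR amplifies one strand; after
  conversion the two genomic strands are non-complementary, so all
  coordinates, CpG positions and the SNP are defined on that strand in
  its unconverted state.  Reads arriving in the opposite orientation are
  reverse-complemented according to the sample sheet; there is no
  orientation autodetection.
* **No non-CpG methylation.** Mammalian somatic context: every non-CpG
  cytosine is assumed unmethylated, which is what makes those sites
  usable as conversion-efficiency sentinels.
* **Conversion-surviving SNP.** Allele identity must come from a SNP
  whose post-conversion read alphabets are disjoint.
  `snp_bisulfite_visibility` computes this for any base pair: C maps to
  {T} outside CpG context and {C, T} inside it; A/G/T map to
  themselves.  A C/T SNP is therefore ambiguous while G/A survives.  A
  SNP inside a CpG is rejected at spec load because its methylation
  state would confound the allele call.
* **No PCR bias.** Clones are treated as a uniform with-replacement
  sample of the allele pool.

## Coordinates and the region partition

Coordinates are 0-based with half-open region intervals; a CpG is
located by the offset of its C, and region membership (O, S, I, or
unassigned) is decided by that single offset.  The packaged fixture
amplicon is synthetic: it is assembled from per-CpG blocks (an A/T
spacer carrying exactly one non-CpG cytosine, then `CG`) so that the
canonical 2/9/13 O/S/I layout, a ≥ 10 non-CpG-C conversion-QC floor and
a mid-shore G/A SNP in non-CpG context hold by construction for any
seed.  No real genomic sequence is shipped or required.

## Alignment and QC

Reads are globally aligned to the unconverted reference with an
asymmetric substitution matrix (Biopython `PairwiseAligner`): reference
C vs read T scores as a match (conversion is expected), read C vs
reference T does not, N is neutral.  Defaults: match +1, mismatch −2,
affine gaps −4/−1, bisulfite-aware identity threshold 0.8, read length
within 20% of the amplicon.  These are fixture-validated conventions for
near-full-length amplicon clones, all configurable.

Conversion efficiency is estimated as converted / (converted +
unconverted) over non-CpG reference-C sites (SNP position excluded);
reads below 0.95 are rejected (`incomplete_conversion`), with the
boundary inclusive.  Rejected reads appear only in the QC report, which
conserves counts exactly: inputs = passes + rejections and passes =
WT + KO + ambiguous.  Ambiguous-SNP reads stay in the report but never
enter per-allele statistics.

## RM classification and statistics

A read is an RM (reduced-methylation) allele when its S-region
unmethylated count reaches `⌈f·n⌉` with f = 0.75 — for the canonical
nine shore CpGs, 7 of 9.  The ceiling generalizes the 9-CpG instance
consistently to any region size.  Reads with *any* missing S-region call
are excluded before classification: the rule's denominator is the full
region, so partial vectors are not comparable.

RM ratios carry Wilson score 95% intervals (good boundary behavior for
small clone counts; an alternative would be mean ± SD across clones,
which conflates binomial sampling with biology).  Passage deltas are
simple late-minus-early differences per (line, allele); direction
concordance compares delta signs, with exact-zero ties reported as their
own category rather than forced into up/down.  Correlation is Pearson by
default with Spearman behind a flag.  The two-sample test is the classic
pooled-variance Student's t (zero pooled variance: p = 1 when means
coincide, a degenerate-flagged infinite t otherwise).  No
multiple-testing correction is applied: the assay is single-locus and
tests are interpreted at α = 0.05 individually.

Functional-mRNA accounting uses WT-linked quantities only.  The KO
allele's RM ratio is deliberately absent from that output column: KO
transcripts are removed by nonsense-mediated decay after splicing, so KO
methylation cannot move mature-message levels.

## Expression model

Intensities are post-densitometry arbitrary units; normalization divides
replicate i of a target by replicate i of the housekeeping reference, so
a triplicate stays a triplicate (n = 3) for downstream t-tests, and the
result is invariant to common rescaling.  SD uses the n−1 denominator.
The mRNA/preRNA ratio is computed per replicate and summarized; a
zero-preRNA replicate is NaN-flagged rather than dropped silently.

## Synthetic-data generator

The generator is the package's test bed and defines the simulated study
conditions:

* Each cell carries one WT and one KO allele; each allele is
  independently hypo with probability `p_hypo` (latent epiallele state).
* Conditional on state, S-region CpGs are independent Bernoulli draws
  with methylation probability `m_low` = 0.1 (hypo) or `m_high` = 0.9
  (hyper); O CpGs draw from `m_high` and I CpGs from `m_low` regardless
  of state (constitutive flanks).  Per-CpG independence given the state
  is a deliberate simplification — real epialleles show blockier
  patterns — so recovery results quantify estimator behavior under a
  two-state mixture, not under arbitrary correlation structure.
* Clone reads sample the 2·n_cells allele pool uniformly with
  replacement (default n_reads = 40, within the 29–45 clones typical of
  such experiments; n_cells = 400).  Reads are converted in silico, then
  optionally degraded: an unmethylated C survives as C with probability
  `conversion_failure`; each base is substituted with probability
  `error_rate`.
* Expression: per replicate, mRNA = max(0, baseline + slope · WT-hypo
  fraction + N(0, noise)); preRNA is state-independent and the reference
  is constant — so the mRNA/preRNA ratio falls exactly when the WT hypo
  fraction falls.
* Cohorts: per line and allele the early-passage `p_hypo` is uniform on
  (0.1, 0.9) (the KO allele can be given its own, e.g. wider, range);
  the late-passage value adds N(−0.08, 0.3) clipped to (0.02, 0.98).
  The negative drift mean encodes the tendency of shore methylation to
  accrete in prolonged culture; the large drift SD lets individual lines
  move either way, matching the broad line-to-line swings such
  experiments show.

All generators are pure functions of (config, seed); cohort outputs are
byte-reproducible.

What the generator does **not** emulate: Sanger trace artifacts,
bisulfite-induced degradation/fragmentation, PCR bias or chimeras,
within-allele correlation beyond the two-state mixture, and realistic
RT-PCR chemistry.  Passing tests therefore demonstrate correctness of
the algorithms and calibration of the estimators under the stated
generative model, not robustness to every artifact of real clone data.

## Verification design and problem sizes

* Exhaustive oracles where the space is small: all 512 S-region call
  vectors against count-and-compare; all 6 base pairs × 2 CpG contexts
  against enumeration of conversion outcomes (via the conversion engine
  itself, an independent code path); threshold counts against smallest-k
  search.
* An independent plain-DP affine aligner (in the test suite only) checks
  the production aligner's scores; a hand-rolled covariance formula
  checks Pearson r to 1e-12; an exhaustive/Monte-Carlo permutation test
  checks the t-test p-value.
* Round-trip fidelity: 1,000 noise-free reads re-aligned, allele-assigned
  and called with 100% agreement to generator truth.
* Estimator recovery: over true hypo fractions 0.1–0.9 (40 reads, 200
  replicates each) the RM ratio's mean absolute error stays below 0.12
  and Wilson intervals cover the truth-induced RM probability ≥ 90% of
  the time.  The RM ratio is a noisy proxy for the latent hypo fraction:
  its expectation is ≈ 0.947·p_hypo under the default emission
  probabilities (a hypo allele passes 7-of-9 with probability 0.947),
  which bounds the attainable accuracy.
* Correlation structure: across 200 simulated six-line cohorts the
  per-cohort Pearson r between expression change and WT RM-ratio change
  exceeds 0.8 in ≥ 95% of cohorts under coupling, and is centered on
  zero with the coupling removed.  For this population-level check the
  RM ratio is computed by applying the classifier to every allele of the
  simulated population (the quantity a finite clone sample estimates);
  clone-sampling noise at n = 40 is quantified separately by the
  recovery study above.
* QC calibration: simulated conversion-failure sweeps (500 reads per
  rate) match the closed-form binomial-tail rejection probability at the
  0.95 threshold.

These sizes (≤ 1,000 reads per test, 100–200 replicate cohorts at
n_cells ≤ 600) were chosen so the full suite completes in well under a
minute while keeping Monte-Carlo error far from every asserted bound.

## Known limitations

* Single-amplicon scope: no genome-scale CpG-island/shore annotation,
  no paired-end NGS bisulfite alignment, no AB1 chromatogram parsing.
* The alignment model penalizes but does not explicitly model
  5′/3′ primer artifacts beyond the trim offsets.
* Methylation–expression outputs are descriptive (correlations,
  concordance); the package makes no causal claim.
* Whether real clone datasets were pre-filtered for conversion failure
  is generally unknowable; the 0.95 threshold is a convention and is
  configurable.
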