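# Methods

## Problem and model

Somatic variants inside exonic splicing enhancers (ESEs) can prevent SR
proteins from binding, so the exon carrying the variant is skipped during
splicing.  In a tumor-only cohort there is no matched normal RNA-seq to
compare against, but exon skipping leaves a direct footprint in
splice-junction read counts: reads spanning the exon N−1 → N+1 gap exist
only in transcripts that excluded exon N.  eseskip detects these events
from per-sample junction count tables alone.

For a variant in internal exon N, three within-sample junction counts are
taken after counts-per-million normalization (each junction count divided
by the sample's total junction-aligned reads, × 10⁶):

* A — skip junction, exon N−1 → N+1,
* B — inclusion junction, exon N−1 → N,
* C — inclusion junction, exon N → N+1,

and the exon exclusion rate is EER(N−1) = A/B, EER(N+1) = A/C.  A
heterozygous, fully clonal ESE-disrupting variant in a pure tumor makes
one allele's transcripts skip the exon, so both EER values sit near 1;
tumor purity ρ < 1 dilutes this toward ρ.  The *candidate* filter keeps
variants with both EER values in [0.5, 2.0] (inclusive) — deliberately
permissive, with error control deferred to validation.

**Validation.** For each candidate, control samples are all same-project
samples with a usable junction profile and *no* somatic variant of any
classification inside the exon.  A Gaussian KDE is fitted to the
controls' normalized count A for the same skip junction and the carrier's
A is scored by its upper-tail probability; p < α (default 0.05) calls the
variant ESE-disrupting.  Controls and densities never cross project
boundaries.

**Permutation null.** The variant↔profile pairing is shuffled uniformly
within each project and the whole pipeline re-run (default 1000
iterations); the mean permuted call count estimates the pipeline's false
positives while preserving per-project variant burden and depth structure.
Fixed points are allowed (true uniform shuffle, not a derangement).

**NMD analysis.** Nonsense variants are cross-classified by ESE status
(membership in the detection call set) × reading frame of the skip (exon
length divisible by 3).  Each carrier's expression is scored as a KDE
lower-tail probability against same-project samples with no nonsense
variant in that gene.  NMD degradation drags non-ESE carriers' tails
toward 0; ESE-disrupting nonsense variants lose the premature stop along
with the skipped exon and escape, with medians at or above 0.5.

## KDE numerics

* Bandwidth: the nrd0 rule of thumb, `0.9·min(sd, IQR/1.349)·n^(−1/5)`,
  ported from the reference estimator including its fallback chain
  (sd/IQR → |x₁| → 1) and cross-checked against `bw.nrd0`.  A relative
  tolerance (sd ≤ max|x|·1e−12 treated as 0) makes the fallback fire on
  numerically-constant inputs where pairwise summation leaves an
  ulp-sized sd.
* Density: Gaussian kernel tabulated on 512 evenly spaced points spanning
  [min − 3h, max + 3h], mirroring the reference defaults.
* Tails: lower(X) = ∫₀^X f, upper(X) = 1 − lower(X), by trapezoidal
  integration on a fixed lattice anchored at 0 with spacing one quarter of
  the tabulated grid's, density evaluated exactly from the mixture at each
  abscissa.  At the 512-point resolution alone the composite trapezoid
  error reaches ~1e−4; the refinement brings agreement with the
  closed-form mixture integral to ~1e−5 while keeping the tails
  deterministic and monotone in X.  Integration is capped 10 bandwidths
  past the largest control value, where remaining mass is below double
  precision.
* Truncation at zero: the integral starts at 0, so kernel mass leaking
  below zero is excluded and upper-tail values are inflated
  (conservative).  This matters when controls contain an atom at exactly
  0 — common for skip junctions, where each zero-valued control leaks half
  a kernel below zero and floors the upper tail near 0.18 at typical zero
  fractions.  The detection step therefore renormalizes the tail to the
  [0, ∞) support by default (`renormalize=True`); the kde module's default
  keeps the raw truncated integral.  For expression lower tails the two
  conventions agree to rounding because expression values sit far from 0.
* Minimum control-set size: 20 (configurable).  Below it a candidate is
  reported *unvalidatable*, not rejected.
* Zero-variance control sets use the bandwidth fallback chain rather than
  being dropped.

## Design choices on open points

* **Transcript selection**: a variant falling in exons of several
  transcripts is assigned to the transcript with the most exons, ties
  broken by lexicographic transcript id; an all-transcripts mode exists
  (`VariantAssigner.assign_all`).
* **Splice-site exclusion** is by MAF classification only
  (`Splice_Site`, an intronic annotation); exonic bases near junctions are
  not additionally excluded.
* **Indels** are assigned by start position; variants extending past the
  exon end are dropped with a warning.
* **Control exclusion** uses any variant in the exon, not just
  same-position variants.
* **Absent junction rows are zero counts**, not missing data: the legacy
  junction tables enumerate a fixed junction universe.
* **No multiple-testing correction** on α: error control is the
  permutation test's job, matching the source method.
* **Hypergeometric enrichment** is the exact upper tail P(X ≥ k)
  (scipy's survival function; the test suite carries an exhaustive
  enumeration oracle for all N ≤ 12).
* **PWMs are user-supplied** (YAML: name, threshold, or-group, 4×L
  matrix).  The classical SELEX-derived SR-protein matrices are an
  external licensed resource and are not shipped; an or-group expresses
  proteins scored by two matrices where either hit counts.
* **Motif disruption** at a variant: *absent* (no reference hit overlaps
  the variant base), *disrupted* (overlapping reference hit, no
  overlapping alternate hit), *retained* (both), *created* (alternate
  only).  Minus-strand genes are scanned on the reverse complement
  (caller-provided windows).
* **Positional histogram**: 20 left-closed bins on [0, 1], 0 = 5′ end of
  the exon in transcript orientation.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
in the same file dialects it parses (junction tables, MAF, RSEM tables,
refFlat, manifest), plus a ground-truth table.

* Depth: per (sample, gene) gamma with shape = dispersion (default 10) and
  mean μ (default 200); per-junction inclusion counts Poisson around it —
  marginally negative binomial, correlated along a gene as reads of one
  transcript are.
* Background skipping: skip junctions draw Poisson(ε·depth), ε = 0.005.
* Planted ESE variants add `round(ψρ·(B+C)/2)` skip reads against the
  carrier's own realized B, C, so realized EERs track ψρ per sample
  despite count noise (defaults ψ = 0.8, ρ = 0.9).
* Expression: log-normal with gene-level (sdlog 0.75) and sample-level
  (sdlog 0.3) components around exp(7) ≈ 1100 normalized counts.
  Non-ESE nonsense carriers are multiplied by δ = 0.4 (NMD degradation).
  ESE nonsense carriers are multiplied by an escape/accumulation factor of
  1.25: carriers exchangeable with controls would put the group median
  *exactly* at 0.5 (a coin flip at any group size), whereas the observed
  escape signature is a median strictly above 0.5 — consistent with
  skipped transcripts accumulating; 1.25 (≈ +0.7 sample-level standard
  deviations in log space) is the minimal structure that reproduces that
  direction robustly.
* Decoys (no count effect) carry a Missense/Silent/Nonsense mix so
  variant-type summaries and false-positive rates are measurable; each
  variant occupies a fresh (sample, gene) pair so expression effects never
  collide.
* Internal exon lengths alternate between frame-preserving
  {90, 120, 150, 180} and frame-breaking {100, 130, 160, 190} pools, so
  both frame classes always exist and nonsense plantings can balance the
  four-way NMD table.

What the generator does **not** emulate: nucleotide sequence (no FASTA,
no actual motifs — PWM scanning is tested with toy matrices), multiple
transcripts per gene, purity variation between samples, junction-universe
differences between samples, or depth↔expression coupling.  A green
recovery test therefore establishes that the statistics behave as designed
on data with the assumed noise structure, not that real-cohort quirks
(batch effects, alignment artifacts, annotation errors) are handled.

## Known limitations

* EER is undefined when a flanking junction has zero coverage; such
  variants are never candidates (logged).
* No tumor-purity estimation or EER rescaling; the permissive candidate
  window absorbs purity dilution, as in the source method.
* Single-transcript reasoning: alternative first/last exons beyond the
  chosen transcript model are invisible.
* The NMD analysis is purely distributional; no PTC-position rules
  (e.g. last-exon or 50-nt boundary) are modeled.
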