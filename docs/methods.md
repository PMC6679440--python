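# Methods

## Scope and data contract

`ampsnv` operates on per-sample count tables, not on alignments. The input
contract is a TSV with one row per position carrying the reference base,
per-strand depths and per-strand counts of all four bases; the four base
counts on a strand must partition that strand's depth. Base- and
read-quality filtering is assumed to have happened upstream in whatever
produced the counts, and positions a count extractor dropped (e.g. below
its own minimum coverage) may simply be absent — an absent position counts
as unusable for that normal during error estimation. Panels are ordinary
BED (0-based half-open); count files and call outputs use 1-based inclusive
coordinates as in pileup/VCF practice.

## Error model

For each (position, alternative allele, strand) the background rate is the
pooled fraction of supporting reads across usable normals plus the
pseudo-count C: `s = Er/Erd + C`. Usability is decided by two filters:

* **Germline/noise separation** (`vaf_cap`, default 0.05): a normal whose
  strand-combined VAF for the allele exceeds the cap is excluded *for that
  allele only*. Strand-combined VAF is used because a germline variant
  manifests on both strands; per-strand VAF would let one noisy strand
  disqualify a clean one.
* **Coverage** (`min_strand_coverage`, default 100 reads): a normal below
  the threshold on either strand is excluded for *all* alleles at the
  position — a thin strand makes both Er and Erd unreliable.

When the excluded fraction reaches `max_unusable_fraction` (default 2/3,
inclusive) the (position, allele) is non-callable and the caller suppresses
candidates there, reporting them in a side channel instead of raising.
Non-callable sites typically include common polymorphisms (many normals
carry the allele above the cap); since the intended use is somatic calling,
that loss is accepted rather than worked around. The degenerate case
`Erd = 0` (possible only when `min_strand_coverage=0` admits zero-depth
samples) is likewise marked non-callable: no rate is estimable from zero
reads.

`max_normal_vaf` — the largest strand-combined VAF among the *usable*
normals — is stored per entry and drives the `PositionWithHighNoise` flag.
Samples excluded by the VAF cap do not contribute: including germline
carriers would raise the threshold to ~50% at every polymorphic site and
the flag would fire on essentially all somatic calls there, defeating its
purpose as a noise indicator.

Fewer than 10 normals triggers a warning (not an error): the pooled
denominator becomes small enough that rare-error positions are badly
estimated. The constant-rate fallback (`constant_error_model`, default
0.01) supports panels with no normals at all; 0.01 reflects the typical
raw error scale of amplicon semiconductor sequencing.

The model persists as a versioned TSV with `#`-prefixed metadata lines
(configuration and cohort size). Floats are written with `repr`, so a
save/load round-trip is bit-exact; a version mismatch is a hard error.

## Calling

Candidates are (position, alt) pairs with at least one supporting read on
either strand, at positions whose depth is *strictly* greater than `rd_min`
on both strands (the depth rule is worded as "higher than" and implemented
strictly). Each strand is scored with its own `s` via the Poisson upper
tail `P(X ≥ k)`, computed as the regularised incomplete gamma function
`gammainc(k, K·s)` — numerically stable where naive summation of
`1 − Σ pmf` cancels catastrophically. A brute-force summation oracle in
the test suite pins the implementation to 1e−12 absolute over the grid
k ≤ 50, λ ≤ 20.

P-values are clamped at `p_floor = 1e-320` before Phred conversion, so Q is
finite (≤ 3200) even where the tail underflows double precision; Q values
are written to 2 decimals. A variant is reported iff Q ≥ 5 on both strands
(p ≤ 10^−0.5 per strand); the reported quality is the mean of the two
strand Qs. No multiple-testing correction is applied — the position-wise
error rates already absorb the systematic component of the noise, and the
flags (not a genome-wide error rate) are the intended precision control.

Flag semantics follow the thresholds exactly as worded, which makes two of
them deliberately non-complementary: `LowSupportingReads` fires at k < 5
and `PositionWithHighNoise` requires k > 5, so k = 5 satisfies neither.
`PositionWithHighNoise` compares the call's VAF against the entry's
`max_normal_vaf`. The strand-bias test is the two-sided Fisher exact test
on `[[k+, K+−k+], [k−, K−−k−]]` with the minimum-likelihood convention for
two-sidedness (the dominant convention across exact-test implementations;
an enumeration oracle in the tests verifies it). `PASS` appears iff no
warning flag does.

Two flags depend on optional inputs and are skipped when those are absent:

* **AmpliconEdge** — fires when ≥ 2 amplicons cover the position *and* it
  lies within `edge_window` (default 10 bp) of a boundary of a covering
  amplicon. Requiring overlap restricts the flag to the zones where
  amplicon ends actually coexist with read starts of a neighbouring
  amplicon; both conditions are configurable.
* **HomoPolymerRegion** — fires when the reference context contains a run
  of ≥ `homopolymer_min_run` (default 5) identical bases and the call sits
  inside or immediately adjacent to the run. Adjacency is included because
  indel-driven misalignment at a run's edge shows up one base outside it.
  The rule is a self-contained criterion chosen for this package;
  run-length 5 matches the scale at which semiconductor-sequencing
  homopolymer errors become prominent.

Defaults `rd_min=100`, `sb_threshold=0.05`; the `lenient` preset
(`rd_min=50`, `sb_threshold=0.01`) trades a small amount of precision for
recall at poorly covered positions, mirroring the trade-off users face on
real panels.

## Simulator

`simulate_normals` draws, per sample and position, a per-strand depth from
a negative binomial (mean 1000 reads/strand, dispersion size 20 by default
— uneven amplicon coverage with CV ≈ 23%; a constant-depth mode exists for
exact tests) and per (allele, strand) a Binomial(depth, e_true) read count.
`heterogeneous_profile` draws e_true from a log-normal centred at 3e−4
(σ = 1), multiplies transition-type substitutions (A>G/T>C, C>T/G>A) by 3,
makes 2% of (position, allele) pairs "hot" at ~20× the base rate, and caps
everything at 0.045 so hot positions still register as sub-5% noise. These
magnitudes emulate the systematic, position- and substitution-type-specific
error structure of amplicon semiconductor data; they are scientific
defaults of this package, not fitted to any particular instrument.
Germline heterozygous sites are simulated population-style: each sample is
a carrier with a configurable frequency (default 0.3) and carriers draw the
allele at rate 0.5. Carrier frequencies below ~0.5 keep such sites callable
(the VAF filter excludes carriers, but fewer than 2/3 of normals).

What the simulator does **not** model: read-level effects (mapping,
soft-clipping, primer sequences), correlated errors across positions or
samples, amplicon-edge pileup artifacts, contamination, and the exact noise
magnitudes of any real platform. Passing benchmarks on simulated cohorts
therefore demonstrates correctness of the statistical machinery and the
direction of the trained-model advantage, not field performance on a given
instrument.

Two protocol drivers reproduce the package's benchmark designs:

* **Self-consistency** (`run_self_consistency`): per repeat, train on a
  random M of N normals, call the held-out N−M, and label candidate alleles
  (≥ 1 supporting read at a deep-enough position) with VAF ≥ 20% as
  positives — on normal samples those are the germline variants. FDR and
  TPR are computed both over calls with Q ≥ 20 on both strands and over
  PASS-only calls; medians are taken across repeats. The default here is
  10 repeats on a 60-sample cohort with M = 20 — a reduced scale chosen so
  the whole protocol runs in seconds while keeping ≥ 40 held-out samples
  per repeat; the protocol accepts any (M, c) grid and repeat count.
  `baseline_caller_run` is the comparison arm: identical protocol with the
  constant model s = c (no estimation step).
* **Spiked variants** (`run_synthetic_variant_experiment`): every callable
  (position, allele) receives a synthetic observation with depth COV split
  evenly across strands and a = COV·VAF/2 supporting reads per strand; the
  (COV, VAF) grids default to COV ∈ {800, 1600, 3200, 6400} and VAF ∈
  {0.5, 1, 1.25, 2, 3, 4}%, pairs constrained to integer a. All spikes are
  positives, so only TPR (of PASS calls) is defined. Because spikes are
  strand-symmetric the Fisher test cannot fire; the LowQ, support-count and
  high-noise flags operate as in normal calling.

The truth threshold of 20% VAF separates germline heterozygotes (~50%)
from sub-5% noise with a wide margin on both real and simulated VAF
distributions. Zero-count alleles are not part of the candidate universe:
the caller cannot emit them, so counting them as negatives would inflate
the denominator with undecidable cases.

## Numerical and tie-break choices

* Poisson tail via `scipy.special.gammainc(k, λ)`; k = 0 returns exactly 1,
  λ = 0 with k > 0 returns exactly 0 (before clamping).
* Fisher p via `scipy.stats.fisher_exact`, two-sided.
* Percent renderings of TPR/PPV/FDR/F1 round half up to integers; the
  fractional values are always retained because published tables sometimes
  truncate rather than round, and the fraction is the canonical value.
* Undefined measures (empty denominators) are `None`, rendered as
  "undefined", never an exception.
* The 2/3 callability cutoff is inclusive (excluded fraction ≥ 2/3) and is
  evaluated jointly over both strands per (position, allele).
* Sample order never affects estimates (summation is commutative and the
  implementation iterates a deterministic position union).

## Known limitations

* No indel calling; substitutions only.
* Germline/somatic separation is left to the user (call tumor and matched
  normal, diff the outputs) — by design, as the error model needs no
  matched normal.
* Positions non-callable in the model are invisible to calling; panels with
  many common SNPs lose those sites.
* The constant-rate fallback ignores position effects entirely; on
  heterogeneous noise it produces the large FDR excess that the
  self-consistency benchmark quantifies, and it is meant as a last resort.
* With very few normals the model under-estimates rare position effects;
  the < 10-normals warning is the only guard.
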