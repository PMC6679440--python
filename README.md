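# ampsnv

Detection of single-nucleotide variants (SNVs) at low allele fractions in
amplicon-based deep sequencing data — the regime of liquid-biopsy / ctDNA
panels sequenced to 1000x and beyond, where PCR and platform artifacts
routinely reach 1% variant allele frequency (VAF) and drown out real
low-frequency mutations.

`ampsnv` is aimed at groups running targeted amplicon panels (for example on
semiconductor sequencers, which have comparatively high raw error rates) who
have a collection of normal samples from the same panel and want to call
somatic SNVs in tumor or plasma samples without matched-normal subtraction
at the calling stage.

## The model

**Background error estimation.** The method assumes that non-reference
alleles seen at VAF < 5% in normal samples are, overwhelmingly, sequencing
noise. For every genomic position, every alternative allele α and each strand
(+/−), the background error is the pooled read fraction across N normal
samples plus a pseudo-count C:

    s^{α,±} = Er^{α,±} / Erd^{±} + C,
    Er^{α,±} = Σ_i R_i^{α,±},   Erd^{±} = Σ_i RD_i^{±}

where R_i is sample i's count of reads supporting α on that strand and RD_i
its strand depth. Two filters guard the estimate: samples where α exceeds 5%
VAF are excluded for that allele (germline variants are not noise), and
samples with fewer than 100 reads on either strand are excluded for all
alleles at that position. When two-thirds or more of the normals are excluded
the (position, allele) is *non-callable*. With no normals available, a
constant rate (default 0.01) can be assigned everywhere.

**Calling.** In a sample of interest, a candidate allele with k supporting
reads at strand depth K is scored against a Poisson null with mean K·s (the
expected number of error reads at that depth):

    p = P(X ≥ k),  X ~ Poisson(K·s),   Q = −10·log10(p)

each strand with its own s. Positions need depth > RD_min (default 100) per
strand; a variant is reported when Q ≥ 5 on both strands and its mean strand
Q is the call quality. P-values are deliberately not corrected for multiple
testing. Reported calls acquire warning flags — `LowQ` (Q < 20 on a strand),
`LowSupportingReads` (< 5 reads on a strand), `AmpliconEdge` (inside an
overlapping amplicon edge zone), `StrandBias` (two-sided Fisher exact test
p < SB_th, default 0.05), `HomoPolymerRegion`, `PositionWithHighNoise`
(VAF below the highest VAF seen among the noise reads of the normals) — or
`PASS` when none applies. The pseudo-count C acts as a sensitivity floor:
variants at VAF ≲ C are by construction indistinguishable from noise.

## Worked example

The package ships a cohort simulator, so the full workflow runs without any
external data. Simulate 20 normals over a 60-position panel (heterogeneous
position-specific noise plus a handful of germline heterozygous sites),
train the error matrix, and call one sample against it:

```sh
ampsnv simulate normals --n 20 --n-positions 60 --seed 11 --out-dir cohort
ampsnv error-estimate cohort/normal_*.tsv --out errors.tsv --pseudo-count 0.002
ampsnv call --counts cohort/normal_000.tsv --error-model errors.tsv --out calls.tsv
```

`calls.tsv` then contains (abridged):

```
chrom  pos   ref alt vaf        k_fwd k_rev K_fwd K_rev q_fwd   q_rev   q_mean  flags
chr1   1001  A   G   0.525741   310   364   596   686   3200.00 3200.00 3200.00 PASS
chr1   1017  T   C   0.0322447  42    36    1178  1241  7.18    12.00   9.59    LowQ;PositionWithHighNoise
chr1   1026  T   A   0.508118   646   512   1250  1029  3200.00 3200.00 3200.00 PASS
```

The PASS rows are the sample's simulated germline heterozygous variants,
recovered at ~50% VAF with saturated Q scores. The chr1:1017 T>C row is a
noisy position: 3.2% VAF support that the position-specific model recognises
as marginal (Q barely above the reporting threshold) and flags — on a
constant-error model this would have been a convincing false positive.
Calling a matched normal and diffing the two output files separates germline
from somatic calls.

To quantify performance against a truth set:

```sh
ampsnv evaluate --calls calls.tsv --truth truth.tsv
```

prints one row with sensitivity (TPR), precision (PPV), false discovery rate
(FDR = 1 − PPV) and F1, as fractions and integer percents.

Benchmark drivers are available as `ampsnv simulate self-consistency`
(train on M of N normals, test on the held-out rest, VAF ≥ 20% defining
positives; median FDR/TPR over repeats) and `ampsnv simulate variants`
(spiked alleles at fixed coverage and VAF; PASS-call sensitivity over the
grid).

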