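"""Cumulative-Poisson SNV calling against a background-error model.

For a candidate allele with k supporting reads at strand depth K and
background error rate s, the p-value is the upper tail of a Poisson
distribution with mean K*s (the expected number of error-driven
substitutions at that depth):

    p = P(X >= k),  X ~ Poisson(K * s)

Each strand is tested with its own s, p-values are Phred-scaled
(Q = -10*log10 p) and a variant is reported only when Q >= 5 on both
strands; the reported score is the mean of the two strand Q scores.
P-values are deliberately not adjusted for multiple testing. Reported
calls then receive warning flags (low quality, few supporting reads,
amplicon-edge location, strand bias, homopolymer context, noisy position)
or PASS when no warning applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from scipy import special, stats

from .counts_io import (
    BASES,
    AmpliconPanel,
    PositionKey,
    SampleCounts,
    reference_context,
)
from .error_model import ErrorModel

#: Smallest p-value before Phred conversion; Poisson tails underflow to 0.0
#: at large k and this clamp keeps Q finite (Q <= 3200).
P_FLOOR = 1e-320

PASS = "PASS"
LOW_Q = "LowQ"
LOW_SUPPORTING_READS = "LowSupportingReads"
AMPLICON_EDGE = "AmpliconEdge"
STRAND_BIAS = "StrandBias"
HOMOPOLYMER_REGION = "HomoPolymerRegion"
POSITION_WITH_HIGH_NOISE = "PositionWithHighNoise"

WARNING_FLAGS = (
    LOW_Q,
    LOW_SUPPORTING_READS,
    AMPLICON_EDGE,
    STRAND_BIAS,
    HOMOPOLYMER_REGION,
    POSITION_WITH_HIGH_NOISE,
)


@dataclass(frozen=True)
class CallerConfig:
    """Variant-calling thresholds.

    rd_min
        Positions are considered only when the depth on each strand is
        strictly greater than this (reads, default 100).
    sb_threshold
        Fisher exact-test p-value below which the strand-bias flag fires
        (default 0.05).
    q_report
        Per-strand Phred threshold for a variant to be reported at all
        (default 5).
    q_lowq
        Per-strand Phred threshold under which a reported variant is flagged
        LowQ (default 20, i.e. p > 0.01 on some strand).
    min_supporting
        Supporting reads per strand below which LowSupportingReads fires
        (default 5).
    homopolymer_min_run
        Run length of identical reference bases that defines a homopolymer
        (default 5).
    edge_window
        Distance in bp from an amplicon boundary that counts as the edge zone
        (default 10).
    """

    rd_min: int = 100
    sb_threshold: float = 0.05
    q_report: float = 5.0
    q_lowq: float = 20.0
    min_supporting: int = 5
    homopolymer_min_run: int = 5
    edge_window: int = 10

    def __post_init__(self) -> None:
        if self.rd_min < 0:
            raise ValueError("rd_min must be >= 0")
        if not 0 < self.sb_threshold < 1:
            raise ValueError("sb_threshold must be in (0, 1)")
        if self.q_report > self.q_lowq:
            raise ValueError("q_report must not exceed q_lowq")

    @classmethod
    def lenient(cls, **overrides) -> "CallerConfig":
        """Preset trading a little precision for recall: RD_min=50, SB_th=0.01."""
        defaults = {"rd_min": 50, "sb_threshold": 0.01}
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class ObservedAllele:
    """A candidate substitution: per-strand supporting reads and depths."""

    key: PositionKey
    alt: str
    k_fwd: int
    k_rev: int
    K_fwd: int
    K_rev: int

    def __post_init__(self) -> None:
        for k, K, strand in ((self.k_fwd, self.K_fwd, "+"), (self.k_rev, self.K_rev, "-")):
            if k < 0 or K < 0:
                raise ValueError(f"negative counts on strand {strand}")
            if k > K:
                raise ValueError(
                    f"supporting reads {k} exceed depth {K} on strand {strand}"
                )

    @property
    def vaf(self) -> float:
        depth = self.K_fwd + self.K_rev
        return (self.k_fwd + self.k_rev) / depth if depth else 0.0


@dataclass(frozen=True)
class VariantCall:
    """A reported SNV with per-strand statistics and quality flags."""

    observed: ObservedAllele
    vaf: float
    p_fwd: float
    p_rev: float
    q_fwd: float
    q_rev: float
    q_mean: float
    flags: frozenset[str]

    @property
    def is_pass(self) -> bool:
        return PASS in self.flags


def poisson_tail_pvalue(k: int, K: int, s: float) -> float:
    """P(X >= k) for X ~ Poisson(K*s), the chance that background error alone
    produces k or more supporting reads at strand depth K.

    Uses the regularised incomplete gamma function (P(X >= k) =
    gammainc(k, K*s)) rather than naive term summation.
    """
    if k < 0 or K < 0 or s < 0:
        raise ValueError(f"k, K and s must be non-negative (k={k}, K={K}, s={s})")
    if k == 0:
        return 1.0
    lam = K * s
    if lam == 0:
        return 0.0
    return float(special.gammainc(k, lam))


def qscore(p: float, clamp: bool = True) -> float:
    """Phred-scale a p-value: Q = -10*log10(p), clamping p at P_FLOOR first."""
    if clamp:
        p = min(max(p, P_FLOOR), 1.0)
    if not 0 < p <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def strand_bias_pvalue(obs: ObservedAllele) -> float:
    """Two-sided Fisher exact test for strand imbalance of variant support.

    Tests the 2x2 table [[k_fwd, K_fwd-k_fwd], [k_rev, K_rev-k_rev]] against
    the null that variant reads split across strands in proportion to the
    strand depths; the two-sided p sums all tables at most as likely as the
    observed one (minimum-likelihood convention).
    """
    if obs.K_fwd < 1 or obs.K_rev < 1:
        raise ValueError("strand-bias test requires depth >= 1 on both strands")
    table = [
        [obs.k_fwd, obs.K_fwd - obs.k_fwd],
        [obs.k_rev, obs.K_rev - obs.k_rev],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def is_homopolymer(context: str, centre_index: int, min_run: int = 5) -> bool:
    """Whether the centre base sits inside, or immediately adjacent to, a run
    of >= min_run identical bases within ``context``."""
    if not 0 <= centre_index < len(context):
        raise ValueError(
            f"centre_index {centre_index} outside context of length {len(context)}"
        )
    context = context.upper()
    i = 0
    while i < len(context):
        j = i
        while j < len(context) and context[j] == context[i]:
            j += 1
        if j - i >= min_run and i - 1 <= centre_index <= j:
            return True
        i = j
    return False


def is_amplicon_edge(
    key: PositionKey, panel: AmpliconPanel, edge_window: int = 10
) -> bool:
    """Whether the position lies in an overlapping amplicon edge zone.

    True iff >= 2 amplicons cover the position and it is within
    ``edge_window`` bp of a boundary of at least one covering amplicon.
    """
    covering = panel.covering(key.chrom, key.pos)
    if len(covering) < 2:
        return False
    p0 = key.pos - 1
    return any(
        p0 - start < edge_window or end - 1 - p0 < edge_window
        for _, start, end, _ in covering
    )


def score_allele(
    obs: ObservedAllele, s_fwd: float, s_rev: float
) -> tuple[float, float, float, float]:
    """Per-strand (p_fwd, p_rev, q_fwd, q_rev) for an observed allele."""
    p_fwd = poisson_tail_pvalue(obs.k_fwd, obs.K_fwd, s_fwd)
    p_rev = poisson_tail_pvalue(obs.k_rev, obs.K_rev, s_rev)
    return p_fwd, p_rev, qscore(p_fwd), qscore(p_rev)


def assign_flags(
    obs: ObservedAllele,
    q_fwd: float,
    q_rev: float,
    config: CallerConfig,
    max_normal_vaf: float = 0.0,
    at_edge: bool = False,
    in_homopolymer: bool = False,
) -> frozenset[str]:
    """Warning flags for a reported variant; PASS when no warning applies."""
    flags: set[str] = set()
    if min(q_fwd, q_rev) < config.q_lowq:
        flags.add(LOW_Q)
    if obs.k_fwd < config.min_supporting or obs.k_rev < config.min_supporting:
        flags.add(LOW_SUPPORTING_READS)
    if at_edge:
        flags.add(AMPLICON_EDGE)
    if strand_bias_pvalue(obs) < config.sb_threshold:
        flags.add(STRAND_BIAS)
    if in_homopolymer:
        flags.add(HOMOPOLYMER_REGION)
    if (
        obs.k_fwd > config.min_supporting
        and obs.k_rev > config.min_supporting
        and obs.vaf < max_normal_vaf
    ):
        flags.add(POSITION_WITH_HIGH_NOISE)
    if not flags:
        flags.add(PASS)
    return frozenset(flags)


def call_variants(
    sample: SampleCounts,
    model: ErrorModel,
    config: CallerConfig | None = None,
    panel: AmpliconPanel | None = None,
    reference: str | Path | None = None,
    side_report: list | None = None,
) -> list[VariantCall]:
    """Call SNVs in one sample against a background-error model.

    Only positions with depth strictly above ``rd_min`` on both strands are
    examined. Candidates at positions or alleles the model marks non-callable
    (or does not cover) are suppressed and, when ``side_report`` is given,
    recorded there as ``(PositionKey, alt, reason)`` tuples.
    """
    config = config or CallerConfig()
    fasta = None
    if reference is not None:
        from pyfaidx import Fasta

        fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))

    calls: list[VariantCall] = []
    for key, sc in sample:
        if sc.depth_fwd <= config.rd_min or sc.depth_rev <= config.rd_min:
            continue
        at_edge = (
            is_amplicon_edge(key, panel, config.edge_window) if panel is not None else False
        )
        in_homopolymer = False
        if fasta is not None:
            window = config.homopolymer_min_run + 1
            context = reference_context(fasta, key, window)
            centre = min(key.pos - 1, window)
            in_homopolymer = is_homopolymer(context, centre, config.homopolymer_min_run)
        for alt in BASES:
            if alt == key.ref:
                continue
            k_fwd = sc.alt_fwd.get(alt, 0)
            k_rev = sc.alt_rev.get(alt, 0)
            if k_fwd == 0 and k_rev == 0:
                continue
            entry = model.get(key, alt)
            if entry is None:
                if side_report is not None:
                    side_report.append((key, alt, "absent_from_model"))
                continue
            if not entry.callable:
                if side_report is not None:
                    side_report.append((key, alt, "non_callable"))
                continue
            obs = ObservedAllele(key, alt, k_fwd, k_rev, sc.depth_fwd, sc.depth_rev)
            p_fwd, p_rev, q_fwd, q_rev = score_allele(obs, entry.s_fwd, entry.s_rev)
            if min(q_fwd, q_rev) < config.q_report:
                continue
            flags = assign_flags(
                obs,
                q_fwd,
                q_rev,
                config,
                max_normal_vaf=entry.max_normal_vaf,
                at_edge=at_edge,
                in_homopolymer=in_homopolymer,
            )
            calls.append(
                VariantCall(
                    observed=obs,
                    vaf=obs.vaf,
                    p_fwd=p_fwd,
                    p_rev=p_rev,
                    q_fwd=q_fwd,
                    q_rev=q_rev,
                    q_mean=(q_fwd + q_rev) / 2.0,
                    flags=flags,
                )
            )
    return calls


CALLS_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf",
    "k_fwd",
    "k_rev",
    "K_fwd",
    "K_rev",
    "q_fwd",
    "q_rev",
    "q_mean",
    "flags",
)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ampsnv
##INFO=<ID=VAF,Number=1,Type=Float,Description="Strand-combined variant allele fraction">
##INFO=<ID=KF,Number=1,Type=Integer,Description="Variant reads, forward strand">
##INFO=<ID=KR,Number=1,Type=Integer,Description="Variant reads, reverse strand">
##INFO=<ID=DPF,Number=1,Type=Integer,Description="Read depth, forward strand">
##INFO=<ID=DPR,Number=1,Type=Integer,Description="Read depth, reverse strand">
##INFO=<ID=QF,Number=1,Type=Float,Description="Phred score, forward strand">
##INFO=<ID=QR,Number=1,Type=Float,Description="Phred score, reverse strand">
##FILTER=<ID=LowQ,Description="Q below 20 on at least one strand">
##FILTER=<ID=LowSupportingReads,Description="Fewer than 5 supporting reads on a strand">
##FILTER=<ID=AmpliconEdge,Description="Within an overlapping amplicon edge zone">
##FILTER=<ID=StrandBias,Description="Fisher strand-bias p below threshold">
##FILTER=<ID=HomoPolymerRegion,Description="Within or adjacent to a homopolymer run">
##FILTER=<ID=PositionWithHighNoise,Description="VAF below the maximum normal-sample VAF">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _ordered_flags(flags: frozenset[str]) -> str:
    if PASS in flags:
        return PASS
    return ";".join(f for f in WARNING_FLAGS if f in flags)


def write_calls(
    calls: Sequence[VariantCall], path: str | Path, format: str = "tsv"
) -> None:
    """Write calls as TSV (Q scores to 2 decimals) or minimal VCF 4.2."""
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("\t".join(CALLS_COLUMNS) + "\n")
            for c in calls:
                o = c.observed
                fh.write(
                    "\t".join(
                        (
                            o.key.chrom,
                            str(o.key.pos),
                            o.key.ref,
                            o.alt,
                            f"{c.vaf:.6g}",
                            str(o.k_fwd),
                            str(o.k_rev),
                            str(o.K_fwd),
                            str(o.K_rev),
                            f"{c.q_fwd:.2f}",
                            f"{c.q_rev:.2f}",
                            f"{c.q_mean:.2f}",
                            _ordered_flags(c.flags),
                        )
                    )
                    + "\n"
                )
    elif format == "vcf":
        with path.open("w") as fh:
            fh.write(_VCF_HEADER)
            for c in calls:
                o = c.observed
                info = (
                    f"VAF={c.vaf:.6g};KF={o.k_fwd};KR={o.k_rev};"
                    f"DPF={o.K_fwd};DPR={o.K_rev};QF={c.q_fwd:.2f};QR={c.q_rev:.2f}"
                )
                fh.write(
                    "\t".join(
                        (
                            o.key.chrom,
                            str(o.key.pos),
                            ".",
                            o.key.ref,
                            o.alt,
                            f"{c.q_mean:.2f}",
                            _ordered_flags(c.flags),
                            info,
                        )
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown output format {format!r} (expected 'tsv' or 'vcf')")
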