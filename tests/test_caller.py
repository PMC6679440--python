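import itertools
import math
from fractions import Fraction
from math import comb, exp, fsum

import numpy as np
import pytest

from ampsnv.caller import (
    AMPLICON_EDGE,
    HOMOPOLYMER_REGION,
    LOW_Q,
    LOW_SUPPORTING_READS,
    P_FLOOR,
    PASS,
    POSITION_WITH_HIGH_NOISE,
    STRAND_BIAS,
    WARNING_FLAGS,
    CallerConfig,
    ObservedAllele,
    assign_flags,
    call_variants,
    is_amplicon_edge,
    is_homopolymer,
    poisson_tail_pvalue,
    qscore,
    strand_bias_pvalue,
    write_calls,
)
from ampsnv.counts_io import AmpliconPanel, PositionKey, read_panel_bed
from ampsnv.error_model import ErrorModelConfig, constant_error_model, estimate_errors

from conftest import single_position_sample

KEY = PositionKey("chr1", 100, "A")


def poisson_tail_oracle(k: int, lam: float) -> float:
    """Brute-force upper tail: sum Poisson pmf terms from k upward."""
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    terms = []
    t = exp(-lam) * lam**k / math.factorial(k)
    i = k
    while t > 1e-300 or i < k + 10 + 10 * lam:
        terms.append(t)
        i += 1
        t *= lam / i
        if i > k + 2000:
            break
    return fsum(terms)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration (min-likelihood)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(c1, r1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


class TestPoissonTail:
    def test_zero_variant_reads_gives_one(self):
        assert poisson_tail_pvalue(0, 5000, 0.01) == 1.0
        assert poisson_tail_pvalue(0, 0, 0.0) == 1.0

    def test_zero_error_rate_gives_zero(self):
        assert poisson_tail_pvalue(1, 1000, 0.0) == 0.0

    def test_pinned_oracle_value_lambda_one(self):
        # k=5, K=1000, s=0.001: oracle value computed by direct summation
        assert poisson_tail_pvalue(5, 1000, 0.001) == pytest.approx(
            0.003659846827343713, abs=1e-12
        )

    def test_pinned_oracle_value_k20_lambda_two(self):
        p = poisson_tail_pvalue(20, 2000, 0.001)
        assert p == pytest.approx(6.44e-14, abs=1e-12)
        assert qscore(p) > 20

    def test_matches_brute_force_on_grid(self):
        lams = [0.01, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0]
        for k, lam in itertools.product(range(51), lams):
            assert poisson_tail_pvalue(k, 1000, lam / 1000) == pytest.approx(
                poisson_tail_oracle(k, lam), abs=1e-12
            ), (k, lam)

    def test_monotone_in_k_K_and_s(self):
        ks = range(0, 30, 3)
        ps = [poisson_tail_pvalue(k, 2000, 0.002) for k in ks]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        ss = [poisson_tail_pvalue(8, 2000, s) for s in (1e-4, 1e-3, 5e-3, 1e-2)]
        assert all(a <= b for a, b in zip(ss, ss[1:]))
        Ks = [poisson_tail_pvalue(8, K, 0.002) for K in (500, 1000, 2000, 4000)]
        assert all(a <= b for a, b in zip(Ks, Ks[1:]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_tail_pvalue(-1, 100, 0.01)
        with pytest.raises(ValueError):
            poisson_tail_pvalue(1, 100, -0.01)


class TestQScore:
    def test_phred_correspondence(self):
        assert qscore(0.01) == pytest.approx(20.0)
        assert qscore(1.0) == 0.0
        assert qscore(1e-6) == pytest.approx(60.0)

    def test_underflow_clamped_to_floor(self):
        assert qscore(0.0) == pytest.approx(-10 * math.log10(P_FLOOR))

    def test_unclamped_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            qscore(0.0, clamp=False)


class TestStrandBias:
    def test_proportional_table_is_null(self):
        obs = ObservedAllele(KEY, "C", 5, 5, 1000, 1000)
        assert strand_bias_pvalue(obs) == pytest.approx(1.0)

    def test_empty_variant_row_is_null(self):
        obs = ObservedAllele(KEY, "C", 0, 0, 1000, 1000)
        assert strand_bias_pvalue(obs) == pytest.approx(1.0)

    def test_pinned_enumeration_value(self):
        # all 10 variant reads on one strand at equal depths
        obs = ObservedAllele(KEY, "C", 10, 0, 1000, 1000)
        assert strand_bias_pvalue(obs) == pytest.approx(
            0.001909465165341615, abs=1e-10
        )

    def test_matches_enumeration_small_margins(self):
        for K1, K2 in itertools.product(range(1, 13), range(1, 13)):
            for k1 in range(K1 + 1):
                for k2 in range(0, K2 + 1, 3):
                    obs = ObservedAllele(KEY, "C", k1, k2, K1, K2)
                    assert strand_bias_pvalue(obs) == pytest.approx(
                        fisher_oracle(k1, K1 - k1, k2, K2 - k2), abs=1e-9
                    ), (k1, k2, K1, K2)

    def test_matches_enumeration_sampled_to_margin_60(self):
        rng = np.random.default_rng(77)
        for _ in range(150):
            K1, K2 = int(rng.integers(1, 61)), int(rng.integers(1, 61))
            k1, k2 = int(rng.integers(0, K1 + 1)), int(rng.integers(0, K2 + 1))
            obs = ObservedAllele(KEY, "C", k1, k2, K1, K2)
            assert strand_bias_pvalue(obs) == pytest.approx(
                fisher_oracle(k1, K1 - k1, k2, K2 - k2), abs=1e-9
            ), (k1, k2, K1, K2)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ObservedAllele(KEY, "C", 11, 0, 10, 10)
        with pytest.raises(ValueError):
            strand_bias_pvalue(ObservedAllele(KEY, "C", 0, 0, 0, 10))


class TestHomopolymer:
    def test_no_run(self):
        assert not is_homopolymer("ACGTACGTA", 4, 5)

    def test_centre_inside_run(self):
        ctx = "TTAAAAACC"
        for centre in range(2, 7):
            assert is_homopolymer(ctx, centre, 5)

    def test_centre_adjacent_to_run(self):
        assert is_homopolymer("CAAAAAG", 0, 5)  # immediately left
        assert is_homopolymer("AAAAAG", 5, 5)  # immediately right
        assert not is_homopolymer("CTAAAAAG", 0, 5)  # one base away

    def test_run_shorter_than_min(self):
        assert not is_homopolymer("TTAAAACC", 3, 5)

    def test_centre_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            is_homopolymer("ACGT", 9, 5)


class TestAmpliconEdge:
    PANEL = AmpliconPanel(
        [("chr1", 0, 120, "a1"), ("chr1", 90, 220, "a2"), ("chr2", 0, 100, "b1")]
    )

    def test_single_amplicon_coverage_is_not_edge(self):
        assert not is_amplicon_edge(PositionKey("chr1", 50, "A"), self.PANEL, 10)
        assert not is_amplicon_edge(PositionKey("chr2", 5, "A"), self.PANEL, 10)

    def test_overlap_near_boundary_is_edge(self):
        # 1-based 118 is 0-based 117, 3 bp from a1's end boundary (119)
        assert is_amplicon_edge(PositionKey("chr1", 118, "A"), self.PANEL, 10)

    def test_overlap_far_from_every_boundary_is_not_edge(self):
        # overlap zone is 0-based [90, 120); 0-based 105 is >= 10 bp from
        # a1's end (119), a2's start (90) and both outer boundaries
        assert not is_amplicon_edge(PositionKey("chr1", 106, "A"), self.PANEL, 10)


class TestFlagLogic:
    def test_pass_iff_no_warning_over_all_combinations(self):
        # drive each warning flag independently through assign_flags inputs
        for low_q, low_k, edge, bias, homo, noise in itertools.product(
            [False, True], repeat=6
        ):
            q = 10.0 if low_q else 50.0
            k = 2 if low_k else 50
            if bias:
                obs = ObservedAllele(KEY, "C", k, 0 if not low_k else 0, 1000, 1000)
            else:
                obs = ObservedAllele(KEY, "C", k, k, 1000, 1000)
            max_vaf = 1.0 if noise else 0.0
            flags = assign_flags(
                obs, q, q, CallerConfig(), max_normal_vaf=max_vaf,
                at_edge=edge, in_homopolymer=homo,
            )
            expect = set()
            if low_q:
                expect.add(LOW_Q)
            if obs.k_fwd < 5 or obs.k_rev < 5:
                expect.add(LOW_SUPPORTING_READS)
            if edge:
                expect.add(AMPLICON_EDGE)
            if strand_bias_pvalue(obs) < 0.05:
                expect.add(STRAND_BIAS)
            if homo:
                expect.add(HOMOPOLYMER_REGION)
            if obs.k_fwd > 5 and obs.k_rev > 5 and obs.vaf < max_vaf:
                expect.add(POSITION_WITH_HIGH_NOISE)
            if not expect:
                expect.add(PASS)
            assert flags == expect
            assert (PASS in flags) == (not flags & set(WARNING_FLAGS))

    def test_exactly_five_reads_fires_neither_support_flag(self):
        obs = ObservedAllele(KEY, "C", 5, 5, 1000, 1000)
        flags = assign_flags(obs, 50, 50, CallerConfig(), max_normal_vaf=1.0)
        assert LOW_SUPPORTING_READS not in flags
        assert POSITION_WITH_HIGH_NOISE not in flags

    def test_raising_sb_threshold_keeps_flag_monotone(self):
        obs = ObservedAllele(KEY, "C", 12, 2, 1000, 1000)
        p = strand_bias_pvalue(obs)
        flagged = [
            STRAND_BIAS
            in assign_flags(obs, 50, 50, CallerConfig(sb_threshold=th))
            for th in (0.001, 0.01, 0.05, 0.2)
        ]
        # once flagged at some threshold, flagged at every higher threshold
        assert flagged == sorted(flagged)
        assert flagged[-1] == (p < 0.2)


class TestCallVariants:
    def model(self, s=0.001, key=KEY):
        return constant_error_model([key], rate=s)

    def test_no_substitutions_no_output(self):
        sample = single_position_sample("t", KEY, 2000, 2000)
        assert call_variants(sample, self.model()) == []

    def test_clear_variant_is_emitted_clean(self):
        # k=20 per strand at depth 2000, s=0.001 (lambda=2): oracle p ~ 6.4e-14
        sample = single_position_sample("t", KEY, 2000, 2000, C_fwd=20, C_rev=20)
        calls = call_variants(sample, self.model())
        assert len(calls) == 1
        c = calls[0]
        assert c.p_fwd == pytest.approx(6.44e-14, abs=1e-12)
        assert c.q_fwd > 20 and c.q_rev > 20
        assert LOW_Q not in c.flags and LOW_SUPPORTING_READS not in c.flags
        assert c.is_pass
        assert c.q_mean == pytest.approx((c.q_fwd + c.q_rev) / 2)
        assert c.vaf == pytest.approx(40 / 4000)

    def test_per_strand_q_report_rule(self):
        # strong forward signal, single reverse read: q_rev < 5 -> suppressed
        sample = single_position_sample("t", KEY, 2000, 2000, C_fwd=30, C_rev=1)
        assert call_variants(sample, self.model(s=0.002)) == []

    def test_depth_threshold_is_strict(self):
        sample = single_position_sample("t", KEY, 100, 2000, C_fwd=30, C_rev=30)
        assert call_variants(sample, self.model(), CallerConfig(rd_min=100)) == []
        sample = single_position_sample("t", KEY, 101, 2000, C_fwd=30, C_rev=30)
        assert len(call_variants(sample, self.model(), CallerConfig(rd_min=100))) == 1

    def test_non_callable_entries_go_to_side_report(self):
        normals = [
            single_position_sample(f"n{i}", KEY, 50, 50) for i in range(10)
        ]
        model = estimate_errors(
            normals, ErrorModelConfig(min_strand_coverage=100)
        )
        sample = single_position_sample("t", KEY, 2000, 2000, C_fwd=30, C_rev=30)
        side = []
        calls = call_variants(sample, model, side_report=side)
        assert calls == []
        assert (KEY, "C", "non_callable") in side

    def test_position_missing_from_model_goes_to_side_report(self):
        other = PositionKey("chr9", 7, "G")
        sample = single_position_sample("t", other, 2000, 2000, A_fwd=30, A_rev=30)
        side = []
        assert call_variants(sample, self.model(), side_report=side) == []
        assert side == [(other, "A", "absent_from_model")]

    def test_homopolymer_flag_from_reference(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\n" + "ACGT" * 24 + "AAAAAACG" + "ACGT" * 10 + "\n")
        # positions 97..102 are the A-run
        key = PositionKey("chr1", 99, "A")
        sample = single_position_sample("t", key, 2000, 2000, C_fwd=20, C_rev=20)
        calls = call_variants(
            sample, self.model(key=key), reference=str(fa)
        )
        assert len(calls) == 1
        assert HOMOPOLYMER_REGION in calls[0].flags

    def test_amplicon_edge_flag_from_panel(self):
        panel = AmpliconPanel([("chr1", 0, 105, "a1"), ("chr1", 95, 200, "a2")])
        sample = single_position_sample("t", KEY, 2000, 2000, C_fwd=20, C_rev=20)
        calls = call_variants(sample, self.model(), panel=panel)
        assert len(calls) == 1 and AMPLICON_EDGE in calls[0].flags


class TestWriteCalls:
    def make_call(self, **alt_counts):
        sample = single_position_sample("t", KEY, 2000, 2000, **alt_counts)
        return call_variants(sample, constant_error_model([KEY], rate=0.001))

    def test_tsv_pass_row(self, tmp_path):
        calls = self.make_call(C_fwd=20, C_rev=20)
        out = tmp_path / "calls.tsv"
        write_calls(calls, out, format="tsv")
        lines = out.read_text().splitlines()
        assert lines[0].split("\t")[:5] == ["chrom", "pos", "ref", "alt", "vaf"]
        fields = lines[1].split("\t")
        assert fields[:4] == ["chr1", "100", "A", "C"]
        assert fields[-1] == "PASS"

    def test_tsv_multiple_warnings_no_pass(self, tmp_path):
        calls = self.make_call(C_fwd=4, C_rev=4)  # LowQ impossible: q>20? check flags
        out = tmp_path / "calls.tsv"
        write_calls(calls, out)
        flags = out.read_text().splitlines()[1].split("\t")[-1].split(";")
        assert "LowSupportingReads" in flags and "PASS" not in flags

    def test_empty_call_list_writes_header_only(self, tmp_path):
        out = tmp_path / "calls.tsv"
        write_calls([], out)
        assert out.read_text().splitlines() == ["\t".join(
            ("chrom", "pos", "ref", "alt", "vaf", "k_fwd", "k_rev", "K_fwd",
             "K_rev", "q_fwd", "q_rev", "q_mean", "flags")
        )]

    def test_vcf_output_parses(self, tmp_path):
        calls = self.make_call(C_fwd=20, C_rev=20)
        out = tmp_path / "calls.vcf"
        write_calls(calls, out, format="vcf")
        lines = out.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        data = [l for l in lines if not l.startswith("#")]
        fields = data[0].split("\t")
        assert fields[0] == "chr1" and fields[3] == "A" and fields[4] == "C"
        assert fields[6] == "PASS"
        assert "KF=20" in fields[7]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_calls([], tmp_path / "x", format="parquet")
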