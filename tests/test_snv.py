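from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import beta as beta_dist

from panelval.snv import (
    CallThresholds, PileupError, PileupRecord, apply_filters, call_variants,
    observed_maf, posterior_variant_prob, strand_fraction,
)
from panelval.panel import Panel, TargetRegion

from oracles import brute_force_filters


def pileup(alt_fwd=0, alt_rev=0, ref_fwd=0, ref_rev=0, normal_alt=0,
           normal_depth=0, ref="A", alt="T"):
    return PileupRecord("chr1", 100, ref, alt, alt_fwd, alt_rev,
                        ref_fwd, ref_rev, normal_alt, normal_depth)


class TestObservedMaf:
    def test_exact_one_percent(self):
        assert observed_maf(pileup(5, 0, 495, 0)) == Fraction(1, 100)

    def test_zero_and_one(self):
        assert observed_maf(pileup(0, 0, 10, 0)) == 0
        assert observed_maf(pileup(5, 5)) == 1

    def test_depth_zero_undefined(self):
        with pytest.raises(PileupError):
            observed_maf(pileup())


class TestStrandFraction:
    def test_biased(self):
        assert strand_fraction(pileup(19, 1)) == Fraction(95, 100)

    def test_symmetric(self):
        assert strand_fraction(pileup(7, 7, 10, 10)) == Fraction(1, 2)

    def test_all_reverse(self):
        assert strand_fraction(pileup(0, 10)) == 0

    def test_no_alt_undefined(self):
        with pytest.raises(PileupError):
            strand_fraction(pileup(0, 0, 10, 10))


class TestPosterior:
    def test_no_evidence_low(self):
        assert posterior_variant_prob(pileup(0, 0, 500, 500)) < 0.5

    def test_strong_evidence_high_vs_numeric_integration(self):
        p = pileup(50, 50, 50, 50)  # alt=100, depth=200
        post = posterior_variant_prob(p)
        assert post > 0.999
        # independent oracle: integrate the Beta(1+100, 99+100) density
        a, b = 1 + 100, 99 + 100
        num, _ = integrate.quad(lambda x: beta_dist.pdf(x, a, b), 0.01, 1.0)
        assert post == pytest.approx(num, abs=1e-6)

    def test_hotspot_prior_raises_posterior(self):
        p = pileup(2, 1, 50, 47)
        assert posterior_variant_prob(p, hotspot=True) >= posterior_variant_prob(p)

    def test_monotone_in_alt_count(self):
        posts = [
            posterior_variant_prob(pileup(k, 0, 100 - k, 0)) for k in range(0, 20)
        ]
        assert posts == sorted(posts)


class TestFilterBoundaries:
    def test_depth_29_fails_30_passes(self):
        assert "LOW_DEPTH" in apply_filters(pileup(5, 5, 10, 9)).filters  # 29
        assert "LOW_DEPTH" not in apply_filters(pileup(5, 5, 10, 10)).filters  # 30

    def test_maf_exactly_one_percent_is_filtered(self):
        # 5/500 = 1% -> strict cut: filtered
        call = apply_filters(pileup(3, 2, 248, 247))
        assert "LOW_MAF" in call.filters

    def test_hotspot_relaxation_passes_0_7_percent(self):
        # 7/1000 = 0.7% > 0.5% hotspot cut
        call = apply_filters(pileup(4, 3, 497, 496), hotspot=True)
        assert call.passed

    def test_normal_boundary_inclusive(self):
        # 0.03 exactly is the allowed maximum; 0.04 is not
        ok = apply_filters(pileup(25, 25, 25, 25, normal_alt=3, normal_depth=100))
        bad = apply_filters(pileup(25, 25, 25, 25, normal_alt=4, normal_depth=100))
        assert "NORMAL_EVIDENCE" not in ok.filters
        assert "NORMAL_EVIDENCE" in bad.filters

    def test_strand_bias_skipped_below_two_alt_reads(self):
        call = apply_filters(pileup(1, 0, 20, 20))
        assert "STRAND_BIAS" not in call.filters
        call = apply_filters(pileup(19, 1, 40, 40))  # 0.95 > 0.9
        assert "STRAND_BIAS" in call.filters

    def test_repeat_rule_for_indels(self):
        # 7 alt of 400 (1.75%): above the plain MAF cut, below both repeat bars
        p = pileup(4, 3, 197, 196, ref="AT", alt="A")
        in_repeat = apply_filters(p, in_repeat=True)
        plain = apply_filters(p)
        assert "REPEAT" in in_repeat.filters and plain.passed
        # 10 alt of 400 (2.5%) with >= 8 reads satisfies the raised bar
        p2 = pileup(5, 5, 195, 195, ref="AT", alt="A")
        assert apply_filters(p2, in_repeat=True).passed

    def test_negative_counts_rejected(self):
        with pytest.raises(PileupError):
            pileup(-1, 0, 10, 10)


class TestOracleEquivalence:
    def test_exhaustive_small_grid(self):
        """The cascade agrees with a brute-force predicate written straight
        from the rules, over an exhaustive small grid of pileups."""
        normals = [(0, 0), (0, 100), (3, 100), (4, 100)]
        for depth in (1, 15, 29, 30, 31, 45, 60):
            for alt in range(depth + 1):
                ref = depth - alt
                fwd_options = {0, 1, alt // 2, max(alt - 1, 0), alt}
                for alt_fwd in sorted(f for f in fwd_options if f <= alt):
                    for n_alt, n_depth in normals:
                        for hotspot in (False, True):
                            for is_indel, in_repeat in (
                                (False, False), (True, False), (True, True),
                            ):
                                ref_allele, alt_allele = (
                                    ("AT", "A") if is_indel else ("A", "T")
                                )
                                p = pileup(
                                    alt_fwd, alt - alt_fwd, ref, 0,
                                    n_alt, n_depth, ref_allele, alt_allele,
                                )
                                got = apply_filters(
                                    p, hotspot=hotspot, in_repeat=in_repeat
                                ).filters
                                want = brute_force_filters(
                                    alt_fwd, alt - alt_fwd, ref, 0,
                                    n_alt, n_depth, hotspot, in_repeat, is_indel,
                                )
                                assert got == frozenset(want), (
                                    depth, alt, alt_fwd, n_alt, n_depth,
                                    hotspot, is_indel, in_repeat,
                                )

    @given(
        alt_fwd=st.integers(0, 200), alt_rev=st.integers(0, 200),
        ref_fwd=st.integers(0, 400), ref_rev=st.integers(0, 400),
        normal_alt=st.integers(0, 20), normal_depth=st.integers(20, 600),
        hotspot=st.booleans(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_random_pileups_match_oracle(
        self, alt_fwd, alt_rev, ref_fwd, ref_rev, normal_alt, normal_depth, hotspot
    ):
        p = pileup(alt_fwd, alt_rev, ref_fwd, ref_rev, normal_alt, normal_depth)
        got = apply_filters(p, hotspot=hotspot).filters
        want = brute_force_filters(
            alt_fwd, alt_rev, ref_fwd, ref_rev, normal_alt, normal_depth, hotspot
        )
        assert got == frozenset(want)


class TestCascadeProperties:
    def test_hotspot_relaxation_preserves_pass(self):
        # every PASS under the plain cut remains PASS at a hotspot
        for alt in range(0, 60):
            for depth in (30, 100, 400):
                if alt > depth:
                    continue
                p = pileup(alt // 2, alt - alt // 2, depth - alt, 0, 0, 100)
                if apply_filters(p).passed:
                    assert apply_filters(p, hotspot=True).passed

    def test_more_alt_reads_never_lose_pass_off_strand_route(self):
        # adding balanced alt reads only raises MAF; PASS is preserved
        base = pileup(10, 10, 200, 200, 0, 100)
        assert apply_filters(base).passed
        for extra in (2, 10, 50):
            boosted = pileup(10 + extra, 10 + extra, 200, 200, 0, 100)
            assert apply_filters(boosted).passed


class TestCallVariants:
    def test_empty_input(self):
        assert len(call_variants([])) == 0

    def test_mixed_pass_and_fail(self):
        calls = call_variants([
            pileup(25, 25, 200, 200, 0, 100),  # PASS
            pileup(5, 5, 10, 9, 0, 100),  # LOW_DEPTH
        ])
        assert len(calls) == 2 and len(calls.passing()) == 1

    def test_sites_outside_panel_dropped_and_counted(self):
        panel = Panel([TargetRegion("chr1", 0, 1000)])
        calls = call_variants(
            [pileup(25, 25, 200, 200),  # pos 100, inside
             PileupRecord("chr9", 5, "A", "T", 25, 25, 200, 200, 0, 0)],
            panel=panel,
        )
        assert len(calls) == 1
        assert calls.n_outside_panel == 1
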