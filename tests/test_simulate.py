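import numpy as np
import pytest

from panelval.panel import TruthVariant
from panelval.simulate import (
    AmpliconSpec, SimConfig, downsample_pileup, simulate_coverage,
    simulate_fusion_reads, simulate_pileup, simulate_pileups, simulate_truth,
)
from panelval.snv import PileupRecord


class TestSimulateTruth:
    def test_fixed_maf(self, panel):
        cfg = SimConfig(seed=1, n_snv=10, maf_model=("fixed", 0.5))
        truth = simulate_truth(cfg, panel)
        assert len(truth) == 10
        assert all(v.true_maf == 0.5 for v in truth)
        assert all(v.var_kind == "SNV" for v in truth)

    def test_positions_unique_and_inside_panel(self, panel):
        cfg = SimConfig(seed=2, n_snv=200, n_indel=50)
        truth = simulate_truth(cfg, panel)
        assert len({(v.chrom, v.pos) for v in truth}) == 250
        assert all(panel.contains(v.chrom, v.pos) for v in truth)
        assert sum(v.var_kind == "indel" for v in truth) == 50

    def test_cellline_pool_mass_below_30pct(self, panel):
        # Monte-Carlo check of the truncated Beta(1.2, 12) spectrum: the
        # bulk of somatic MAFs in cell-line pools sits below 0.30.
        cfg = SimConfig(seed=3, n_snv=10_000, maf_model="cellline_pool")
        mafs = np.array([v.true_maf for v in simulate_truth(cfg, panel)])
        frac = float((mafs < 0.30).mean())
        assert 0.93 <= frac <= 0.99

    def test_germline_pool_spans_5_to_100(self, panel):
        cfg = SimConfig(seed=4, n_snv=5000, maf_model="germline_pool")
        mafs = np.array([v.true_maf for v in simulate_truth(cfg, panel)])
        assert mafs.min() >= 0.05 and mafs.max() <= 1.0
        assert (mafs >= 0.5).mean() > 0.3  # broad, not low-skewed

    def test_too_many_variants_rejected(self, panel):
        cfg = SimConfig(seed=5, n_snv=panel.total_span + 1)
        with pytest.raises(ValueError):
            simulate_truth(cfg, panel)

    def test_deterministic_under_seed(self, panel):
        cfg = SimConfig(seed=6, n_snv=50, n_indel=10)
        assert simulate_truth(cfg, panel) == simulate_truth(cfg, panel)


class TestSimulatePileup:
    def test_pure_variant_no_error(self):
        v = TruthVariant("chr1", 1, "A", "T", "SNV", 1.0)
        cfg = SimConfig(seed=1, error_rate=0.0)
        p = simulate_pileup(v, cfg, fixed_depth=100)
        assert p.alt == 100 and p.depth == 100
        assert p.normal_alt == 0

    def test_binomial_concentration(self):
        # alt/D within 4 sigma of 0.5 at D=10000
        v = TruthVariant("chr1", 1, "A", "T", "SNV", 0.5)
        p = simulate_pileup(v, SimConfig(seed=2), fixed_depth=10_000)
        assert 0.48 <= p.alt / p.depth <= 0.52

    def test_depth_zero(self):
        v = TruthVariant("chr1", 1, "A", "T", "SNV", 0.5)
        p = simulate_pileup(v, SimConfig(seed=3, depth=0.0))
        assert p.depth == 0 and p.alt == 0

    def test_empirical_maf_converges(self, panel):
        # law of large numbers across replicate pileups, 4 sigma bound
        v = TruthVariant("chr1", 1, "A", "T", "SNV", 0.2)
        cfg = SimConfig(seed=4, depth=200.0)
        rng = np.random.default_rng(cfg.seed)
        reps = [simulate_pileup(v, cfg, rng=rng) for _ in range(500)]
        total_alt = sum(p.alt for p in reps)
        total_depth = sum(p.depth for p in reps)
        sigma = np.sqrt(0.2 * 0.8 / total_depth)
        assert abs(total_alt / total_depth - 0.2) < 4 * sigma

    def test_reproducible(self):
        v = TruthVariant("chr1", 1, "A", "T", "SNV", 0.3)
        cfg = SimConfig(seed=5, depth=300.0)
        assert simulate_pileup(v, cfg) == simulate_pileup(v, cfg)


class TestDownsample:
    def _pileup(self, alt_fwd, alt_rev, ref_fwd, ref_rev, n_alt=0, n_depth=0):
        return PileupRecord("chr1", 1, "A", "T", alt_fwd, alt_rev,
                            ref_fwd, ref_rev, n_alt, n_depth)

    def test_full_depth_identity(self):
        p = self._pileup(10, 12, 30, 28)
        assert downsample_pileup(p, p.depth, seed=0) == p

    def test_to_zero(self):
        p = self._pileup(10, 12, 30, 28)
        d = downsample_pileup(p, 0, seed=0)
        assert d.depth == 0 and d.alt == 0

    def test_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            downsample_pileup(self._pileup(5, 5, 5, 5), 21, seed=0)

    def test_hypergeometric_mean_preserved(self):
        # mean alt fraction over many seeds equals the source fraction
        p = self._pileup(250, 250, 250, 250)  # alt=500, ref=500
        fracs = [
            downsample_pileup(p, 100, seed=s).alt / 100 for s in range(2000)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.02

    def test_normal_thinned_to_target(self):
        p = self._pileup(50, 50, 200, 200, n_alt=3, n_depth=500)
        d = downsample_pileup(p, 100, seed=1)
        assert d.normal_depth == 100 and 0 <= d.normal_alt <= 3


class TestSimulateCoverage:
    def _mean_ratio(self, panel, amplicons, purity, gene, seed=0):
        cfg = SimConfig(seed=seed, depth=20_000.0, purity=purity, n_snv=0)
        bins = simulate_coverage(panel, amplicons, cfg)
        sel = [b for b in bins if b.region.gene == gene]
        return np.mean([b.tumor_count / b.normal_count for b in sel])

    def test_zero_purity_equalizes(self, cnv_panel, amplicons):
        r = self._mean_ratio(cnv_panel, amplicons, 0.0, "CCND1")
        assert abs(r - 1.0) < 0.02

    def test_full_purity_cn4_doubles(self, cnv_panel):
        r = self._mean_ratio(cnv_panel, (AmpliconSpec("AKT1", 4),), 1.0, "AKT1")
        assert abs(r - 2.0) < 0.04

    def test_mixed_purity_closed_form(self, cnv_panel):
        # purity 0.2, CN_t 4 -> (0.2*4 + 1.6)/2 = 1.2
        r = self._mean_ratio(cnv_panel, (AmpliconSpec("AKT1", 4),), 0.2, "AKT1")
        assert abs(r - 1.2) < 0.03

    def test_unknown_gene_rejected(self, cnv_panel):
        with pytest.raises(ValueError):
            simulate_coverage(cnv_panel, (AmpliconSpec("NOPE", 4),), SimConfig())


class TestSimulateFusionReads:
    def test_split_reads_clip_at_breakpoint(self):
        pairs = simulate_fusion_reads(
            ("chr2", 1000, "+"), ("chr21", 50_000, "-"),
            n_split=3, n_discordant=0, seed=1,
        )
        assert len(pairs) == 3
        for p in pairs:
            assert p.read1.pos + p.read1.aligned_len == 1000  # clip boundary
            assert p.read1.clip_right >= 15
            assert p.read2.chrom == "chr21"

    def test_no_signal_only_background(self):
        pairs = simulate_fusion_reads(
            ("chr2", 1000, "+"), ("chr2", 5000, "-"),
            n_split=0, n_discordant=0, n_background=7, seed=2,
        )
        assert len(pairs) == 7
        assert all(p.pair_id.startswith("bg_") for p in pairs)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_fusion_reads(("chr1", 1, "+"), ("chr1", 9, "-"), n_split=-1)

    def test_reproducible(self):
        a, b = ("chr2", 1000, "+"), ("chr21", 9000, "-")
        assert simulate_fusion_reads(a, b, seed=3) == simulate_fusion_reads(a, b, seed=3)


def test_pileups_bit_reproducible(panel):
    cfg = SimConfig(seed=11, n_snv=30, depth=100.0)
    truth = simulate_truth(cfg, panel)
    assert simulate_pileups(truth, cfg) == simulate_pileups(truth, cfg)
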