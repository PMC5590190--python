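import numpy as np
import pytest

from panelval.fusion import (
    BreakpointCluster, ReadAln, ReadPairRecord, call_fusions,
    classify_rearrangement, cluster_breakpoints, detect_fusions,
    discordant_evidence, extract_clipped, read_pairs_sam, select_discordant,
    BreakpointEvidence,
)
from panelval.panel import Panel, TargetRegion
from panelval.simulate import simulate_fusion_reads

from oracles import brute_force_discordant


def pair(c1, p1, s1, c2, p2, s2, alen=100, clips1=(0, 0), clips2=(0, 0), pid="p"):
    return ReadPairRecord(
        ReadAln(c1, p1, s1, alen, *clips1),
        ReadAln(c2, p2, s2, alen, *clips2),
        pair_id=pid,
    )


class TestExtractClipped:
    def test_right_clip_breakpoint_arithmetic(self):
        p = pair("chr2", 100, "+", "chr21", 5000, "-", alen=80, clips1=(0, 20))
        (ev,) = extract_clipped([p])
        assert (ev.chrom_a, ev.pos_a, ev.strand_a) == ("chr2", 180, "+")
        assert ev.kind == "split"

    def test_left_clip_at_read_start(self):
        p = pair("chr2", 100, "-", "chr21", 5000, "+", alen=80, clips1=(25, 0))
        (ev,) = extract_clipped([p])
        assert (ev.chrom_a, ev.pos_a, ev.strand_a) == ("chr2", 100, "-")

    def test_unclipped_reads_give_nothing(self):
        assert extract_clipped([pair("chr1", 1, "+", "chr1", 300, "-")]) == []

    def test_below_min_clip_excluded(self):
        p = pair("chr1", 1, "+", "chr1", 300, "-", clips1=(0, 5))
        assert extract_clipped([p], min_clip=10) == []


class TestSelectDiscordant:
    def test_separate_chromosomes_kept(self):
        assert select_discordant([pair("chr2", 100, "+", "chr21", 100, "-")])

    def test_short_proper_pair_excluded(self):
        # span 1500 bp, +/- orientation: concordant
        p = pair("chr3", 1000, "+", "chr3", 2400, "-", alen=100)
        assert select_discordant([p]) == []

    def test_same_direction_kept_despite_short_span(self):
        p = pair("chr3", 1000, "+", "chr3", 2400, "+", alen=100)
        assert select_discordant([p]) == [p]

    def test_long_span_kept(self):
        p = pair("chr3", 1000, "+", "chr3", 3000, "-", alen=100)  # span 2100
        assert select_discordant([p]) == [p]

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        chroms = ["chr1", "chr2", "chr3"]
        kept = 0
        for _ in range(10_000):
            c1, c2 = rng.choice(chroms, size=2)
            p1, p2 = (int(x) for x in rng.integers(0, 5000, size=2))
            s1, s2 = ("+-"[rng.integers(2)], "+-"[rng.integers(2)])
            alen = int(rng.integers(50, 150))
            p = pair(c1, p1, s1, c2, p2, s2, alen=alen)
            got = bool(select_discordant([p]))
            want = brute_force_discordant(
                c1, p1, p1 + alen, s1, c2, p2, p2 + alen, s2
            )
            assert got == want
            kept += got
        assert 0 < kept < 10_000  # both outcomes exercised


class TestClustering:
    def ev(self, pa, pb, kind="split", sa="+", sb="-"):
        return BreakpointEvidence(kind, "chr2", pa, sa, "chr21", pb, sb)

    def test_nearby_evidence_forms_one_cluster(self):
        clusters = cluster_breakpoints(
            [self.ev(1000, 5000), self.ev(1004, 5003), self.ev(1010, 4998)]
        )
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.n_split == 3 and cl.pos_a == 1004

    def test_distant_junctions_split(self):
        clusters = cluster_breakpoints([self.ev(1000, 5000), self.ev(11_000, 5000)])
        assert len(clusters) == 2

    def test_orientation_separates_clusters(self):
        clusters = cluster_breakpoints(
            [self.ev(1000, 5000, sa="+"), self.ev(1001, 5001, sa="-")]
        )
        assert len(clusters) == 2

    def test_empty(self):
        assert cluster_breakpoints([]) == []


class TestClassification:
    def cluster(self, ca, cb, sa, sb, pa=1000, pb=200_000):
        return BreakpointCluster(ca, pa, sa, cb, pb, sb, n_split=3)

    def test_translocation(self):
        assert classify_rearrangement(
            self.cluster("chr2", "chr21", "+", "-")) == "translocation"

    def test_inversion_same_direction(self):
        assert classify_rearrangement(
            self.cluster("chr2", "chr2", "+", "+")) == "inversion"

    def test_long_deletion_forward_junction(self):
        assert classify_rearrangement(
            self.cluster("chr7", "chr7", "+", "-")) == "long_deletion"

    def test_tandem_duplication_reversed_junction(self):
        assert classify_rearrangement(
            self.cluster("chr7", "chr7", "-", "+")) == "tandem_duplication"


class TestCallFusions:
    def test_low_support_flagged(self, panel):
        cl = BreakpointCluster("chr2", 29_456_400, "+", "chr17", 37_840_050, "-",
                               n_split=1, n_discordant=1)
        events, _ = call_fusions([cl], panel)
        assert events[0].status == "low_support"

    def test_both_sides_outside_panel_dropped(self, panel):
        cl = BreakpointCluster("chr5", 1000, "+", "chr6", 2000, "-", n_split=10)
        events, dropped = call_fusions([cl], panel)
        assert events == [] and dropped == 1

    def test_gene_annotation_from_panel_overlap(self, panel):
        cl = BreakpointCluster("chr2", 29_456_400, "+", "chr2", 42_492_200, "+",
                               n_split=5)
        events, _ = call_fusions([cl], panel)
        assert events[0].gene_a == "ALK" and events[0].gene_b == "EML4"
        assert events[0].status == "PASS"


class TestRoundTrip:
    CASES = {
        "translocation": (("chr2", 29_456_400, "+"), ("chr17", 37_840_060, "-")),
        "inversion": (("chr2", 29_456_400, "+"), ("chr2", 42_492_100, "+")),
        "long_deletion": (("chr7", 55_240_050, "+"), ("chr7", 55_261_000, "-")),
    }

    @pytest.mark.parametrize("kind", sorted(CASES))
    def test_simulated_junction_recovered(self, panel, kind):
        """Each simulated rearrangement kind yields exactly one PASS event
        whose breakpoints sit within the clustering window of the truth."""
        a, b = self.CASES[kind]
        pairs = simulate_fusion_reads(
            a, b, n_split=5, n_discordant=6, n_background=15, seed=11
        )
        events, _ = detect_fusions(pairs, panel)
        passing = [e for e in events if e.status == "PASS"]
        assert len(passing) == 1
        ev = passing[0]
        assert ev.rearrangement_kind == kind
        sides = sorted([(ev.cluster.chrom_a, ev.cluster.pos_a),
                        (ev.cluster.chrom_b, ev.cluster.pos_b)])
        truth = sorted([(a[0], a[1]), (b[0], b[1])])
        for (gc, gp), (tc, tp) in zip(sides, truth):
            assert gc == tc and abs(gp - tp) <= 50

    def test_short_concordant_background_never_called(self, panel):
        pairs = simulate_fusion_reads(
            ("chr7", 55_240_050, "+"), ("chr7", 55_241_500, "-"),
            n_split=0, n_discordant=0, n_background=50, seed=5,
        )
        events, _ = detect_fusions(pairs, panel)
        assert events == []


def test_sam_reader_matches_tsv_semantics(tmp_path):
    sam = tmp_path / "toy.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:unknown\n"
        "@SQ\tSN:chr2\tLN:50000000\n"
        "@SQ\tSN:chr21\tLN:50000000\n"
        "p1\t0\tchr2\t101\t60\t80M20S\t=\t5001\t0\t*\t*\n"
        "p1\t16\tchr21\t5001\t60\t100M\t=\t101\t0\t*\t*\n"
    )
    (rec,) = read_pairs_sam(sam)
    r1 = rec.read1 if rec.read1.chrom == "chr2" else rec.read2
    assert r1.pos == 100 and r1.aligned_len == 80 and r1.clip_right == 20
    (ev,) = extract_clipped([rec])
    assert ev.pos_a == 180
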