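"""Small built-in panels for demonstrations, tests and simulations.

These are toy analogs of a real hybrid-capture design (hundreds of genes,
thousands of baited exons): a generic exon panel for SNV/indel work, a
copy-number panel carrying the classic 11q13 amplicon genes (CCND1, FGF3,
FGF4, FGF19) plus AKT1, and intronic baits on ALK for fusion calling.
GC fractions are assigned deterministically so GC correction is exercised
without a genome FASTA.
"""

from __future__ import annotations

import zlib

import numpy as np

from .panel import Panel, TargetRegion
from .simulate import AmpliconSpec

#: The amplified genes of the dilution fixture and their assumed tumor
#: copy numbers.  AKT1 carries the lowest amplification so it is the
#: first to fall below the detection floor as purity drops.
DILUTION_AMPLICONS = (
    AmpliconSpec("CCND1", 10),
    AmpliconSpec("FGF3", 10),
    AmpliconSpec("FGF4", 10),
    AmpliconSpec("FGF19", 10),
    AmpliconSpec("AKT1", 4),
)


def _gene_block(
    chrom: str, start: int, gene: str, n_exons: int, exon_len: int = 150,
    spacing: int = 2000, kind: str = "exon", gc_seed: int = 0,
) -> list[TargetRegion]:
    # crc32 keeps the per-gene GC draw stable across processes
    rng = np.random.default_rng(zlib.crc32(f"{gene}:{gc_seed}".encode()) % 2**31)
    out = []
    for i in range(n_exons):
        s = start + i * (exon_len + spacing)
        gc = float(np.clip(rng.normal(0.48, 0.08), 0.25, 0.75))
        out.append(TargetRegion(chrom, s, s + exon_len, gene, kind, round(gc, 4)))
    return out


def toy_panel() -> Panel:
    """General-purpose toy panel: a handful of driver genes plus ALK introns."""
    regions: list[TargetRegion] = []
    regions += _gene_block("chr7", 55_240_000, "EGFR", 10)
    regions += _gene_block("chr12", 25_360_000, "KRAS", 6)
    regions += _gene_block("chr17", 7_570_000, "TP53", 11)
    regions += _gene_block("chr17", 37_840_000, "ERBB2", 8)
    regions += _gene_block("chr2", 42_490_000, "EML4", 6)
    regions += _gene_block("chr2", 29_440_000, "ALK", 8)
    # rearrangement-prone ALK introns, baited like the exons
    regions.append(TargetRegion("chr2", 29_456_000, 29_458_500, "ALK", "intron", 0.41))
    regions.append(TargetRegion("chr2", 29_458_600, 29_460_000, "ALK", "intron", 0.44))
    return Panel(regions, name="toy")


def dilution_panel(n_neutral_genes: int = 20, exons_per_gene: int = 10) -> Panel:
    """Copy-number panel: the five amplified genes plus a neutral backbone.

    CCND1/FGF3/FGF4/FGF19 sit adjacently on chr11 (as in the 11q13
    amplicon), AKT1 on chr14; neutral genes are spread over other
    chromosomes with varied GC so GC correction has signal to estimate.
    """
    regions: list[TargetRegion] = []
    start = 69_450_000
    for gene in ("CCND1", "FGF3", "FGF4", "FGF19"):
        regions += _gene_block("chr11", start, gene, 12)
        start += 12 * 2150 + 50_000
    regions += _gene_block("chr14", 105_230_000, "AKT1", 12)
    rng = np.random.default_rng(12345)
    for g in range(n_neutral_genes):
        chrom = f"chr{1 + g % 10}"
        base = 10_000_000 + (g // 10) * 5_000_000 + (g % 10) * 1_000_000
        gene = f"NEUT{g:02d}"
        for i in range(exons_per_gene):
            s = base + i * 2150
            gc = float(np.clip(rng.uniform(0.28, 0.72), 0.0, 1.0))
            regions.append(TargetRegion(chrom, s, s + 150, gene, "exon", round(gc, 4)))
    return Panel(regions, name="dilution")
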