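"""Standard-format writers shared by all stages (VCF 4.2, BEDPE)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .snv import CallThresholds, VariantCall
from .fusion import FusionEvent

_FILTER_DESCRIPTIONS = {
    "LOW_DEPTH": "Total depth at the site below the minimum",
    "NORMAL_EVIDENCE": "Matched-normal alt fraction above the allowed maximum",
    "STRAND_BIAS": "Forward fraction of alt reads outside the accepted band",
    "LOW_MAF": "Observed MAF at or below the calling threshold",
    "REPEAT": "Indel in a repeat tract below the raised evidence requirement",
}


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    thresholds: CallThresholds | None = None,
    sample: str = "TUMOR",
) -> None:
    """Write calls as VCF 4.2 (positions converted to 1-based).

    FILTER is PASS or the sorted, semicolon-joined filter names; INFO
    carries MAF, DP, SB (forward alt fraction) and POSTERIOR.  The header
    records every threshold the cascade used.
    """
    t = thresholds or CallThresholds()
    lines = [
        "##fileformat=VCFv4.2",
        "##source=panelval",
        f"##panelval_min_depth={t.min_depth}",
        f"##panelval_max_normal_maf={t.max_normal_maf}",
        f"##panelval_maf_min={t.maf_min}",
        f"##panelval_maf_min_hotspot={t.maf_min_hotspot}",
        f"##panelval_strand_bias_band=[{t.strand_bias_low},{t.strand_bias_high}]",
        f"##panelval_repeat_rule=maf>={t.repeat_maf_min},alt>={t.repeat_min_alt}",
    ]
    for name, desc in _FILTER_DESCRIPTIONS.items():
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    lines += [
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Observed mutation allele frequency">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total deduplicated depth">',
        '##INFO=<ID=SB,Number=1,Type=Float,Description="Forward-strand fraction of alt reads">',
        '##INFO=<ID=POSTERIOR,Number=1,Type=Float,Description="Posterior probability the true allele fraction exceeds the error rate">',
        '##INFO=<ID=VK,Number=1,Type=String,Description="Variant kind (SNV or indel)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for c in calls:
            filt = "PASS" if c.passed else ";".join(sorted(c.filters))
            sb = "." if c.strand_fraction is None else f"{c.strand_fraction:.4f}"
            info = (
                f"MAF={c.observed_maf:.6f};DP={c.depth};SB={sb};"
                f"POSTERIOR={c.posterior:.6f};VK={c.var_kind}"
            )
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\t"
                f"{filt}\t{info}\n"
            )


def write_bedpe(fusions: Iterable[FusionEvent], path: str | Path) -> None:
    """Write fusion events as BEDPE (0-based half-open single-base sides)."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
            "strand1\tstrand2\tkind\tn_split\tn_discordant\tgene1\tgene2\tstatus\n"
        )
        for ev in fusions:
            cl = ev.cluster
            name = f"{ev.gene_a or '.'}--{ev.gene_b or '.'}"
            fh.write(
                f"{cl.chrom_a}\t{cl.pos_a}\t{cl.pos_a + 1}\t"
                f"{cl.chrom_b}\t{cl.pos_b}\t{cl.pos_b + 1}\t"
                f"{name}\t{cl.support}\t{cl.strand_a}\t{cl.strand_b}\t"
                f"{ev.rearrangement_kind}\t{cl.n_split}\t{cl.n_discordant}\t"
                f"{ev.gene_a or '.'}\t{ev.gene_b or '.'}\t{ev.status}\n"
            )
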