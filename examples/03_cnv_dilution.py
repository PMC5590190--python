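"""Purity-dilution limit of detection for amplification calling.

A tumor carrying CCND1/FGF3/FGF4/FGF19 at 10 copies and AKT1 at 4 copies
is mixed with matched normal DNA from 50% down to 10% tumor content.  At
each purity the full CNV pipeline runs (log2 ratio, GC correction,
BIC segmentation, purity-aware amplification calling); the printed matrix
shows which amplifications survive dilution.
"""

from panelval import dilution_lod
from panelval.toy import DILUTION_AMPLICONS, dilution_panel

panel = dilution_panel()
res = dilution_lod(panel, DILUTION_AMPLICONS, depth=800.0, seed=1)

genes = [a.gene for a in DILUTION_AMPLICONS]
print("gene    CN  " + "  ".join(f"{p:>5.0%}" for p in res.purity_grid) + "   LOD")
for spec in DILUTION_AMPLICONS:
    row = "  ".join(
        "  yes" if res.detected[(spec.gene, p)] else "    -"
        for p in res.purity_grid
    )
    lod = res.lod[spec.gene]
    lod_s = f"{lod:.0%}" if lod is not None else "none"
    print(f"{spec.gene:<6} {spec.tumor_copy_number:>3}  {row}  {lod_s:>5}")
# The high-level (10-copy) amplifications stay callable down to 20%
# tumor content; the modest 4-copy AKT1 gain is diluted below the
# detection floor already at 20% — the observed ratio falls to
# log2(1.2) ~ 0.26, indistinguishable from coverage noise.
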