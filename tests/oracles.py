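"""Independent brute-force re-implementations used as test oracles.

These are written directly from the calling rules, deliberately without
reusing any package internals, so the implementation and the oracle can
only agree by computing the same thing.
"""

from fractions import Fraction


def brute_force_filters(
    alt_fwd: int, alt_rev: int, ref_fwd: int, ref_rev: int,
    normal_alt: int, normal_depth: int,
    hotspot: bool = False, in_repeat: bool = False, is_indel: bool = False,
) -> set[str]:
    """The four published cascade rules plus the repeat rule, verbatim."""
    filters = set()
    alt = alt_fwd + alt_rev
    depth = alt + ref_fwd + ref_rev

    # total reads at the variant position may not be below 30
    if depth < 30:
        filters.add("LOW_DEPTH")

    # normal-control variant fraction at most 0.03
    if normal_depth > 0 and Fraction(normal_alt, normal_depth) > Fraction(3, 100):
        filters.add("NORMAL_EVIDENCE")

    # strand bias: forward fraction of alt reads > 0.9 or < 0.1
    if alt >= 2:
        sf = Fraction(alt_fwd, alt)
        if sf > Fraction(9, 10) or sf < Fraction(1, 10):
            filters.add("STRAND_BIAS")

    # MAF strictly above 1% (0.5% at hotspots)
    cut = Fraction(1, 200) if hotspot else Fraction(1, 100)
    if depth == 0 or Fraction(alt, depth) <= cut:
        filters.add("LOW_MAF")

    # raised requirement for indels in repeat tracts
    if is_indel and in_repeat:
        maf = Fraction(alt, depth) if depth else Fraction(0)
        if maf < Fraction(2, 100) or alt < 8:
            filters.add("REPEAT")

    return filters


def brute_force_discordant(
    chrom1: str, pos1: int, end1: int, strand1: str,
    chrom2: str, pos2: int, end2: int, strand2: str,
    max_span: int = 2000,
) -> bool:
    """Disjunction of the three selection rules, verbatim."""
    if chrom1 != chrom2:
        return True  # mates on separate chromosomes
    if max(end1, end2) - min(pos1, pos2) > max_span:
        return True  # at a distance of over 2 kb
    return strand1 == strand2  # aligned in the same direction
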