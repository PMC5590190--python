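"""Synthetic inputs for every pipeline stage.

The generator emulates the bench materials a targeted-panel validation
uses: pooled germline DNA whose SNP allele fractions span 5–100%, cancer
cell-line pools whose somatic MAF spectrum is concentrated below 30%,
stranded tumor/normal pileups at configurable depth, tumor/normal coverage
with purity mixing and GC bias, and read-pair evidence around rearrangement
junctions.  Everything is bit-reproducible given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .panel import Panel, TruthVariant
from .snv import PileupRecord
from .fusion import ReadAln, ReadPairRecord

_BASES = np.array(list("ACGT"))

# MAF models:
#   "germline_pool"      — uniform over pooled-heterozygote fractions
#                          k/20, k = 1..20 (5%..100%)
#   "cellline_pool"      — Beta(1.2, 12) truncated to [0.01, 1]; ~97.5% of
#                          mass below MAF 0.30, like somatic spectra of
#                          cancer cell-line pools
#   ("uniform", lo, hi)  — uniform on [lo, hi)
#   ("fixed", m)         — constant
MafModel = str | tuple

CELLLINE_BETA_A = 1.2
CELLLINE_BETA_B = 12.0
CELLLINE_MAF_FLOOR = 0.01


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment."""

    seed: int = 0
    n_snv: int = 100
    n_indel: int = 0
    maf_model: MafModel = "cellline_pool"
    depth: float = 500.0  # mean coverage (x)
    error_rate: float = 0.001  # background alt fraction (matched normal)
    strand_prob: float = 0.5  # expected forward-strand fraction
    purity: float = 1.0  # tumor fraction

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must be in [0, 0.01)")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class AmpliconSpec:
    """A gene amplified in the simulated tumor."""

    gene: str
    tumor_copy_number: int

    def __post_init__(self) -> None:
        if self.tumor_copy_number < 2:
            raise ValueError("tumor_copy_number must be >= 2")


def _draw_mafs(model: MafModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if model == "germline_pool":
        # pool of 10 diploid lines: a het SNP shared by k lines sits at k/20
        return rng.integers(1, 21, size=n) / 20.0
    if model == "cellline_pool":
        m = rng.beta(CELLLINE_BETA_A, CELLLINE_BETA_B, size=n)
        # truncate by redrawing below the floor
        low = m < CELLLINE_MAF_FLOOR
        while low.any():
            m[low] = rng.beta(CELLLINE_BETA_A, CELLLINE_BETA_B, size=int(low.sum()))
            low = m < CELLLINE_MAF_FLOOR
        return np.minimum(m, 1.0)
    if isinstance(model, tuple) and model[0] == "uniform":
        _, lo, hi = model
        return rng.uniform(lo, hi, size=n)
    if isinstance(model, tuple) and model[0] == "fixed":
        return np.full(n, float(model[1]))
    raise ValueError(f"unknown maf_model {model!r}")


def simulate_truth(config: SimConfig, panel: Panel) -> list[TruthVariant]:
    """Place SNV/indel truth variants uniformly over panel bases.

    Positions are drawn without replacement across the panel footprint;
    MAFs follow ``config.maf_model``.  A tenth of indels are flagged as
    repeat-tract sites to exercise the raised repeat requirement.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    n_total = config.n_snv + config.n_indel
    span = panel.total_span
    if n_total > span:
        raise ValueError(f"{n_total} variants exceed panel footprint of {span} bases")

    rng = np.random.default_rng(config.seed)
    offsets = rng.choice(span, size=n_total, replace=False)
    offsets.sort()

    # map flat offsets back to (chrom, pos)
    sites: list[tuple[str, int]] = []
    bounds = np.cumsum([r.length for r in panel.regions])
    region_idx = np.searchsorted(bounds, offsets, side="right")
    for off, ridx in zip(offsets, region_idx):
        r = panel.regions[int(ridx)]
        prev = 0 if ridx == 0 else int(bounds[ridx - 1])
        sites.append((r.chrom, r.start + int(off) - prev))

    mafs = _draw_mafs(config.maf_model, n_total, rng)
    kind_is_indel = np.zeros(n_total, dtype=bool)
    if config.n_indel:
        kind_is_indel[rng.choice(n_total, size=config.n_indel, replace=False)] = True

    variants: list[TruthVariant] = []
    for i, ((chrom, pos), maf) in enumerate(zip(sites, mafs)):
        ref = str(rng.choice(_BASES))
        if kind_is_indel[i]:
            if rng.random() < 0.5:  # insertion
                ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
                alt = ref + ins
            else:  # deletion represented as anchored multi-base ref
                tail = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
                ref, alt = ref + tail, ref
            kind = "indel"
            in_repeat = bool(rng.random() < 0.1)
        else:
            alt = str(rng.choice(_BASES[_BASES != ref]))
            kind = "SNV"
            in_repeat = False
        variants.append(
            TruthVariant(chrom, pos, ref, alt, kind, float(maf), in_repeat=in_repeat)
        )
    return variants


def simulate_pileup(
    variant: TruthVariant,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    fixed_depth: int | None = None,
) -> PileupRecord:
    """Sample one stranded tumor/normal pileup for a truth variant.

    Tumor depth is Poisson around ``config.depth`` (or fixed when
    ``fixed_depth`` is given), alt reads are Binomial(depth, true_maf)
    with a Binomial(alt, strand_prob) forward split; the matched normal is
    generated the same way with the background error rate in place of the
    true MAF.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    d = int(fixed_depth) if fixed_depth is not None else int(rng.poisson(config.depth))
    alt = int(rng.binomial(d, variant.true_maf)) if d else 0
    ref = d - alt
    alt_fwd = int(rng.binomial(alt, config.strand_prob)) if alt else 0
    ref_fwd = int(rng.binomial(ref, config.strand_prob)) if ref else 0
    nd = int(fixed_depth) if fixed_depth is not None else int(rng.poisson(config.depth))
    n_alt = int(rng.binomial(nd, config.error_rate)) if nd else 0
    return PileupRecord(
        chrom=variant.chrom, pos=variant.pos,
        ref_allele=variant.ref_allele, alt_allele=variant.alt_allele,
        alt_fwd=alt_fwd, alt_rev=alt - alt_fwd,
        ref_fwd=ref_fwd, ref_rev=ref - ref_fwd,
        normal_alt=n_alt, normal_depth=nd,
    )


def simulate_pileups(
    variants: Sequence[TruthVariant], config: SimConfig
) -> list[PileupRecord]:
    rng = np.random.default_rng(config.seed)
    return [simulate_pileup(v, config, rng=rng) for v in variants]


def downsample_pileup(
    pileup: PileupRecord, target_depth: int, seed: int | np.random.Generator
) -> PileupRecord:
    """Draw ``target_depth`` reads without replacement from a pileup.

    The draw is hypergeometric — first alt vs ref, then forward vs reverse
    within each class — so the expected MAF is preserved exactly.  The
    matched normal is thinned to the same target when it is at least that
    deep.
    """
    d = pileup.depth
    if target_depth > d:
        raise ValueError(f"target depth {target_depth} exceeds pileup depth {d}")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if target_depth == d:
        new_alt, new_ref = pileup.alt, d - pileup.alt
        alt_fwd, ref_fwd = pileup.alt_fwd, pileup.ref_fwd
    else:
        new_alt = int(rng.hypergeometric(pileup.alt, d - pileup.alt, target_depth)) \
            if target_depth else 0
        new_ref = target_depth - new_alt
        alt_fwd = int(rng.hypergeometric(pileup.alt_fwd, pileup.alt_rev, new_alt)) \
            if new_alt else 0
        ref_fwd = int(rng.hypergeometric(pileup.ref_fwd, pileup.ref_rev, new_ref)) \
            if new_ref else 0
    if pileup.normal_depth >= target_depth and pileup.normal_depth > 0:
        n_alt = int(
            rng.hypergeometric(
                pileup.normal_alt, pileup.normal_depth - pileup.normal_alt,
                target_depth,
            )
        ) if target_depth else 0
        n_depth = target_depth
    else:
        n_alt, n_depth = pileup.normal_alt, pileup.normal_depth
    return replace(
        pileup,
        alt_fwd=alt_fwd, alt_rev=new_alt - alt_fwd,
        ref_fwd=ref_fwd, ref_rev=new_ref - ref_fwd,
        normal_alt=n_alt, normal_depth=n_depth,
    )


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def gc_weight(gc: float | np.ndarray) -> float | np.ndarray:
    """Unimodal capture-efficiency weight, maximal at GC 0.5."""
    return 1.0 - 2.0 * (np.asarray(gc) - 0.5) ** 2


def simulate_coverage(
    panel: Panel,
    amplicons: Sequence[AmpliconSpec],
    config: SimConfig,
    gc_decouple: bool = False,
):
    """Paired tumor/normal Poisson read counts per panel region.

    The expected tumor count per bin is
    ``depth * (purity*CN_t + 2*(1-purity))/2 * gc_weight(gc)`` with CN_t
    from the amplicon specs (2 elsewhere); the normal uses CN 2 under the
    same GC weight, so GC bias cancels in the tumor/normal ratio unless
    ``gc_decouple`` leaves the normal unbiased (to exercise GC correction).
    Returns a list of :class:`panelval.cnv.CoverageBin`.
    """
    from .cnv import CoverageBin  # local import to avoid a cycle

    panel_genes = set(panel.genes())
    cn_by_gene = {}
    for spec in amplicons:
        if spec.gene not in panel_genes:
            raise ValueError(f"amplicon gene {spec.gene!r} absent from panel")
        cn_by_gene[spec.gene] = spec.tumor_copy_number

    rng = np.random.default_rng(config.seed)
    p = config.purity
    bins: list[CoverageBin] = []
    for r in panel.regions:
        gc = 0.5 if r.gc_fraction is None else r.gc_fraction
        w = float(gc_weight(gc))
        cn_t = cn_by_gene.get(r.gene, 2)
        mix = (p * cn_t + 2.0 * (1.0 - p)) / 2.0
        mu_t = config.depth * mix * w
        mu_n = config.depth * (1.0 if gc_decouple else w)
        bins.append(
            CoverageBin(
                region=r,
                tumor_count=int(rng.poisson(mu_t)),
                normal_count=int(rng.poisson(mu_n)),
            )
        )
    return bins


# ---------------------------------------------------------------------------
# rearrangement read pairs
# ---------------------------------------------------------------------------

def simulate_fusion_reads(
    break_a: tuple[str, int, str],
    break_b: tuple[str, int, str],
    n_split: int = 5,
    n_discordant: int = 5,
    n_background: int = 0,
    read_len: int = 100,
    insert_mean: int = 300,
    min_clip: int = 15,
    seed: int | np.random.Generator = 0,
) -> list[ReadPairRecord]:
    """Construct read pairs supporting a junction between two breakpoints.

    Split pairs carry one read soft-clipped exactly at breakpoint A (clip
    length >= ``min_clip``) with its mate anchored tightly at breakpoint B;
    discordant pairs have fully aligned mates flanking the junction.
    Breakpoint strands follow junction geometry: '+' means the joined
    segment extends leftward of the breakpoint (the read's 3' end abuts
    the junction), '-' the reverse.  Background pairs are concordant
    (+/- within the insert size) and must not survive discordant
    selection.
    """
    if min(n_split, n_discordant, n_background) < 0:
        raise ValueError("read-pair counts must be non-negative")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chrom_a, pos_a, strand_a = break_a
    chrom_b, pos_b, strand_b = break_b
    pairs: list[ReadPairRecord] = []

    def anchored_read(chrom: str, bp: int, strand: str, clipped: bool) -> ReadAln:
        aligned = int(rng.integers(max(30, read_len - 60), read_len - min_clip + 1)) \
            if clipped else read_len
        clip = read_len - aligned if clipped else 0
        if strand == "+":
            # junction at the read's right end
            start = bp - aligned
            return ReadAln(chrom, start, strand, aligned, clip_left=0, clip_right=clip)
        start = bp
        return ReadAln(chrom, start, strand, aligned, clip_left=clip, clip_right=0)

    def mate_read(chrom: str, bp: int, strand: str) -> ReadAln:
        # fully aligned, tight to its breakpoint so clusters stay compact
        jitter = int(rng.integers(0, 25))
        if strand == "+":
            start = bp - read_len - jitter
        else:
            start = bp + jitter
        return ReadAln(chrom, start, strand, read_len, 0, 0)

    k = 0
    for _ in range(n_split):
        pairs.append(ReadPairRecord(
            read1=anchored_read(chrom_a, pos_a, strand_a, clipped=True),
            read2=mate_read(chrom_b, pos_b, strand_b),
            pair_id=f"split_{k}",
        ))
        k += 1
    for _ in range(n_discordant):
        pairs.append(ReadPairRecord(
            read1=mate_read(chrom_a, pos_a, strand_a),
            read2=mate_read(chrom_b, pos_b, strand_b),
            pair_id=f"disc_{k}",
        ))
        k += 1
    for _ in range(n_background):
        start = int(rng.integers(0, 10_000_000))
        gap = int(rng.integers(0, max(1, insert_mean - 2 * read_len + 1)))
        pairs.append(ReadPairRecord(
            read1=ReadAln(chrom_a, start, "+", read_len, 0, 0),
            read2=ReadAln(chrom_a, start + read_len + gap, "-", read_len, 0, 0),
            pair_id=f"bg_{k}",
        ))
        k += 1
    return pairs
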