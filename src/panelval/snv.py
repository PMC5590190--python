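"""SNV/indel calling from tumor/normal pileup counts.

The caller is a cascade of four published-style threshold filters — minimum
depth, matched-normal contamination, strand bias, and a MAF cut-off relaxed
at hotspots — plus an advisory beta-binomial posterior that scores how
likely the site's true allele fraction exceeds the background error rate.
All threshold comparisons are made on exact rationals so that boundary
cases (a MAF of exactly 1%, a normal fraction of exactly 0.03) behave
identically regardless of depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import beta as _beta_dist

from .panel import Panel

# filter names, one per cascade rule
LOW_DEPTH = "LOW_DEPTH"
NORMAL_EVIDENCE = "NORMAL_EVIDENCE"
STRAND_BIAS = "STRAND_BIAS"
LOW_MAF = "LOW_MAF"
REPEAT = "REPEAT"


class PileupError(ValueError):
    pass


def _frac(x: float) -> Fraction:
    """Exact rational for a decimal threshold (0.03 -> 3/100, not the float)."""
    return Fraction(str(x))


@dataclass(frozen=True)
class PileupRecord:
    """Stranded allele counts at one site for tumor plus matched normal.

    This is the caller's sole evidence unit: read-level detail (qualities,
    alignments) is assumed to have been reduced to deduplicated counts
    upstream.
    """

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    normal_alt: int = 0
    normal_depth: int = 0

    def __post_init__(self) -> None:
        for name in ("alt_fwd", "alt_rev", "ref_fwd", "ref_rev",
                     "normal_alt", "normal_depth"):
            if getattr(self, name) < 0:
                raise PileupError(f"{name} is negative")
        if self.normal_alt > self.normal_depth:
            raise PileupError("normal_alt exceeds normal_depth")

    @property
    def alt(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def depth(self) -> int:
        return self.alt_fwd + self.alt_rev + self.ref_fwd + self.ref_rev

    @property
    def var_kind(self) -> str:
        return "SNV" if len(self.ref_allele) == len(self.alt_allele) else "indel"


@dataclass(frozen=True)
class CallThresholds:
    """The filter-cascade thresholds.

    Defaults encode the cascade as published for the panel this package
    emulates: depth >= 30 reads; normal-control alt fraction at most 0.03;
    alt-read forward fraction within [0.1, 0.9]; MAF strictly above 1%
    (0.5% at hotspots).  Indels flagged as lying in repeat tracts face an
    empirically raised requirement, quantified here as MAF >= 2% and >= 8
    supporting reads.
    """

    min_depth: int = 30
    max_normal_maf: float = 0.03
    maf_min: float = 0.01
    maf_min_hotspot: float = 0.005
    strand_bias_low: float = 0.1
    strand_bias_high: float = 0.9
    repeat_maf_min: float = 0.02
    repeat_min_alt: int = 8
    min_alt_for_strand_test: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.maf_min_hotspot <= self.maf_min < 1:
            raise ValueError("need 0 < maf_min_hotspot <= maf_min < 1")
        if not self.strand_bias_low < self.strand_bias_high:
            raise ValueError("need strand_bias_low < strand_bias_high")


@dataclass
class VariantCall:
    """One scored, filter-annotated candidate call."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    observed_maf: float
    depth: int
    strand_fraction: float | None
    posterior: float
    filters: frozenset[str]
    var_kind: str = "SNV"

    @property
    def passed(self) -> bool:
        return not self.filters


def observed_maf(pileup: PileupRecord) -> Fraction:
    """Alt-read fraction of the tumor pileup, as an exact rational."""
    if pileup.depth == 0:
        raise PileupError("MAF undefined at depth 0")
    return Fraction(pileup.alt, pileup.depth)


def strand_fraction(pileup: PileupRecord) -> Fraction:
    """Fraction of alt reads on the forward strand."""
    if pileup.alt == 0:
        raise PileupError("strand fraction undefined with no alt reads")
    return Fraction(pileup.alt_fwd, pileup.alt)


def posterior_variant_prob(
    pileup: PileupRecord,
    error_rate: float = 0.01,
    hotspot: bool = False,
    prior: tuple[float, float] = (1.0, 99.0),
    hotspot_prior: tuple[float, float] = (5.0, 95.0),
) -> float:
    """P(true allele fraction > error_rate) under a beta-binomial model.

    The allele fraction carries a Beta(a, b) prior (a larger `a` at
    hotspots encodes the raised prior expectation of mutation there); the
    posterior after observing `alt` of `depth` reads is
    Beta(a + alt, b + depth - alt), and the returned probability is its
    upper tail beyond the background error rate.  The score is advisory:
    it is reported with each call but the cascade's gates are the four
    threshold filters.
    """
    if pileup.depth == 0:
        raise PileupError("posterior undefined at depth 0")
    a, b = hotspot_prior if hotspot else prior
    return float(
        _beta_dist.sf(error_rate, a + pileup.alt, b + pileup.depth - pileup.alt)
    )


def apply_filters(
    pileup: PileupRecord,
    thresholds: CallThresholds | None = None,
    hotspot: bool = False,
    in_repeat: bool = False,
) -> VariantCall:
    """Run the full filter cascade on one pileup.

    Filter semantics (each boundary is deliberate):

    * ``LOW_DEPTH``        — tumor depth < min_depth (depth == 30 passes);
    * ``NORMAL_EVIDENCE``  — normal alt fraction strictly above 0.03 (the
      stated maximum is itself allowed);
    * ``STRAND_BIAS``      — forward fraction of alt reads > 0.9 or < 0.1,
      tested only when at least 2 alt reads exist (a single read is always
      at 0 or 1);
    * ``LOW_MAF``          — observed MAF <= 1% (<= 0.5% at hotspots): the
      cut is strict, a MAF of exactly the threshold is filtered;
    * ``REPEAT``           — indels in repeat tracts additionally require
      MAF >= repeat_maf_min and alt reads >= repeat_min_alt.
    """
    t = thresholds or CallThresholds()
    filters: set[str] = set()

    depth = pileup.depth
    if depth < t.min_depth:
        filters.add(LOW_DEPTH)

    if pileup.normal_depth > 0:
        normal_maf = Fraction(pileup.normal_alt, pileup.normal_depth)
        if normal_maf > _frac(t.max_normal_maf):
            filters.add(NORMAL_EVIDENCE)

    sf: Fraction | None = None
    if pileup.alt >= t.min_alt_for_strand_test:
        sf = strand_fraction(pileup)
        if sf > _frac(t.strand_bias_high) or sf < _frac(t.strand_bias_low):
            filters.add(STRAND_BIAS)
    elif pileup.alt > 0:
        sf = strand_fraction(pileup)

    maf = observed_maf(pileup) if depth > 0 else Fraction(0)
    maf_cut = _frac(t.maf_min_hotspot if hotspot else t.maf_min)
    if depth == 0 or maf <= maf_cut:
        filters.add(LOW_MAF)

    if in_repeat and pileup.var_kind == "indel":
        if maf < _frac(t.repeat_maf_min) or pileup.alt < t.repeat_min_alt:
            filters.add(REPEAT)

    posterior = (
        posterior_variant_prob(pileup, hotspot=hotspot) if depth > 0 else 0.0
    )
    return VariantCall(
        chrom=pileup.chrom,
        pos=pileup.pos,
        ref_allele=pileup.ref_allele,
        alt_allele=pileup.alt_allele,
        observed_maf=float(maf),
        depth=depth,
        strand_fraction=None if sf is None else float(sf),
        posterior=posterior,
        filters=frozenset(filters),
        var_kind=pileup.var_kind,
    )


@dataclass
class CallSet:
    calls: list[VariantCall]
    n_outside_panel: int = 0

    def passing(self) -> list[VariantCall]:
        return [c for c in self.calls if c.passed]

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def call_variants(
    pileups: Iterable[PileupRecord],
    thresholds: CallThresholds | None = None,
    hotspot_test=None,
    repeat_sites: set[tuple[str, int]] | None = None,
    panel: Panel | None = None,
) -> CallSet:
    """Run the cascade over a pileup collection.

    Sites outside the panel (when one is given) are dropped and counted,
    mirroring calling restricted to the targeted regions.  ``hotspot_test``
    is a predicate (chrom, pos, ref, alt) -> bool, typically built with
    :func:`panelval.panel.hotspot_lookup`.
    """
    repeat_sites = repeat_sites or set()
    calls: list[VariantCall] = []
    dropped = 0
    for p in pileups:
        if panel is not None and not panel.contains(p.chrom, p.pos):
            dropped += 1
            continue
        hs = bool(hotspot_test(p.chrom, p.pos, p.ref_allele, p.alt_allele)) \
            if hotspot_test else False
        rep = (p.chrom, p.pos) in repeat_sites
        calls.append(apply_filters(p, thresholds, hotspot=hs, in_repeat=rep))
    return CallSet(calls, n_outside_panel=dropped)


# ---------------------------------------------------------------------------
# pileup TSV I/O
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "alt_fwd", "alt_rev", "ref_fwd", "ref_rev",
    "normal_alt", "normal_depth",
]


def read_pileups(path: str | Path) -> list[PileupRecord]:
    out: list[PileupRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            f = line.split("\t")
            out.append(
                PileupRecord(
                    chrom=f[0], pos=int(f[1]), ref_allele=f[2], alt_allele=f[3],
                    alt_fwd=int(f[4]), alt_rev=int(f[5]),
                    ref_fwd=int(f[6]), ref_rev=int(f[7]),
                    normal_alt=int(f[8]), normal_depth=int(f[9]),
                )
            )
    return out


def write_pileups(pileups: Iterable[PileupRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        for p in pileups:
            fh.write(
                f"{p.chrom}\t{p.pos}\t{p.ref_allele}\t{p.alt_allele}\t"
                f"{p.alt_fwd}\t{p.alt_rev}\t{p.ref_fwd}\t{p.ref_rev}\t"
                f"{p.normal_alt}\t{p.normal_depth}\n"
            )
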