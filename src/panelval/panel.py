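"""Capture-panel data model: target regions, hotspot catalog, truth sets.

All coordinates are 0-based half-open (BED convention) in memory; readers
convert from the 1-based conventions of their file formats where needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

VALID_BASES = frozenset("ACGT")
_CHROM_NUM = re.compile(r"^chr(\d+)$")


class PanelFormatError(ValueError):
    """Raised when a panel/hotspot/truth file cannot be parsed or validated."""


def _chrom_key(chrom: str) -> tuple:
    """Natural sort key: chr1 < chr2 < ... < chr10 < chrX."""
    m = _CHROM_NUM.match(chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class TargetRegion:
    """One baited target (exon or rearrangement-prone intron)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    gene: str = "."
    region_kind: str = "exon"
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelFormatError(
                f"region {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.gc_fraction is not None and not 0.0 <= self.gc_fraction <= 1.0:
            raise PanelFormatError(f"gc_fraction {self.gc_fraction} outside [0,1]")
        if self.region_kind not in ("exon", "intron"):
            raise PanelFormatError(f"unknown region_kind {self.region_kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class Panel:
    """Ordered, validated collection of target regions.

    Regions are kept sorted by (chromosome, start); overlapping regions on
    the same chromosome are rejected so that bin arithmetic downstream is
    unambiguous.
    """

    regions: list[TargetRegion]
    name: str = "panel"

    def __post_init__(self) -> None:
        self.regions = sorted(
            self.regions, key=lambda r: (_chrom_key(r.chrom), r.start)
        )
        prev: TargetRegion | None = None
        for r in self.regions:
            if prev is not None and prev.chrom == r.chrom and r.start < prev.end:
                raise PanelFormatError(
                    f"overlapping regions {prev.chrom}:{prev.start}-{prev.end} "
                    f"and {r.chrom}:{r.start}-{r.end}"
                )
            prev = r
        if self.total_span <= 0:
            raise PanelFormatError("panel has zero total span")

    @property
    def total_span(self) -> int:
        return sum(r.length for r in self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def contains(self, chrom: str, pos: int) -> bool:
        """Half-open membership test used by every calling stage."""
        return self.region_at(chrom, pos) is not None

    def region_at(self, chrom: str, pos: int) -> TargetRegion | None:
        for r in self.regions:
            if r.contains(chrom, pos):
                return r
        return None

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            if r.gene != ".":
                seen.setdefault(r.gene, None)
        return list(seen)


@dataclass(frozen=True)
class HotspotSite:
    """A recurrently mutated site granted the relaxed MAF threshold."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or not set(allele) <= VALID_BASES:
                raise PanelFormatError(f"invalid allele {allele!r}")


@dataclass(frozen=True)
class TruthVariant:
    """Declared ground-truth alteration with its true allele fraction."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    var_kind: str  # "SNV" | "indel"
    true_maf: float
    is_hotspot: bool = False
    in_repeat: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.true_maf <= 1.0:
            raise PanelFormatError(f"true_maf {self.true_maf} outside (0,1]")
        if self.var_kind not in ("SNV", "indel"):
            raise PanelFormatError(f"unknown var_kind {self.var_kind!r}")
        equal_len = len(self.ref_allele) == len(self.alt_allele)
        if self.var_kind == "SNV" and not equal_len:
            raise PanelFormatError("SNV alleles must have equal length")
        if self.var_kind == "indel" and equal_len:
            raise PanelFormatError("indel alleles must differ in length")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_panel_bed(path: str | Path, name: str | None = None) -> Panel:
    """Read a BED3+ panel file.

    Columns beyond chrom/start/end are interpreted, in order, as gene
    symbol, region kind (exon/intron) and GC fraction; missing GC is left
    unset for later annotation.
    """
    path = Path(path)
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelFormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            gene = fields[3] if len(fields) > 3 and fields[3] else "."
            kind = fields[4] if len(fields) > 4 and fields[4] else "exon"
            gc = float(fields[5]) if len(fields) > 5 and fields[5] not in ("", ".") else None
            try:
                regions.append(
                    TargetRegion(fields[0], start, end, gene, kind, gc)
                )
            except PanelFormatError as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
    return Panel(regions, name=name or path.stem)


def write_panel_bed(panel: Panel, path: str | Path) -> None:
    """Write a panel back to BED; round-trips coordinates bit-exactly."""
    with open(path, "w") as fh:
        for r in panel:
            gc = "" if r.gc_fraction is None else f"\t{r.gc_fraction:.6g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t{r.region_kind}{gc}\n")


def read_hotspots(path: str | Path) -> list[HotspotSite]:
    """Read a hotspot TSV (chrom, pos 1-based, ref, alt); dedups rows."""
    path = Path(path)
    seen: dict[HotspotSite, None] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelFormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                pos1 = int(fields[1])
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: non-integer pos") from exc
            try:
                site = HotspotSite(fields[0], pos1 - 1, fields[2], fields[3])
            except PanelFormatError as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
            seen.setdefault(site, None)
    return list(seen)


def read_truth(path: str | Path) -> list[TruthVariant]:
    """Read a truth-set TSV (chrom, pos 0-based, ref, alt, kind, true_maf,
    is_hotspot, in_repeat)."""
    path = Path(path)
    out: list[TruthVariant] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("chrom\t"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise PanelFormatError(f"{path}:{lineno}: expected >=6 columns")
            out.append(
                TruthVariant(
                    chrom=f[0],
                    pos=int(f[1]),
                    ref_allele=f[2],
                    alt_allele=f[3],
                    var_kind=f[4],
                    true_maf=float(f[5]),
                    is_hotspot=len(f) > 6 and f[6] in ("1", "True", "true"),
                    in_repeat=len(f) > 7 and f[7] in ("1", "True", "true"),
                )
            )
    return out


def write_truth(variants: Iterable[TruthVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tkind\ttrue_maf\tis_hotspot\tin_repeat\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t{v.var_kind}"
                f"\t{v.true_maf:.6g}\t{int(v.is_hotspot)}\t{int(v.in_repeat)}\n"
            )


def annotate_gc(
    panel: Panel, sequence_source: Callable[[TargetRegion], str]
) -> Panel:
    """Fill gc_fraction on each region from a per-region sequence provider."""
    annotated: list[TargetRegion] = []
    for r in panel:
        seq = sequence_source(r).upper()
        if len(seq) != r.length:
            raise PanelFormatError(
                f"sequence length {len(seq)} != region length {r.length} "
                f"for {r.chrom}:{r.start}-{r.end}"
            )
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        annotated.append(replace(r, gc_fraction=gc))
    return Panel(annotated, name=panel.name)


def hotspot_lookup(
    hotspots: Sequence[HotspotSite], positional_only: bool = False
) -> Callable[[str, int, str, str], bool]:
    """Membership predicate over a hotspot catalog.

    Exact (chrom, pos, ref, alt) matching by default; ``positional_only``
    relaxes to (chrom, pos).
    """
    if positional_only:
        keys = {(h.chrom, h.pos) for h in hotspots}
        return lambda chrom, pos, ref, alt: (chrom, pos) in keys
    full = {(h.chrom, h.pos, h.ref_allele, h.alt_allele) for h in hotspots}
    return lambda chrom, pos, ref, alt: (chrom, pos, ref, alt) in full
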