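"""Rearrangement detection from clipped reads and discordant pairs.

Evidence comes in two flavours: a soft-clipped (split) read whose clip
boundary pins a breakpoint to the base, and a discordant pair whose mates
straddle the junction.  A pair is discordant when its mates map to
different chromosomes, span more than the concordant limit (2 kb) on one
chromosome, or align in the same direction.  Evidence is clustered by
junction, classified geometrically (translocation / inversion / long
deletion / tandem duplication) and restricted to junctions with at least
one side inside the baited panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import median_low
from typing import Iterable, Sequence

from .panel import Panel, _chrom_key

MAX_CONCORDANT_SPAN = 2000  # bp; pairs wider than this are rearrangement evidence


@dataclass(frozen=True)
class ReadAln:
    """Simplified alignment of a single read."""

    chrom: str
    pos: int  # 0-based leftmost aligned base
    strand: str  # '+' | '-'
    aligned_len: int
    clip_left: int = 0
    clip_right: int = 0

    def __post_init__(self) -> None:
        if self.aligned_len <= 0:
            raise ValueError("aligned_len must be positive")
        if self.clip_left < 0 or self.clip_right < 0:
            raise ValueError("clip lengths must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.pos + self.aligned_len

    @property
    def junction_side(self) -> int:
        """The breakpoint-proximal coordinate: right end on '+', start on '-'."""
        return self.end if self.strand == "+" else self.pos


@dataclass(frozen=True)
class ReadPairRecord:
    read1: ReadAln
    read2: ReadAln
    pair_id: str = ""


@dataclass(frozen=True)
class BreakpointEvidence:
    """One junction observation with canonically ordered sides."""

    kind: str  # "split" | "discordant"
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    pair_id: str = ""


def _make_evidence(kind: str, side1, side2, pair_id: str) -> BreakpointEvidence:
    # canonical side order by (chromosome, position)
    k1 = (_chrom_key(side1[0]), side1[1])
    k2 = (_chrom_key(side2[0]), side2[1])
    a, b = (side1, side2) if k1 <= k2 else (side2, side1)
    return BreakpointEvidence(kind, a[0], a[1], a[2], b[0], b[1], b[2], pair_id)


@dataclass
class BreakpointCluster:
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    n_split: int = 0
    n_discordant: int = 0

    @property
    def support(self) -> int:
        return self.n_split + self.n_discordant


@dataclass
class FusionEvent:
    cluster: BreakpointCluster
    rearrangement_kind: str
    gene_a: str | None
    gene_b: str | None
    status: str  # "PASS" | "low_support"


# ---------------------------------------------------------------------------
# evidence extraction
# ---------------------------------------------------------------------------

def extract_clipped(
    pairs: Iterable[ReadPairRecord], min_clip: int = 10
) -> list[BreakpointEvidence]:
    """Split-read evidence: one record per read clipped by >= min_clip bp.

    A left clip marks a junction at the read start ('-' orientation: the
    partner segment lies to the left); a right clip marks it at
    pos + aligned_len ('+').  The mate's junction-proximal coordinate
    approximates the other side.
    """
    if min_clip < 1:
        raise ValueError("min_clip must be >= 1")
    out: list[BreakpointEvidence] = []
    for pair in pairs:
        for read, mate in ((pair.read1, pair.read2), (pair.read2, pair.read1)):
            if read.clip_right >= min_clip:
                side = (read.chrom, read.end, "+")
            elif read.clip_left >= min_clip:
                side = (read.chrom, read.pos, "-")
            else:
                continue
            mate_side = (mate.chrom, mate.junction_side, mate.strand)
            out.append(_make_evidence("split", side, mate_side, pair.pair_id))
    return out


def is_discordant(
    pair: ReadPairRecord, max_concordant_span: int = MAX_CONCORDANT_SPAN
) -> bool:
    r1, r2 = pair.read1, pair.read2
    if r1.chrom != r2.chrom:
        return True
    span = max(r1.end, r2.end) - min(r1.pos, r2.pos)
    if span > max_concordant_span:
        return True
    return r1.strand == r2.strand


def select_discordant(
    pairs: Iterable[ReadPairRecord],
    max_concordant_span: int = MAX_CONCORDANT_SPAN,
) -> list[ReadPairRecord]:
    """Keep pairs mapping across chromosomes, wider than the concordant
    span, or aligned in the same direction."""
    return [p for p in pairs if is_discordant(p, max_concordant_span)]


def discordant_evidence(
    pairs: Iterable[ReadPairRecord],
) -> list[BreakpointEvidence]:
    return [
        _make_evidence(
            "discordant",
            (p.read1.chrom, p.read1.junction_side, p.read1.strand),
            (p.read2.chrom, p.read2.junction_side, p.read2.strand),
            p.pair_id,
        )
        for p in pairs
    ]


# ---------------------------------------------------------------------------
# clustering / classification / calling
# ---------------------------------------------------------------------------

def cluster_breakpoints(
    evidence: Iterable[BreakpointEvidence], window: int = 50
) -> list[BreakpointCluster]:
    """Single-linkage clustering of junction evidence.

    Evidence sharing chromosomes and orientations on both sides is chained
    when consecutive (sorted) observations agree within ``window`` bp on
    both sides; cluster coordinates are the per-side medians.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    groups: dict[tuple, list[BreakpointEvidence]] = {}
    for ev in evidence:
        groups.setdefault(
            (ev.chrom_a, ev.strand_a, ev.chrom_b, ev.strand_b), []
        ).append(ev)

    clusters: list[BreakpointCluster] = []
    for key in sorted(groups, key=lambda k: (_chrom_key(k[0]), _chrom_key(k[2]), k)):
        members = sorted(groups[key], key=lambda e: (e.pos_a, e.pos_b, e.pair_id))
        run: list[BreakpointEvidence] = []
        for ev in members:
            if run and (
                abs(ev.pos_a - run[-1].pos_a) > window
                or abs(ev.pos_b - run[-1].pos_b) > window
            ):
                clusters.append(_finalize(run))
                run = []
            run.append(ev)
        if run:
            clusters.append(_finalize(run))
    return clusters


def _finalize(members: Sequence[BreakpointEvidence]) -> BreakpointCluster:
    ev = members[0]
    return BreakpointCluster(
        chrom_a=ev.chrom_a,
        pos_a=median_low([m.pos_a for m in members]),
        strand_a=ev.strand_a,
        chrom_b=ev.chrom_b,
        pos_b=median_low([m.pos_b for m in members]),
        strand_b=ev.strand_b,
        n_split=sum(1 for m in members if m.kind == "split"),
        n_discordant=sum(1 for m in members if m.kind == "discordant"),
    )


def classify_rearrangement(cluster: BreakpointCluster) -> str:
    """Geometric classification of a breakpoint cluster.

    Different chromosomes are a translocation; same-direction junctions on
    one chromosome an inversion; a forward junction (left side '+' joined
    to right side '-') a deletion — reported as long_deletion since only
    spans beyond the concordant limit reach this stage — and the reversed
    junction a tandem duplication.
    """
    if cluster.chrom_a != cluster.chrom_b:
        return "translocation"
    if cluster.strand_a == cluster.strand_b:
        return "inversion"
    if (cluster.strand_a, cluster.strand_b) == ("+", "-"):
        return "long_deletion"
    return "tandem_duplication"


def call_fusions(
    clusters: Iterable[BreakpointCluster],
    panel: Panel,
    min_split: int = 3,
    min_discordant: int = 5,
) -> tuple[list[FusionEvent], int]:
    """Turn clusters into fusion events restricted to baited regions.

    Clusters with both sides outside the panel are dropped (their count is
    returned alongside the events); an event PASSes with >= min_split
    split reads or >= min_discordant discordant pairs.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    events: list[FusionEvent] = []
    dropped = 0
    for cl in clusters:
        region_a = panel.region_at(cl.chrom_a, cl.pos_a)
        region_b = panel.region_at(cl.chrom_b, cl.pos_b)
        if region_a is None and region_b is None:
            dropped += 1
            continue
        status = (
            "PASS"
            if cl.n_split >= min_split or cl.n_discordant >= min_discordant
            else "low_support"
        )
        events.append(
            FusionEvent(
                cluster=cl,
                rearrangement_kind=classify_rearrangement(cl),
                gene_a=region_a.gene if region_a else None,
                gene_b=region_b.gene if region_b else None,
                status=status,
            )
        )
    return events, dropped


def detect_fusions(
    pairs: Sequence[ReadPairRecord],
    panel: Panel,
    min_clip: int = 10,
    window: int = 50,
    min_split: int = 3,
    min_discordant: int = 5,
    max_concordant_span: int = MAX_CONCORDANT_SPAN,
) -> tuple[list[FusionEvent], int]:
    """End-to-end fusion calling from raw read pairs."""
    split_ev = extract_clipped(pairs, min_clip=min_clip)
    disc_ev = discordant_evidence(select_discordant(pairs, max_concordant_span))
    clusters = cluster_breakpoints(split_ev + disc_ev, window=window)
    return call_fusions(clusters, panel, min_split, min_discordant)


# ---------------------------------------------------------------------------
# I/O: reads TSV (canonical) and SAM (optional convenience)
# ---------------------------------------------------------------------------

READS_COLUMNS = [
    "pair_id",
    "chrom1", "pos1", "strand1", "aligned_len1", "clip_left1", "clip_right1",
    "chrom2", "pos2", "strand2", "aligned_len2", "clip_left2", "clip_right2",
]


def read_pairs_tsv(path: str | Path) -> list[ReadPairRecord]:
    out: list[ReadPairRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("pair_id\t"):
                continue
            f = line.split("\t")
            out.append(
                ReadPairRecord(
                    read1=ReadAln(f[1], int(f[2]), f[3], int(f[4]), int(f[5]), int(f[6])),
                    read2=ReadAln(f[7], int(f[8]), f[9], int(f[10]), int(f[11]), int(f[12])),
                    pair_id=f[0],
                )
            )
    return out


def write_pairs_tsv(pairs: Iterable[ReadPairRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(READS_COLUMNS) + "\n")
        for p in pairs:
            r1, r2 = p.read1, p.read2
            fh.write(
                f"{p.pair_id}\t"
                f"{r1.chrom}\t{r1.pos}\t{r1.strand}\t{r1.aligned_len}\t{r1.clip_left}\t{r1.clip_right}\t"
                f"{r2.chrom}\t{r2.pos}\t{r2.strand}\t{r2.aligned_len}\t{r2.clip_left}\t{r2.clip_right}\n"
            )


def read_pairs_sam(path: str | Path) -> list[ReadPairRecord]:
    """Read paired alignments from a (text) SAM file via pysam.

    Soft clips are taken from the CIGAR; both mates must be mapped.  This
    is a convenience for real alignments — the canonical input is the
    reads TSV.
    """
    import pysam  # optional path; only needed when SAM input is used

    by_name: dict[str, list[ReadAln]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cig = aln.cigartuples or []
            clip_left = cig[0][1] if cig and cig[0][0] == 4 else 0
            clip_right = cig[-1][1] if cig and cig[-1][0] == 4 else 0
            aligned = sum(n for op, n in cig if op in (0, 7, 8, 2))
            by_name.setdefault(aln.query_name, []).append(
                ReadAln(
                    chrom=aln.reference_name,
                    pos=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    aligned_len=max(aligned, 1),
                    clip_left=clip_left,
                    clip_right=clip_right,
                )
            )
    return [
        ReadPairRecord(read1=reads[0], read2=reads[1], pair_id=name)
        for name, reads in sorted(by_name.items())
        if len(reads) == 2
    ]
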