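"""Copy-number calling from matched tumor/normal target coverage.

The pipeline is: library-size-normalized log2 tumor/normal ratio per
target bin, GC-stratified median correction, an agglomerative
BIC-guided merge into constant-copy-number segments, and purity-aware
amplification calling that inverts the mixing relation

    observed ratio = (p * CN_t + 2 * (1 - p)) / 2

to recover the tumor copy number CN_t at tumor fraction p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .panel import TargetRegion, _chrom_key

_RSS_FLOOR = 1e-12  # keeps log(RSS) finite on noiseless profiles


@dataclass
class CoverageBin:
    """Read counts over one panel target, tumor and matched normal."""

    region: TargetRegion
    tumor_count: int
    normal_count: int
    log2_ratio: float | None = None
    masked: bool = False

    def __post_init__(self) -> None:
        if self.tumor_count < 0 or self.normal_count < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2: float
    inferred_tumor_cn: float | None = None
    amplified: bool = False


def log2_ratio_profile(bins: Sequence[CoverageBin]) -> tuple[list[CoverageBin], int]:
    """Fill log2((tumor/T) / (normal/N)) per bin, library-size normalized.

    Bins with zero normal count are masked rather than imputed; the count
    of masked bins is returned for logging.  Totals are computed over
    unmasked bins so a handful of dropouts cannot shift the profile.
    """
    usable = [b for b in bins if b.normal_count > 0 and b.tumor_count > 0]
    t_total = sum(b.tumor_count for b in usable)
    n_total = sum(b.normal_count for b in usable)
    if t_total == 0 or n_total == 0:
        for b in bins:
            b.masked = True
        return list(bins), len(bins)
    n_masked = 0
    for b in bins:
        if b.normal_count == 0 or b.tumor_count == 0:
            b.masked = True
            b.log2_ratio = None
            n_masked += 1
            continue
        b.masked = False
        b.log2_ratio = math.log2(
            (b.tumor_count / t_total) / (b.normal_count / n_total)
        )
    return list(bins), n_masked


def paired_bins(
    tumor: Sequence[CoverageBin], normal: Sequence[CoverageBin]
) -> list[CoverageBin]:
    """Merge separate tumor and normal count tracks over identical regions."""
    if len(tumor) != len(normal):
        raise ValueError("tumor and normal tracks differ in length")
    out = []
    for t, n in zip(tumor, normal):
        if t.region != n.region:
            raise ValueError(
                f"unpaired bins {t.region.chrom}:{t.region.start} vs "
                f"{n.region.chrom}:{n.region.start}"
            )
        out.append(CoverageBin(t.region, t.tumor_count, n.normal_count))
    return out


def gc_correct(
    bins: Sequence[CoverageBin],
    n_strata: int = 20,
    min_stratum_bins: int = 5,
    neutral_band: float = 0.3,
) -> tuple[list[CoverageBin], int]:
    """Recenter the profile and remove residual GC trend.

    Putatively neutral bins are those within ``neutral_band`` of the
    global median log2 ratio (library-size normalization alone leaves the
    neutral level offset whenever amplified targets inflate the tumor
    total, so the center is estimated from the data — this assumes most
    of the panel is copy-neutral).  Per equal-width GC stratum the median
    log2 ratio of its neutral bins is subtracted; strata with fewer than
    ``min_stratum_bins`` neutral bins fall back to the global neutral
    median.  After correction the per-stratum neutral medians sit at ~0.
    Returns the corrected bins and the number of fallback strata.
    """
    live = [b for b in bins if not b.masked and b.log2_ratio is not None]
    if not live:
        return list(bins), 0
    gcs = np.array([
        0.5 if b.region.gc_fraction is None else b.region.gc_fraction for b in live
    ])
    ratios = np.array([b.log2_ratio for b in live])
    center = float(np.median(ratios))
    neutral = np.abs(ratios - center) <= neutral_band
    global_med = float(np.median(ratios[neutral])) if neutral.any() else center

    strata = np.minimum((gcs * n_strata).astype(int), n_strata - 1)
    n_fallback = 0
    offsets = np.empty(len(live))
    for s in range(n_strata):
        in_s = strata == s
        if not in_s.any():
            continue
        neut_s = in_s & neutral
        if neut_s.sum() >= min_stratum_bins:
            offsets[in_s] = float(np.median(ratios[neut_s]))
        else:
            offsets[in_s] = global_med
            n_fallback += 1
    for b, off in zip(live, offsets):
        b.log2_ratio = float(b.log2_ratio - off)
    return list(bins), n_fallback


# ---------------------------------------------------------------------------
# BIC-guided segmentation
# ---------------------------------------------------------------------------

def _noise_scale(values: np.ndarray, chrom_breaks: np.ndarray) -> float:
    """Robust per-bin noise s.d. from within-chromosome first differences.

    Adjacent same-copy-number bins differ by N(0, 2*sigma^2); the median
    absolute difference estimates sigma without being dragged by the few
    true breakpoints.  Returns at least a small floor so noiseless
    profiles stay well-defined.
    """
    diffs = np.diff(values)
    if len(diffs):
        diffs = diffs[~chrom_breaks[: len(diffs)]]
    if len(diffs) == 0:
        return math.sqrt(_RSS_FLOOR)
    mad = float(np.median(np.abs(diffs)))
    # MAD of N(0, 2 sigma^2) is 0.6745 * sqrt(2) * sigma
    return max(mad / 0.9539, math.sqrt(_RSS_FLOOR))


def bic_segment(
    bins: Sequence[CoverageBin], penalty_lambda: float = 2.0
) -> list[Segment]:
    """Agglomerative merge of adjacent bins guided by the BIC.

    Under a Gaussian model with noise level estimated robustly from
    adjacent-bin differences, ``BIC = RSS/sigma^2 + lambda*k*log(n)`` for
    a piecewise-constant fit with k segments.  Starting from one segment
    per bin, the adjacent within-chromosome pair whose merge increases
    the residual sum of squares least (leftmost on ties) is merged while
    the merge decreases the BIC, i.e. while
    ``min RSS increase < lambda * sigma^2 * log(n)``.  Deterministic for
    a given input and lambda; segmentation never crosses chromosomes.
    """
    live = [b for b in bins if not b.masked and b.log2_ratio is not None]
    if not live:
        return []
    live.sort(key=lambda b: (_chrom_key(b.region.chrom), b.region.start))

    values = np.array([b.log2_ratio for b in live])
    chroms = [b.region.chrom for b in live]
    chrom_breaks = np.array(
        [chroms[i] != chroms[i + 1] for i in range(len(chroms) - 1)] + [False]
    )
    sigma = _noise_scale(values, chrom_breaks)

    # state per segment: chrom, start, end, n, sum
    segs: list[list] = [
        [b.region.chrom, b.region.start, b.region.end, 1, b.log2_ratio]
        for b in live
    ]
    n = len(live)
    threshold = penalty_lambda * sigma ** 2 * (math.log(n) if n > 1 else 0.0)

    def merge_cost(i: int) -> float | None:
        a, b = segs[i], segs[i + 1]
        if a[0] != b[0]:
            return None  # never merge across chromosomes
        ma, mb = a[4] / a[3], b[4] / b[3]
        return (a[3] * b[3]) / (a[3] + b[3]) * (ma - mb) ** 2

    while len(segs) > 1:
        best_i, best_cost = -1, None
        for i in range(len(segs) - 1):
            c = merge_cost(i)
            if c is not None and (best_cost is None or c < best_cost):
                best_i, best_cost = i, c
        if best_cost is None or best_cost >= threshold:
            break
        a, b = segs[best_i], segs[best_i + 1]
        segs[best_i] = [a[0], a[1], b[2], a[3] + b[3], a[4] + b[4]]
        del segs[best_i + 1]

    return [
        Segment(chrom=s[0], start=s[1], end=s[2], n_bins=s[3],
                mean_log2=s[4] / s[3])
        for s in segs
    ]


def call_amplification(
    segment: Segment,
    purity: float,
    cn_threshold: float = 3.0,
    min_log2: float = 0.5,
) -> Segment:
    """Purity-corrected amplification call for one segment.

    The mixing relation gives the inferred tumor copy number
    ``CN_t = (2 * 2**mean_log2 - 2*(1 - purity)) / purity``.  A segment is
    amplified when the inferred CN reaches ``cn_threshold`` (a clear gain
    over the diploid 2) *and* the raw mean log2 ratio reaches ``min_log2``
    — the second condition is the detection floor: a diluted signal that
    no longer stands out of the coverage noise is not called, which is
    what makes low-level amplifications fade out of reach as tumor purity
    drops.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    cn = (2.0 * 2.0 ** segment.mean_log2 - 2.0 * (1.0 - purity)) / purity
    segment.inferred_tumor_cn = cn
    segment.amplified = cn >= cn_threshold and segment.mean_log2 >= min_log2
    return segment


def call_cnv(
    bins: Sequence[CoverageBin],
    purity: float,
    penalty_lambda: float = 2.0,
    cn_threshold: float = 3.0,
    min_log2: float = 0.5,
    gc_strata: int = 20,
) -> list[Segment]:
    """Full pipeline: normalize, GC-correct, segment, call amplifications."""
    bins, _ = log2_ratio_profile(list(bins))
    bins, _ = gc_correct(bins, n_strata=gc_strata)
    segments = bic_segment(bins, penalty_lambda=penalty_lambda)
    return [
        call_amplification(s, purity, cn_threshold, min_log2) for s in segments
    ]


# ---------------------------------------------------------------------------
# coverage TSV / SEG I/O
# ---------------------------------------------------------------------------

COVERAGE_COLUMNS = ["chrom", "start", "end", "gene", "gc", "tumor_count", "normal_count"]


def read_coverage(path: str | Path) -> list[CoverageBin]:
    out: list[CoverageBin] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            f = line.split("\t")
            region = TargetRegion(
                chrom=f[0], start=int(f[1]), end=int(f[2]), gene=f[3],
                gc_fraction=None if f[4] in (".", "") else float(f[4]),
            )
            out.append(CoverageBin(region, int(f[5]), int(f[6])))
    return out


def write_coverage(bins: Iterable[CoverageBin], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COVERAGE_COLUMNS) + "\n")
        for b in bins:
            r = b.region
            gc = "." if r.gc_fraction is None else f"{r.gc_fraction:.4f}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t{gc}\t"
                f"{b.tumor_count}\t{b.normal_count}\n"
            )


def write_segments(
    segments: Iterable[Segment], path: str | Path, sample: str = "sample"
) -> None:
    """SEG-style TSV (1-based inclusive starts, as IGV expects)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_bins\tmean_log2\tinferred_cn\tamplified\n")
        for s in segments:
            cn = "." if s.inferred_tumor_cn is None else f"{s.inferred_tumor_cn:.3f}"
            fh.write(
                f"{sample}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{s.n_bins}\t"
                f"{s.mean_log2:.4f}\t{cn}\t{int(s.amplified)}\n"
            )
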