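"""Analytical-validation computations for the panel.

Three experiments mirror how targeted panels are validated at the bench:

* **sensitivity vs depth** — reads are downsampled in silico over a depth
  grid and the filter cascade re-run, giving detection curves per MAF bin
  (low <=10%, intermediate 10-20%, high >=20%) with s.e.m. error bars
  across replicates, plus the depth at which each curve plateaus;
* **dilution limit of detection** — a tumor with known amplifications is
  mixed with matched normal DNA over a purity grid and the CNV pipeline
  re-run, giving the lowest purity at which each amplification is still
  called;
* **orthogonal concordance** — 2x2 agreement statistics against a binary
  truth assay (ARMS / FISH / IHC labels), with both the textbook
  specificity (TN rate) and the positive predictive value that assay
  comparisons restricted to sequencing-positive samples report under the
  name "specificity".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import Panel, TruthVariant
from .simulate import AmpliconSpec, SimConfig, downsample_pileup, simulate_coverage
from .snv import CallThresholds, PileupRecord, apply_filters
from .cnv import call_cnv


@dataclass(frozen=True)
class MafBin:
    label: str
    lower: float
    upper: float
    lower_inclusive: bool = False
    upper_inclusive: bool = True

    def contains(self, maf: float) -> bool:
        above = maf >= self.lower if self.lower_inclusive else maf > self.lower
        below = maf <= self.upper if self.upper_inclusive else maf < self.upper
        return above and below


#: The three reporting bins partition (0, 1]: (0, 0.10], (0.10, 0.20), [0.20, 1].
DEFAULT_MAF_BINS = (
    MafBin("<=10%", 0.0, 0.10),
    MafBin("10-20%", 0.10, 0.20, upper_inclusive=False),
    MafBin(">=20%", 0.20, 1.0, lower_inclusive=True),
)


def assign_bin(maf: float, bins: Sequence[MafBin] = DEFAULT_MAF_BINS) -> str:
    for b in bins:
        if b.contains(maf):
            return b.label
    raise ValueError(f"MAF {maf} outside (0, 1]")


@dataclass
class SensitivityCurve:
    depth_grid: list[int]
    bin_labels: list[str]
    #: sensitivity[(depth, label)] -> mean detection fraction
    sensitivity: dict[tuple[int, str], float]
    sem: dict[tuple[int, str], float]
    n_true: dict[str, int]
    replicates: int

    def pooled(self, depth: int) -> float:
        """Overall sensitivity at a depth, weighted by per-bin truth counts."""
        num = sum(
            self.sensitivity[(depth, lab)] * self.n_true[lab]
            for lab in self.bin_labels if self.n_true[lab]
        )
        den = sum(self.n_true[lab] for lab in self.bin_labels)
        return num / den if den else 0.0


def sensitivity_by_depth(
    truth: Sequence[TruthVariant],
    pileups: Sequence[PileupRecord],
    depth_grid: Sequence[int],
    replicates: int = 10,
    thresholds: CallThresholds | None = None,
    seed: int = 0,
    bins: Sequence[MafBin] = DEFAULT_MAF_BINS,
) -> SensitivityCurve:
    """Downsampling titration of detection sensitivity.

    Every full-depth pileup is thinned to each grid depth ``replicates``
    times with fresh seeds, the filter cascade is re-applied, and the
    detected fraction per true-MAF bin is averaged across replicates with
    its s.e.m.  Truth variants are matched to pileups by order.
    """
    if len(truth) != len(pileups):
        raise ValueError("truth and pileups must align one-to-one")
    min_available = min((p.depth for p in pileups), default=0)
    grid = sorted(int(d) for d in depth_grid)
    if grid and grid[-1] > min_available:
        raise ValueError(
            f"grid depth {grid[-1]} exceeds available depth {min_available}"
        )
    if replicates < 1:
        raise ValueError("need at least one replicate")

    labels = [b.label for b in bins]
    var_labels = [assign_bin(v.true_maf, bins) for v in truth]
    n_true = {lab: var_labels.count(lab) for lab in labels}

    rng = np.random.default_rng(seed)
    # per (depth, label): list over replicates of detection fraction
    per_rep: dict[tuple[int, str], list[float]] = {
        (d, lab): [] for d in grid for lab in labels
    }
    hotspot_flags = [v.is_hotspot for v in truth]
    repeat_flags = [v.in_repeat for v in truth]
    for _ in range(replicates):
        for d in grid:
            detected = {lab: 0 for lab in labels}
            for p, lab, hs, rep in zip(pileups, var_labels, hotspot_flags, repeat_flags):
                ds = downsample_pileup(p, d, rng)
                call = apply_filters(ds, thresholds, hotspot=hs, in_repeat=rep)
                if call.passed:
                    detected[lab] += 1
            for lab in labels:
                frac = detected[lab] / n_true[lab] if n_true[lab] else 0.0
                per_rep[(d, lab)].append(frac)

    sens: dict[tuple[int, str], float] = {}
    sem: dict[tuple[int, str], float] = {}
    for key, vals in per_rep.items():
        arr = np.asarray(vals)
        sens[key] = float(arr.mean())
        sem[key] = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return SensitivityCurve(
        depth_grid=grid, bin_labels=labels, sensitivity=sens, sem=sem,
        n_true=n_true, replicates=replicates,
    )


def find_plateau(
    curve: SensitivityCurve, epsilon: float = 0.002
) -> dict[str, int]:
    """Smallest grid depth within ``epsilon`` of each curve's maximum.

    Returned per MAF bin plus "pooled" for the truth-weighted average
    curve.
    """
    if not curve.depth_grid:
        raise ValueError("empty curve")
    out: dict[str, int] = {}
    for lab in curve.bin_labels:
        vals = [curve.sensitivity[(d, lab)] for d in curve.depth_grid]
        peak = max(vals)
        out[lab] = next(
            d for d, v in zip(curve.depth_grid, vals) if v >= peak - epsilon
        )
    pooled = [curve.pooled(d) for d in curve.depth_grid]
    peak = max(pooled)
    out["pooled"] = next(
        d for d, v in zip(curve.depth_grid, pooled) if v >= peak - epsilon
    )
    return out


def simulated_detection_rate(
    n_sites: int,
    maf_range: tuple[float, float],
    depth: int,
    seed: int,
    var_kind: str = "SNV",
    thresholds: CallThresholds | None = None,
    error_rate: float = 0.001,
) -> float:
    """Percent of simulated true variants the filter cascade detects.

    ``n_sites`` variants with true MAF uniform on ``maf_range`` are given
    binomially sampled alt counts at fixed ``depth`` with a symmetric
    strand split and a matched normal at the background ``error_rate``;
    the default cascade is applied and the PASS percentage returned.
    This is the in-silico analog of scoring known cell-line variants at a
    fixed coverage.
    """
    from .simulate import SimConfig, simulate_pileup  # deferred: avoid cycle

    rng = np.random.default_rng(seed)
    cfg = SimConfig(seed=seed, depth=depth, error_rate=error_rate)
    ref, alt = ("A", "T") if var_kind == "SNV" else ("AT", "A")
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_sites)
    n_pass = 0
    for maf in mafs:
        v = TruthVariant("chr1", 100, ref, alt, var_kind, float(maf))
        p = simulate_pileup(v, cfg, rng=rng, fixed_depth=depth)
        if apply_filters(p, thresholds).passed:
            n_pass += 1
    return 100.0 * n_pass / n_sites


# ---------------------------------------------------------------------------
# dilution limit of detection
# ---------------------------------------------------------------------------

@dataclass
class DilutionResult:
    purity_grid: list[float]  # strictly decreasing
    detected: dict[tuple[str, float], bool]
    lod: dict[str, float | None]  # lowest purity with detection, per gene

    def gene_detected(self, gene: str, purity: float) -> bool:
        return self.detected[(gene, purity)]


def dilution_lod(
    panel: Panel,
    amplicons: Sequence[AmpliconSpec],
    purity_grid: Sequence[float] = (0.5, 0.4, 0.3, 0.2, 0.1),
    depth: float = 800.0,
    seed: int = 0,
    penalty_lambda: float = 2.0,
    cn_threshold: float = 3.0,
    min_log2: float = 0.5,
) -> DilutionResult:
    """Purity titration of amplification detection.

    For each purity the tumor/normal coverage is simulated with the
    amplicon specs, the full CNV pipeline is run, and a gene counts as
    detected when an amplified segment overlaps any of its panel bins.
    """
    if not amplicons:
        raise ValueError("no amplicon specs")
    grid = list(purity_grid)
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise ValueError("purity grid must be strictly decreasing")
    genes = [a.gene for a in amplicons]
    detected: dict[tuple[str, float], bool] = {}
    rng = np.random.default_rng(seed)
    for purity in grid:
        config = SimConfig(
            seed=int(rng.integers(0, 2**31)), depth=depth, purity=purity,
            n_snv=0,
        )
        bins = simulate_coverage(panel, amplicons, config)
        segments = call_cnv(
            bins, purity=purity, penalty_lambda=penalty_lambda,
            cn_threshold=cn_threshold, min_log2=min_log2,
        )
        amp_segs = [s for s in segments if s.amplified]
        for gene in genes:
            regions = [r for r in panel if r.gene == gene]
            hit = any(
                s.chrom == r.chrom and s.start < r.end and r.start < s.end
                for s in amp_segs for r in regions
            )
            detected[(gene, purity)] = hit
    lod = {
        g: min((p for p in grid if detected[(g, p)]), default=None) for g in genes
    }
    return DilutionResult(purity_grid=grid, detected=detected, lod=lod)


# ---------------------------------------------------------------------------
# orthogonal-assay concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    tp: int
    fp: int
    fn: int
    tn: int
    paper_mode: bool = False

    def _rate(self, num: int, den: int) -> float | None:
        return num / den if den else None

    def fraction(self, name: str) -> Fraction | None:
        """Exact count ratio for a named rate."""
        pairs = {
            "sensitivity": (self.tp, self.tp + self.fn),
            "specificity": (
                (self.tp, self.tp + self.fp) if self.paper_mode
                else (self.tn, self.tn + self.fp)
            ),
            "ppv": (self.tp, self.tp + self.fp),
            "npv": (self.tn, self.tn + self.fn),
            "agreement": (self.tp + self.tn, self.tp + self.fp + self.fn + self.tn),
        }
        num, den = pairs[name]
        return Fraction(num, den) if den else None

    @property
    def sensitivity(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def ppv(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def specificity(self) -> float | None:
        """TN rate; in paper mode the PPV is reported under this label,
        matching assay comparisons made only on sequencing-positive
        samples."""
        if self.paper_mode:
            return self.ppv
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def agreement(self) -> float | None:
        total = self.tp + self.fp + self.fn + self.tn
        return self._rate(self.tp + self.tn, total)


def concordance(
    ngs_calls: Mapping[str, bool],
    orthogonal_labels: Mapping[str, bool],
    paper_mode: bool = False,
) -> ConcordanceResult:
    """2x2 agreement between per-sample NGS calls and an orthogonal assay.

    The orthogonal assay is treated as truth: TP are samples positive by
    both, FN positive by the assay only, FP by NGS only.  Sample sets must
    match exactly; order never matters.
    """
    ngs_ids, ortho_ids = set(ngs_calls), set(orthogonal_labels)
    if ngs_ids != ortho_ids:
        only_ngs = sorted(ngs_ids - ortho_ids)
        only_ortho = sorted(ortho_ids - ngs_ids)
        raise ValueError(
            f"sample sets differ: only in NGS {only_ngs}, only in assay {only_ortho}"
        )
    tp = fp = fn = tn = 0
    for sample in ngs_ids:
        n, o = bool(ngs_calls[sample]), bool(orthogonal_labels[sample])
        if n and o:
            tp += 1
        elif n and not o:
            fp += 1
        elif o:
            fn += 1
        else:
            tn += 1
    return ConcordanceResult(tp=tp, fp=fp, fn=fn, tn=tn, paper_mode=paper_mode)


def concordance_from_counts(
    tp: int, fp: int, fn: int, tn: int, paper_mode: bool = False
) -> ConcordanceResult:
    """Build the statistics directly from published 2x2 counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be >= 0")
    return ConcordanceResult(tp=tp, fp=fp, fn=fn, tn=tn, paper_mode=paper_mode)
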