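"""Run configuration and the end-to-end demonstration pipeline.

A single YAML config is the one source of truth for every threshold; a
single top-level seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` so any stage can be re-run in isolation and
the whole run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .panel import Panel, hotspot_lookup, read_hotspots, read_panel_bed, write_truth
from .simulate import (
    AmpliconSpec, SimConfig, simulate_coverage, simulate_fusion_reads,
    simulate_pileups, simulate_truth,
)
from .snv import CallThresholds, call_variants, write_pileups
from .cnv import call_cnv, write_coverage, write_segments
from .fusion import detect_fusions, write_pairs_tsv
from .io import write_bedpe, write_vcf
from .toy import DILUTION_AMPLICONS, dilution_panel, toy_panel
from .validate import dilution_lod, find_plateau, sensitivity_by_depth

logger = logging.getLogger("panelval")

_STAGES = ("simulate", "call_snv", "call_cnv", "call_fusion", "validate")


def stage_seeds(seed: int, n: int = len(_STAGES)) -> list[int]:
    """Derive independent per-stage child seeds from one top-level seed."""
    return [int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "panelval_out"
    panel_path: str | None = None  # None -> built-in toy panel
    hotspots_path: str | None = None
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    # cnv
    penalty_lambda: float = 2.0
    cn_threshold: float = 3.0
    min_log2: float = 0.5
    purity: float = 0.5
    # fusion
    min_clip: int = 10
    cluster_window: int = 50
    min_split: int = 3
    min_discordant: int = 5
    # simulation
    n_snv: int = 200
    n_indel: int = 40
    maf_model: Any = "cellline_pool"
    depth: float = 800.0
    error_rate: float = 0.001
    amplicons: tuple[AmpliconSpec, ...] = DILUTION_AMPLICONS
    # validation
    depth_grid: Sequence[int] = (100, 200, 300, 400, 500, 600, 700, 800)
    replicates: int = 5

    _KNOWN = {
        "seed", "out_dir", "panel_path", "hotspots_path", "thresholds",
        "penalty_lambda", "cn_threshold", "min_log2", "purity",
        "min_clip", "cluster_window", "min_split", "min_discordant",
        "n_snv", "n_indel", "maf_model", "depth", "error_rate",
        "amplicons", "depth_grid", "replicates",
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in raw:
            raw["thresholds"] = CallThresholds(**raw["thresholds"])
        if "amplicons" in raw:
            raw["amplicons"] = tuple(
                AmpliconSpec(a["gene"], int(a["tumor_copy_number"]))
                for a in raw["amplicons"]
            )
        if "maf_model" in raw and isinstance(raw["maf_model"], list):
            raw["maf_model"] = tuple(raw["maf_model"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> call (snv, cnv, fusion) -> validate, with a manifest.

    All outputs are written under ``config.out_dir`` and are byte-identical
    across runs with the same config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(_STAGES, stage_seeds(config.seed)))
    manifest: dict = {
        "panelval_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages_completed": [],
    }

    panel = read_panel_bed(config.panel_path) if config.panel_path else toy_panel()
    hotspots = read_hotspots(config.hotspots_path) if config.hotspots_path else []
    hs_test = hotspot_lookup(hotspots) if hotspots else None

    # --- simulate ------------------------------------------------------
    logger.info("stage=simulate seed=%d", seeds["simulate"])
    sim = SimConfig(
        seed=seeds["simulate"], n_snv=config.n_snv, n_indel=config.n_indel,
        maf_model=config.maf_model, depth=config.depth,
        error_rate=config.error_rate, purity=config.purity,
    )
    truth = simulate_truth(sim, panel)
    pileups = simulate_pileups(truth, sim)
    cnv_panel = dilution_panel()
    coverage = simulate_coverage(cnv_panel, config.amplicons, sim)
    alk_intron = next(r for r in panel if r.gene == "ALK" and r.region_kind == "intron")
    pairs = simulate_fusion_reads(
        ("chr2", 42_492_100, "+"), (alk_intron.chrom, alk_intron.start + 400, "-"),
        n_split=6, n_discordant=8, n_background=20, seed=seeds["simulate"],
    )
    write_truth(truth, out / "truth.tsv")
    write_pileups(pileups, out / "pileups.tsv")
    write_coverage(coverage, out / "coverage.tsv")
    write_pairs_tsv(pairs, out / "reads.tsv")
    manifest["stages_completed"].append("simulate")

    # --- call ----------------------------------------------------------
    logger.info("stage=call_snv")
    calls = call_variants(
        pileups, config.thresholds, hotspot_test=hs_test,
        repeat_sites={(v.chrom, v.pos) for v in truth if v.in_repeat},
        panel=panel,
    )
    write_vcf(calls, out / "calls.vcf", config.thresholds)
    manifest["snv_pass"] = sum(1 for c in calls if c.passed)
    manifest["snv_total"] = len(calls)
    manifest["stages_completed"].append("call_snv")

    logger.info("stage=call_cnv")
    segments = call_cnv(
        coverage, purity=config.purity, penalty_lambda=config.penalty_lambda,
        cn_threshold=config.cn_threshold, min_log2=config.min_log2,
    )
    write_segments(segments, out / "segments.seg")
    manifest["cnv_amplified_segments"] = sum(1 for s in segments if s.amplified)
    manifest["stages_completed"].append("call_cnv")

    logger.info("stage=call_fusion")
    events, dropped = detect_fusions(
        pairs, panel, min_clip=config.min_clip, window=config.cluster_window,
        min_split=config.min_split, min_discordant=config.min_discordant,
    )
    write_bedpe(events, out / "fusions.bedpe")
    manifest["fusion_events"] = len(events)
    manifest["fusion_dropped_outside_panel"] = dropped
    manifest["stages_completed"].append("call_fusion")

    # --- validate ------------------------------------------------------
    logger.info("stage=validate")
    grid = [d for d in config.depth_grid if d <= min(p.depth for p in pileups)]
    curve = sensitivity_by_depth(
        truth, pileups, grid, replicates=config.replicates,
        thresholds=config.thresholds, seed=seeds["validate"],
    )
    plateau = find_plateau(curve)
    dil = dilution_lod(
        cnv_panel, config.amplicons, depth=config.depth, seed=seeds["validate"],
        penalty_lambda=config.penalty_lambda, cn_threshold=config.cn_threshold,
        min_log2=config.min_log2,
    )
    with open(out / "sensitivity.tsv", "w") as fh:
        fh.write("depth\tbin\tsensitivity\tsem\n")
        for d in curve.depth_grid:
            for lab in curve.bin_labels:
                fh.write(
                    f"{d}\t{lab}\t{curve.sensitivity[(d, lab)]:.4f}"
                    f"\t{curve.sem[(d, lab)]:.4f}\n"
                )
    manifest["plateau_depth"] = plateau
    manifest["dilution_lod"] = {g: dil.lod[g] for g in sorted(dil.lod)}
    manifest["stages_completed"].append("validate")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
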