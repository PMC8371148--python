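"""End-to-end orchestration: simulate -> quantify -> stats -> fish -> thermal.

A single :class:`RunConfig` carries the stage configurations and one global
seed. Each stochastic stage derives its own seed deterministically from the
global seed and the stage name (CRC32 fan-out), so stages can be re-run
independently and a full re-run reproduces every artifact bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import densitometry, fishing, stats, synthetic, thermal

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

log = logging.getLogger("cytoblot")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name folded into the
    global seed, kept below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    population: synthetic.PopulationSpec = field(default_factory=synthetic.PopulationSpec)
    render: synthetic.RenderSpec = field(default_factory=synthetic.RenderSpec)
    fishing: fishing.FishingConfig = field(default_factory=fishing.FishingConfig)
    conductor: thermal.ConductorSpec = field(
        default_factory=lambda: thermal.ConductorSpec(E=3000.0, sigma_c=0.13, a=2.5e-3)
    )
    r2_gate: float = densitometry.R2_GATE
    snr_gate: float = densitometry.SNR_GATE
    outlier_filter: bool = True
    seed: int = 0
    out_dir: str = "runs/default"
    stages: tuple[str, ...] = ("simulate", "quantify", "stats", "thermal")

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"] = synthetic.spec_to_json(self.population)
        d["render"] = synthetic.spec_to_json(self.render)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "population" in d:
            d["population"] = synthetic.population_spec_from_json(d["population"])
        if "render" in d:
            d["render"] = synthetic.render_spec_from_json(d["render"])
        if "fishing" in d and isinstance(d["fishing"], dict):
            d["fishing"] = fishing.FishingConfig(**d["fishing"])
        if "conductor" in d and isinstance(d["conductor"], dict):
            d["conductor"] = thermal.ConductorSpec(**d["conductor"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order, writing artifacts under
    ``config.out_dir``. A stage failure is recorded and the run continues so
    partial results are still reported."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "errors": {}}
    cells = truth = blots = None

    if "simulate" in config.stages:
        try:
            pop = dataclasses.replace(config.population, seed=stage_seed(config.seed, "simulate"))
            cells = synthetic.sample_population(pop)
            image, truth = synthetic.render_array(cells, config.render,
                                                  seed=stage_seed(config.seed, "render"))
            cells.to_csv(out / "cells.csv", index=False)
            truth.to_csv(out / "ground_truth.csv", index=False)
            synthetic.write_image(image, out / "array.tiff", out / "array_geometry.json")
            report["stages"]["simulate"] = {"n_cells": len(cells), "n_lanes": len(truth)}
            log.info("simulate: %d cells rendered", len(cells))
        except Exception as exc:  # pragma: no cover - defensive
            report["errors"]["simulate"] = str(exc)

    if "quantify" in config.stages:
        try:
            image = synthetic.read_image(out / "array.tiff", out / "array_geometry.json")
            blots, qrep = densitometry.quantify_array(
                image, outlier_filter=config.outlier_filter,
                r2_gate=config.r2_gate, snr_gate=config.snr_gate)
            blots.to_csv(out / "blots.csv", index=False)
            table = densitometry.blots_to_cell_table(blots, truth)
            table.to_csv(out / "quantified_cells.csv", index=False)
            report["stages"]["quantify"] = {
                "n_lanes": qrep.n_lanes, "n_pass": qrep.n_pass, "rejects": qrep.rejects}
            log.info("quantify: %d/%d lanes pass QC", qrep.n_pass, qrep.n_lanes)
        except Exception as exc:
            report["errors"]["quantify"] = str(exc)

    if "stats" in config.stages:
        try:
            table = pd.read_csv(out / "quantified_cells.csv")
            fr = table["f_ratio"].dropna().to_numpy()
            f = table["F"].dropna().to_numpy()
            st = {
                "n_cells": int(len(fr)),
                "f_ratio_mean": float(fr.mean()) if len(fr) else None,
                "f_ratio_sd": float(fr.std(ddof=1)) if len(fr) > 1 else None,
                "f_ratio_median": float(np.median(fr)) if len(fr) else None,
                "F_cqv": stats.cqv(f) if len(f) >= 4 else None,
                "F_iqr": stats.iqr(f) if len(f) >= 4 else None,
                "f_ratio_skew": stats.pearson_skew(fr) if len(fr) >= 3 else None,
            }
            with open(out / "stats.json", "w") as fh:
                json.dump(st, fh, indent=2)
            report["stages"]["stats"] = st
        except Exception as exc:
            report["errors"]["stats"] = str(exc)

    if "fish" in config.stages:
        try:
            cells_df = pd.read_csv(out / "cells.csv")
            std = fishing.standardize(cells_df)
            is_bait = std["subpop"] != "none"
            cfg = dataclasses.replace(config.fishing, seed=stage_seed(config.seed, "fish"))
            result = fishing.cellfish(std[is_bait], std[~is_bait], cfg)
            result.to_frame().to_csv(out / "fishing.csv", index=False)
            report["stages"]["fish"] = {
                "n_bait": int(is_bait.sum()),
                "n_candidates": int((~is_bait).sum()),
                "n_fished_out": len(result.fished_out),
            }
        except Exception as exc:
            report["errors"]["fish"] = str(exc)

    if "thermal" in config.stages:
        try:
            report["stages"]["thermal"] = {
                "max_delta_T_C": thermal.max_delta_T(config.conductor)}
        except Exception as exc:
            report["errors"]["thermal"] = str(exc)

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
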