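"""End-to-end runs: simulate -> trace -> measure -> stats, and
simulate-counts -> DE -> cross-species concordance.

Each run writes its outputs together with a JSON manifest (parameters,
seeds, per-stage exclusion counts) sufficient to reproduce the run
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .concordance import conserved_set, export_heatmap_matrix, join_orthologs
from .de import filter_degs
from .groupstats import compare_groups
from .params import (
    CONCORDANCE_PRESETS,
    GROUP_N_CELLS,
    IMAGING_PRESETS,
    AcquisitionParams,
    PopulationPreset,
)
from .simulate import gen_cell_population, gen_de_tables
from .trace import LineScanRecording, extract_trace, normalize_f0, smooth_trace
from .transients import CellSummary, analyze_trace, detect_baseline, summarize_cell

__all__ = [
    "RunConfig",
    "DEFAULT_COMPARISON_PLAN",
    "analyze_recording",
    "measure_population",
    "run_imaging_arm",
    "run_transcriptomics_arm",
]

#: planned group comparisons: KO effect, toxin effect, and the rescue test
DEFAULT_COMPARISON_PLAN: dict[str, Any] = {
    "pairs": [["WT", "KO"], ["WT", "WT_HELHO"], ["KO_HELHO", "WT"]],
    "rescue": {
        "treated_ko": "KO_HELHO",
        "reference": "WT",
        "treated_reference": "WT_HELHO",
    },
}


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    All randomness flows from ``seed``; group sub-seeds are ``seed + k`` in
    group order.  ``n_cells`` defaults to the per-group cell counts of the
    imaging study.
    """

    arm: str = "both"
    out_dir: str | Path = "runs/out"
    seed: int = 0
    groups: tuple[str, ...] = ("WT", "KO", "WT_HELHO", "KO_HELHO")
    n_cells: Mapping[str, int] | None = None
    group_seeds: Mapping[str, int] | None = None
    smooth_order: int = 6
    smooth_neighbors: int = 10
    noise: bool = True
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    concordance_preset: str = "default"
    lfc_min: float = 1.0
    q_max: float = 0.05
    require_stages: str = "pattern"

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        acq = data.pop("acquisition", None)
        data.update(overrides)
        cfg = cls(**data)
        if acq:
            cfg.acquisition = AcquisitionParams(**acq)
        return cfg

    def seed_for(self, group: str) -> int:
        if self.group_seeds and group in self.group_seeds:
            return int(self.group_seeds[group])
        return int(self.seed) + self.groups.index(group)


def analyze_recording(
    rec: LineScanRecording,
    pacing_hz: float,
    smooth_order: int = 6,
    smooth_neighbors: int = 10,
    stim_offset_s: float = 0.0,
    min_prominence: float = 0.10,
) -> tuple[CellSummary | None, list[str]]:
    """Full single-cell analysis chain.

    extract mean-intensity trace -> polynomial smoothing -> baseline
    detection -> F/F0 normalization -> epoch segmentation -> per-transient
    measurement -> per-cell summary.  Returns ``(summary, exclusion log)``;
    the summary is None when no epoch held a measurable transient.
    """
    trace = extract_trace(rec)
    trace = smooth_trace(trace, order=smooth_order, neighbors=smooth_neighbors)
    f0 = detect_baseline(trace)
    trace = normalize_f0(trace, f0)
    metrics, exclusions = analyze_trace(
        trace, pacing_hz, stim_offset_s=stim_offset_s, min_prominence=min_prominence
    )
    cell_id = rec.metadata.get("cell_id", "cell")
    batch = int(rec.metadata.get("batch", 0))
    if not metrics:
        return None, exclusions + [f"cell {cell_id}: excluded (no valid transients)"]
    return summarize_cell(metrics, cell_id, batch), exclusions


def measure_population(
    preset: PopulationPreset,
    n_cells: int,
    acq: AcquisitionParams,
    seed: int,
    noise: bool = True,
    smooth_order: int = 6,
    smooth_neighbors: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate one cell population and push every cell through the
    analysis chain, streaming (one recording in memory at a time).

    Returns the per-cell summary table and the exclusion log.
    """
    pacing = preset.mean_params.pacing_hz
    rows = []
    excluded: list[str] = []
    for rec in gen_cell_population(preset, n_cells, acq, seed=seed, noise=noise):
        summary, exclusions = analyze_recording(
            rec, pacing, smooth_order=smooth_order, smooth_neighbors=smooth_neighbors
        )
        excluded.extend(exclusions)
        if summary is None:
            continue
        rows.append(
            {
                "cell_id": summary.cell_id,
                "batch": summary.diff_batch_id,
                "group": preset.group_label,
                "n_transients_used": summary.n_transients_used,
                "amplitude": summary.mean_amplitude,
                "rise_time_ms": summary.mean_rise_time_ms,
                "decay50_ms": summary.mean_decay50_ms,
            }
        )
    return pd.DataFrame(rows), excluded


def run_imaging_arm(config: RunConfig) -> dict[str, Any]:
    """Simulate and measure every configured group; write cells.csv,
    stats.csv, group_summary.json and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_cells = dict(GROUP_N_CELLS)
    if config.n_cells:
        n_cells.update(config.n_cells)

    tables = []
    exclusion_counts: dict[str, int] = {}
    for group in config.groups:
        preset = IMAGING_PRESETS[group]
        cells, excluded = measure_population(
            preset,
            n_cells[group],
            config.acquisition,
            seed=config.seed_for(group),
            noise=config.noise,
            smooth_order=config.smooth_order,
            smooth_neighbors=config.smooth_neighbors,
        )
        tables.append(cells)
        exclusion_counts[group] = len(excluded)
    cells = pd.concat(tables, ignore_index=True)
    cells.to_csv(out / "cells.csv", index=False, float_format="%.10g")

    plan = {
        "pairs": [p for p in DEFAULT_COMPARISON_PLAN["pairs"] if set(p) <= set(config.groups)],
    }
    rescue_groups = set(DEFAULT_COMPARISON_PLAN["rescue"].values())
    if rescue_groups <= set(config.groups):
        plan["rescue"] = DEFAULT_COMPARISON_PLAN["rescue"]
    results, rescue_flags, stats_table = compare_groups(cells, plan)
    stats_table.to_csv(out / "stats.csv", index=False, float_format="%.10g")

    summary = {
        r.group_label: {
            "n_cells": r.n_cells,
            "means": r.means,
            "sds": r.sds,
            "anova": {
                m: {
                    "sigma2_between": a.sigma2_between,
                    "sigma2_within": a.sigma2_within,
                    "F": a.f_stat,
                    "p": a.p_value,
                }
                for m, a in r.anova.items()
            },
        }
        for r in results
    }
    summary["rescue_flags"] = rescue_flags
    (out / "group_summary.json").write_text(json.dumps(summary, indent=1))

    manifest = {
        "stage": "imaging",
        "version": __version__,
        "seed": config.seed,
        "group_seeds": {g: config.seed_for(g) for g in config.groups},
        "n_cells": {g: n_cells[g] for g in config.groups},
        "targeted_epochs_per_cell": int(
            np.floor(
                config.acquisition.duration_s
                * IMAGING_PRESETS[config.groups[0]].mean_params.pacing_hz
            )
        ),
        "acquisition": {
            "n_pixels": config.acquisition.n_pixels,
            "n_lines": config.acquisition.n_lines,
            "line_rate_hz": config.acquisition.line_rate_hz,
        },
        "smoothing": {
            "order": config.smooth_order,
            "neighbors": config.smooth_neighbors,
        },
        "noise": config.noise,
        "excluded_epochs": exclusion_counts,
        "outputs": ["cells.csv", "stats.csv", "group_summary.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "cells": cells,
        "results": results,
        "rescue_flags": rescue_flags,
        "manifest": manifest,
    }


def run_transcriptomics_arm(config: RunConfig) -> dict[str, Any]:
    """Simulate paired species counts, run DE per stage contrast, and
    extract the conserved cross-species gene set."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preset = CONCORDANCE_PRESETS[config.concordance_preset]
    human, mouse, ortho, truth = gen_de_tables(preset, seed=config.seed)
    human.to_csv(out / "human_de.tsv", sep="\t", index=False, float_format="%.6g")
    mouse.to_csv(out / "mouse_de.tsv", sep="\t", index=False, float_format="%.6g")
    ortho.to_csv(out / "orthologs.tsv", sep="\t", index=False)

    paired = join_orthologs(human, mouse, ortho)
    cs = conserved_set(
        paired,
        lfc_min=config.lfc_min,
        q_max=config.q_max,
        require_stages=config.require_stages,  # type: ignore[arg-type]
    )
    cs.entries.to_csv(out / "conserved_set.tsv", sep="\t", index=False, float_format="%.6g")
    if len(cs):
        export_heatmap_matrix(cs, out / "heatmap.tsv")

    deg_counts = {}
    for label, table in (("human", human), ("mouse", mouse)):
        for stage in ("ch", "hf"):
            df = pd.DataFrame(
                {
                    "log2fc": table[f"log2fc_{stage}"],
                    "q_value": table[f"q_{stage}"],
                }
            )
            deg_counts[f"{label}_{stage}"] = int(
                len(filter_degs(df, config.lfc_min, config.q_max))
            )

    manifest = {
        "stage": "transcriptomics",
        "version": __version__,
        "seed": config.seed,
        "preset": config.concordance_preset,
        "n_genes": preset.n_genes,
        "n_planted": preset.n_planted,
        "thresholds": {"lfc_min": config.lfc_min, "q_max": config.q_max},
        "require_stages": config.require_stages,
        "deg_counts": deg_counts,
        "conserved_genes": len(cs),
        "outputs": [
            "human_de.tsv",
            "mouse_de.tsv",
            "orthologs.tsv",
            "conserved_set.tsv",
            "heatmap.tsv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "human": human,
        "mouse": mouse,
        "orthologs": ortho,
        "truth": truth,
        "conserved": cs,
        "manifest": manifest,
    }
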