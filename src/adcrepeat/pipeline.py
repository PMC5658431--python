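"""End-to-end orchestration: cohort -> repeatability -> fit -> GOF ->
standardise -> look-up chart, with figure analogues and a run manifest.

The pipeline consumes either an ROI summary table on disk or a synthetic
cohort specification, and writes: the repeatability records CSV, fitted
parameters JSON, goodness-of-fit JSON, a raw-vs-standardised width
summary, figure files with their underlying numbers exported as CSV, the
look-up grid, and a manifest sufficient to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .adcmap import voxels_to_volume
from .error_model import ErrorModelParams, default_lookup_grid
from .inference import chi_squared_gof, fit_mle, standardise
from .io import (RepeatabilityRecord, pair_sessions, read_roi_table,
                 write_records_csv, write_params_json)
from .metrics import group_summary, make_records, within_subject_cov
from .simulate import SyntheticConfig, generate_cohort

#: ROI-size threshold above which uncertainty gains plateau
PLATEAU_VOXELS = 2000


@dataclass
class PipelineConfig:
    """Inputs for :func:`run_pipeline`.

    Exactly one of ``roi_table`` (path to a measurement table) or
    ``synthetic`` (a :class:`SyntheticConfig`) must be given.
    """

    roi_table: str | None = None
    synthetic: SyntheticConfig | None = None
    variant: str = "three_param"
    exclude_motion: bool = True
    fit_kinds: tuple[str, ...] = ("whole_3d", "slice_largest", "slice_solid")
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.roi_table is None) == (self.synthetic is None):
            raise ValueError("give exactly one of roi_table or synthetic")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        for key in ("roi_kinds", "fit_kinds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**{k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass
class RunManifest:
    """Reproducibility record for a pipeline run."""

    software_version: str = __version__
    seed: int = 0
    config: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    python: str = field(default_factory=platform.python_version)

    def log_stage(self, name: str, **counts) -> None:
        self.stages.append({"stage": name, **counts})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write all outputs under ``outdir``.

    Returns a dict of output paths plus the headline summary (raw and
    standardised 95% width).  Stage failures raise :class:`StageError`
    naming the stage; outputs written before the failure remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, started=_now())
    cfg_dict = dataclasses.asdict(config)
    if config.synthetic is not None:
        cfg_dict["synthetic"] = dataclasses.asdict(config.synthetic)
    manifest.config = cfg_dict

    stage = "load"
    try:
        if config.roi_table is not None:
            path = Path(config.roi_table)
            manifest.input_hashes[str(path)] = _sha256(path)
            measurements = list(read_roi_table(path))
        else:
            measurements = generate_cohort(config.synthetic)
        manifest.log_stage(stage, n_measurements=len(measurements))

        stage = "pair"
        pairing = pair_sessions(measurements)
        manifest.log_stage(stage, n_pairs=len(pairing.pairs),
                           n_unpaired=len(pairing.unpaired))

        stage = "repeatability"
        records = make_records(pairing.pairs)
        records_csv = outdir / "records.csv"
        write_records_csv(records, records_csv)
        raw = group_summary([r.r12 for r in records])
        cov = within_subject_cov(pairing.pairs)
        manifest.log_stage(stage, n_records=len(records),
                           raw_width=raw.ci_width_95, cov_pct=cov)

        stage = "fit"
        fit_records = [r for r in records
                       if r.pair.roi_kind in config.fit_kinds]
        fit = fit_mle(fit_records, variant=config.variant,
                      exclude_motion=config.exclude_motion,
                      seed=config.seed)
        params_json = outdir / "params.json"
        write_params_json(fit, params_json)
        manifest.log_stage(stage, n_used=fit.n_records_used,
                           n_excluded_motion=fit.n_excluded_motion,
                           n_starts=fit.n_starts,
                           nll=fit.neg_log_likelihood)

        stage = "gof"
        gof_all = chi_squared_gof(fit_records, fit.params)
        gof_nomotion = chi_squared_gof(
            fit_records, fit.params, subset=lambda r: not r.motion)
        gof_json = outdir / "gof.json"
        gof_json.write_text(json.dumps(
            {"all_fit_kinds": gof_all.to_dict(),
             "no_motion": gof_nomotion.to_dict()}, indent=2))
        manifest.log_stage(stage, chi2=gof_all.chi2, dof=gof_all.dof)

        stage = "standardise"
        std_records, z_summary = standardise(records, fit.params)
        std_csv = outdir / "records_standardised.csv"
        write_records_csv(std_records, std_csv)
        manifest.log_stage(stage, z_width=z_summary.ci_width_95)

        stage = "lookup"
        grid = default_lookup_grid(fit.params)
        lookup_csv = outdir / "lookup.csv"
        grid.to_csv(lookup_csv)
        grid_meta = outdir / "lookup_meta.json"
        grid_meta.write_text(json.dumps(
            {"params": fit.params.to_dict(), "d_nominal": grid.d_nominal},
            indent=2))
        manifest.log_stage(stage, n_cells=int(grid.cells.size))

        stage = "figures"
        figures = make_figures(std_records, fit.params, outdir)
        manifest.log_stage(stage, n_figures=len(figures))

        stage = "summary"
        summary = {
            "raw_width_95": raw.ci_width_95,
            "standardised_width_95": z_summary.ci_width_95,
            "cov_pct": cov,
            "n_records": len(records),
            "n_motion": sum(r.motion for r in records),
        }
        summary_json = outdir / "summary.json"
        summary_json.write_text(json.dumps(summary, indent=2))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest.finished = _now()
    manifest.write(outdir / "manifest.json")
    return {"records_csv": records_csv, "params_json": params_json,
            "gof_json": gof_json, "records_standardised_csv": std_csv,
            "lookup_csv": lookup_csv, "summary_json": summary_json,
            "manifest_json": outdir / "manifest.json",
            "figures": figures, **summary}


def _records_frame(records: Sequence[RepeatabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "roi_kind": [r.pair.roi_kind for r in records],
        "n_voxels": [(r.pair.roi_1.n_voxels + r.pair.roi_2.n_voxels) / 2
                     for r in records],
        "r12": [r.r12 for r in records],
        "epsilon_r12": [r.epsilon_r12 for r in records],
        "z": [r.z for r in records],
        "motion": [r.motion for r in records],
    })


def make_figures(records: Sequence[RepeatabilityRecord],
                 params: ErrorModelParams,
                 outdir: str | Path) -> dict[str, Path]:
    """Figure analogues of the study plots, with numeric CSV exports.

    Produces: repeatability vs ROI size (motion highlighted), predicted
    uncertainty vs ROI size with the 2000-voxel / 22.5 cm^3 plateau
    threshold annotated, the standardised scatter, and the look-up heat
    map.  Every plotted number is also written to CSV so the figures are
    pure functions of the exported data.
    """
    if not records:
        raise ValueError("no records to plot")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = _records_frame(records)
    out: dict[str, Path] = {}

    def scatter(ax, ycol, ylabel):
        for motion, marker, color in ((False, "o", "tab:blue"),
                                      (True, "o", "black")):
            sub = df[df.motion == motion]
            ax.scatter(sub.n_voxels, sub[ycol], s=18, marker=marker,
                       c=color, label="motion" if motion else "no motion")
        ax.set_xscale("log")
        ax.set_xlabel("ROI size (voxels, log scale)")
        ax.set_ylabel(ylabel)
        ax.axhline(0.0, lw=0.5, color="grey")
        ax.legend(fontsize=8)

    fig, ax = plt.subplots(figsize=(6, 4))
    scatter(ax, "r12", r"$\Delta$ADC% ($R_{12}$)")
    fig.tight_layout()
    p = outdir / "fig_repeatability_vs_size.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out["repeatability_vs_size"] = p

    fig, ax = plt.subplots(figsize=(6, 4))
    for motion, color in ((False, "tab:blue"), (True, "black")):
        sub = df[df.motion == motion]
        ax.scatter(sub.n_voxels, sub.epsilon_r12, s=18, c=color,
                   label="motion" if motion else "no motion")
    thr_cm3 = voxels_to_volume(PLATEAU_VOXELS).cm3
    ax.axvline(PLATEAU_VOXELS, ls="--", color="grey",
               label=f"{PLATEAU_VOXELS} voxels = {thr_cm3:g} cm$^3$")
    ax.set_xscale("log")
    ax.set_xlabel("ROI size (voxels, log scale)")
    ax.set_ylabel(r"$\epsilon_{R12}$ (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = outdir / "fig_uncertainty_vs_size.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out["uncertainty_vs_size"] = p

    fig, ax = plt.subplots(figsize=(6, 4))
    scatter(ax, "z", r"standardised $\Delta$ADC% ($z$)")
    fig.tight_layout()
    p = outdir / "fig_standardised_vs_size.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out["standardised_vs_size"] = p

    grid = default_lookup_grid(params)
    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(grid.sd_values, grid.n_voxels, grid.cells,
                         shading="nearest")
    ax.set_yscale("log")
    ax.set_xlabel(r"ADC histogram SD ($10^{-5}$ mm$^2$/s)")
    ax.set_ylabel("ROI size (voxels)")
    fig.colorbar(mesh, ax=ax, label=r"$\epsilon_{R12}$ (%)")
    fig.tight_layout()
    p = outdir / "fig_lookup_heatmap.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out["lookup_heatmap"] = p

    data_csv = outdir / "figure_data.csv"
    df.to_csv(data_csv, index=False)
    out["figure_data"] = data_csv
    return out
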