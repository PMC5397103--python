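"""End-to-end analysis runs: frames in, histograms and a JSON report out.

A :class:`RunConfig` names one input source (multi-model PDB, vector table,
or the synthetic generator), the photophysical parameters, and the
efficiency convention — per-frame Forster radii rescaled by the
instantaneous kappa^2, or a fixed kappa^2_ref.  :func:`run_analysis`
computes the kappa^2 series, efficiency trace and apparent-distance
reconstruction, writes TSV histograms plus ``report.json``, and returns the
:class:`RunReport`.  Outputs are deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .distributions import (
    DEFAULT_BIN_WIDTH_DISTANCE,
    DEFAULT_BIN_WIDTH_EFFICIENCY,
    DEFAULT_BIN_WIDTH_KAPPA2,
    compare_true_vs_apparent,
    isotropic_kappa2_pdf,
    make_histogram,
    reconstruct_apparent_distribution,
    summarize,
)
from .fret_model import FretParameters, fret_efficiency, instantaneous_efficiency
from .frames import DipoleTrajectory
from .geometry import kappa_squared_series
from .synthetic import LinkerModelParams, simulate_trajectory
from .trajectory_io import ChromophoreSpec, extract_dipole_frames, read_multimodel_pdb, read_vector_table

logger = logging.getLogger("fretkappa")

OUTPUT_FILES = [
    "kappa2_series.tsv",
    "kappa2_histogram.tsv",
    "r_da_histogram.tsv",
    "efficiency_histogram.tsv",
    "apparent_distance_histogram.tsv",
    "report.json",
]


@dataclass
class RunConfig:
    """Configuration of one analysis run (exactly one input source)."""

    input_mode: str  # {"pdb", "table", "simulate"}
    output_directory: str = "fretkappa_run"
    input_path: Optional[str] = None
    linker_params: Optional[LinkerModelParams] = None
    donor_spec: Optional[ChromophoreSpec] = None
    acceptor_spec: Optional[ChromophoreSpec] = None
    fret_params: FretParameters = field(default_factory=lambda: FretParameters(r0_ref=48.0))
    efficiency_mode: str = "instantaneous_kappa2"  # or "fixed_kappa2"
    bin_width_distance: float = DEFAULT_BIN_WIDTH_DISTANCE
    bin_width_efficiency: float = DEFAULT_BIN_WIDTH_EFFICIENCY
    bin_width_kappa2: float = DEFAULT_BIN_WIDTH_KAPPA2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_mode not in ("pdb", "table", "simulate"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.efficiency_mode not in ("instantaneous_kappa2", "fixed_kappa2"):
            raise ValueError(f"unknown efficiency_mode {self.efficiency_mode!r}")
        if self.input_mode in ("pdb", "table") and not self.input_path:
            raise ValueError(f"input_mode {self.input_mode!r} requires input_path")
        if self.input_mode == "pdb" and (self.donor_spec is None or self.acceptor_spec is None):
            raise ValueError("pdb input requires donor_spec and acceptor_spec")
        if self.input_mode == "simulate" and self.linker_params is None:
            raise ValueError("simulate input requires linker_params")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "linker_params" in kwargs and kwargs["linker_params"] is not None:
            kwargs["linker_params"] = LinkerModelParams(**kwargs["linker_params"])
        for key in ("donor_spec", "acceptor_spec"):
            if kwargs.get(key) is not None:
                kwargs[key] = ChromophoreSpec(**kwargs[key])
        if kwargs.get("fret_params") is not None:
            kwargs["fret_params"] = FretParameters(**kwargs["fret_params"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(value):
            if dataclasses.is_dataclass(value) and not isinstance(value, type):
                return {k: conv(v) for k, v in dataclasses.asdict(value).items()}
            if isinstance(value, np.ndarray):
                return value.tolist()
            if isinstance(value, (np.floating, np.integer)):
                return value.item()
            return value

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass(frozen=True)
class RunReport:
    """Aggregated summaries of one run: <kappa^2>, R_DA, E_DA, apparent R."""

    n_frames: int
    kappa2_summary: dict
    r_da_summary: dict
    efficiency_summary: dict
    apparent_summary: dict
    width_ratio: float
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_frames(config: RunConfig) -> DipoleTrajectory:
    if config.input_mode == "pdb":
        frames = read_multimodel_pdb(config.input_path)
        return extract_dipole_frames(frames, config.donor_spec, config.acceptor_spec)
    if config.input_mode == "table":
        return read_vector_table(config.input_path)
    params = dataclasses.replace(config.linker_params, seed=config.seed)
    return simulate_trajectory(params)


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_analysis(config: RunConfig, force: bool = False) -> RunReport:
    """Run the full pipeline described by ``config`` and write its outputs."""
    out = Path(config.output_directory)
    out.mkdir(parents=True, exist_ok=True)
    existing = [name for name in OUTPUT_FILES if (out / name).exists()]
    if existing and not force:
        raise FileExistsError(
            f"outputs already present in {out} ({existing[0]} ...); pass force=True / --force"
        )

    traj = _load_frames(config)
    logger.info("loaded %d frames (input_mode=%s)", len(traj), config.input_mode)

    series = kappa_squared_series(traj)
    k2 = series["kappa2"].to_numpy()
    r_da = series["r_da"].to_numpy()

    params = config.fret_params
    if config.efficiency_mode == "instantaneous_kappa2":
        eff = instantaneous_efficiency(r_da, k2, params)
    else:
        eff = np.asarray(fret_efficiency(r_da, params.r0_ref))

    recon = reconstruct_apparent_distribution(eff, params.r0_ref, config.bin_width_distance)
    n_excluded = recon.n_excluded
    logger.info(
        "efficiency frames: %d kept, %d excluded from inversion", len(eff) - n_excluded, n_excluded
    )

    comparison = compare_true_vs_apparent(
        r_da, recon.histogram, config.bin_width_distance, n_excluded_apparent=n_excluded
    )

    # per-stage histograms
    k2_hist = make_histogram(k2, config.bin_width_kappa2).to_frame()
    mid = 0.5 * (k2_hist["bin_left"] + k2_hist["bin_right"])
    theory = np.where(mid > 0, isotropic_kappa2_pdf(np.maximum(mid, 1e-12)), 0.0)
    k2_hist["isotropic_density"] = theory
    eff_hist = make_histogram(eff, config.bin_width_efficiency).to_frame()
    r_hist = make_histogram(r_da, config.bin_width_distance).to_frame()

    _write_tsv(series, out / "kappa2_series.tsv")
    _write_tsv(k2_hist, out / "kappa2_histogram.tsv")
    _write_tsv(r_hist, out / "r_da_histogram.tsv")
    _write_tsv(eff_hist, out / "efficiency_histogram.tsv")
    _write_tsv(recon.histogram.to_frame(), out / "apparent_distance_histogram.tsv")

    k2_summary = summarize(k2, config.bin_width_kappa2).to_dict()
    eff_summary = summarize(eff, config.bin_width_efficiency, n_excluded=n_excluded).to_dict()
    report = RunReport(
        n_frames=len(traj),
        kappa2_summary={"mean": k2_summary["mean"], "sd": k2_summary["sd"]},
        r_da_summary=comparison.true_summary.to_dict(),
        efficiency_summary=eff_summary,
        apparent_summary=recon.summary.to_dict(),
        width_ratio=comparison.width_ratio,
        provenance={
            "config": config.to_dict(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    logger.info("report written to %s", out / "report.json")
    return report
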