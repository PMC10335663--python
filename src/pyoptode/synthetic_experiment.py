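"""End-to-end synthetic multireactor campaigns.

This module is the package's stand-in for hardware: it simulates a full
batch-incubation campaign -- true oxygen-consumption kinetics, diffusive
ingress through the tube walls, the optode's Stern-Volmer response, and
camera pixel noise -- and emits exactly the artifacts the real pipeline
consumes (TIFF frames, a frame manifest, an ROI layout, a calibration
registry) plus truth tables for verification.

The generating kinetic model mirrors the phase structure seen in sealed
sediment incubations: an early first-order component (rate ``k1*C``) active
for a configurable initial window, a zero-order biotic component (constant
rate) active whenever oxygen remains above an anoxia floor, and diffusive
influx throughout.  Concentration is integrated by forward Euler with a
step of at most cadence/10 -- deliberately a different numerical route than
the closed-form exponential used by the permeability fitter, so the
simulator and the fitter can serve as independent cross-checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import pandas as pd
import yaml

from .calibration import CalibrationCurve, save_registry
from .errors import InputError
from .gas_exchange import (
    EnvironmentConditions,
    ReactorSpec,
    ambient_o2_pressure,
    default_reactor_library,
    o2_solubility,
)
from .imaging import RoiSpec, render_synthetic_frame, write_roi_layout

__all__ = ["TubeTruth", "ScenarioConfig", "CampaignResult", "simulate_tube", "simulate_campaign"]


@dataclass(frozen=True)
class TubeTruth:
    """Generating kinetics for one tube.

    first_order_k [1/min] acts for the first ``first_order_duration_min``
    minutes; zero_order_slope [mg/(L*hr)] acts while C > anoxia_floor
    [mg/L]; c0_mg_L is the concentration at t=0.
    """

    first_order_k: float = 0.08
    zero_order_slope: float = 4.5
    anoxia_floor: float = 0.2
    c0_mg_L: float = 5.5
    first_order_duration_min: float = 10.0


@dataclass
class ScenarioConfig:
    """A simulated campaign: tubes, optics, cadence, noise, and a seed.

    Defaults emulate a typical short sediment incubation: 20 tubes imaged
    every 2 minutes for 70 minutes, each starting well below air saturation
    and declining through a first-order phase into a linear phase before
    hitting an anoxic floor, with mild tube-to-tube parameter scatter and
    16-bit camera noise of a few DN.
    """

    n_tubes: int = 20
    cadence_min: float = 2.0
    duration_min: float = 70.0
    env: EnvironmentConditions = field(
        default_factory=lambda: EnvironmentConditions(temperature_C=21.0)
    )
    reactor_type: str = "plastic_centrifuge_50ml"
    tube_truths: dict[str, TubeTruth] | None = None  # None -> jittered defaults
    cal_truths: dict[str, CalibrationCurve] | None = None  # None -> jittered defaults
    ratio_def: str = "larsen"
    disk_radius_px: float = 10.0
    disk_spacing_px: float = 48.0
    green_level: float = 20000.0
    pixel_noise_sd: float = 30.0
    bit_depth: int = 16
    truth_scatter: float = 0.10  # relative sd of per-tube kinetic jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence_min <= 0:
            raise InputError("cadence_min must be positive")
        if self.duration_min < self.cadence_min:
            raise InputError("duration_min must be >= cadence_min")
        if self.n_tubes < 1:
            raise InputError("n_tubes must be >= 1")


@dataclass
class CampaignResult:
    """In-memory products of a simulated campaign."""

    config: ScenarioConfig
    layout: list[RoiSpec]
    cal_truths: dict[str, CalibrationCurve]
    tube_truths: dict[str, TubeTruth]
    reactors: dict[str, ReactorSpec]
    times_min: np.ndarray
    truth_conc: pd.DataFrame  # tube_id, time_min, conc_mg_L
    frames: list[np.ndarray]
    out_dir: Path | None = None
    manifest: pd.DataFrame | None = None


def simulate_tube(
    truth: TubeTruth,
    reactor: ReactorSpec,
    env: EnvironmentConditions,
    times_min: np.ndarray,
    euler_step_min: float,
) -> np.ndarray:
    """Integrate one tube's oxygen trace by forward Euler.

    dC/dt = -(k1(t)*C + k0*[C > floor]) + r*(pa - C/H)/V, clipped at zero.
    Returns concentrations at ``times_min``.
    """
    H = o2_solubility(env) / ambient_o2_pressure(env)
    pa = ambient_o2_pressure(env)
    k0_per_min = truth.zero_order_slope / 60.0

    t_end = float(times_min[-1])
    n_steps = int(np.ceil(t_end / euler_step_min)) if t_end > 0 else 0
    grid = np.linspace(0.0, t_end, n_steps + 1)
    c = np.empty_like(grid)
    c[0] = truth.c0_mg_L
    for i in range(n_steps):
        t = grid[i]
        dt = grid[i + 1] - grid[i]
        cons = 0.0
        if t < truth.first_order_duration_min:
            cons += truth.first_order_k * c[i]
        if c[i] > truth.anoxia_floor:
            cons += k0_per_min
        influx = reactor.permeability_r * (pa - c[i] / H) / reactor.volume_L
        c[i + 1] = max(c[i] + dt * (influx - cons), 0.0)
    return np.interp(times_min, grid, c)


def _default_truths(cfg: ScenarioConfig, rng: np.random.Generator) -> dict[str, TubeTruth]:
    base = TubeTruth()
    truths = {}
    for i in range(cfg.n_tubes):
        jit = lambda v: float(v * (1.0 + cfg.truth_scatter * rng.standard_normal()))
        truths[f"tube{i:03d}"] = TubeTruth(
            first_order_k=max(jit(base.first_order_k), 0.0),
            zero_order_slope=max(jit(base.zero_order_slope), 0.1),
            anoxia_floor=max(jit(base.anoxia_floor), 0.0),
            c0_mg_L=max(jit(base.c0_mg_L), 0.5),
            first_order_duration_min=base.first_order_duration_min,
        )
    return truths


def _default_cals(cfg: ScenarioConfig, tube_ids, rng: np.random.Generator):
    cals = {}
    for tid in tube_ids:
        cals[tid] = CalibrationCurve(
            disk_id=tid,
            R0=float(1.90 + 0.03 * rng.standard_normal()),
            Ksv=float(max(0.010 + 0.001 * rng.standard_normal(), 1e-4)),
            alpha=0.05,
            ratio_def=cfg.ratio_def,
            temperature_C=cfg.env.temperature_C,
            created_at="1970-01-01T00:00:00+00:00",  # fixed for byte-identical reruns
        )
    return cals


def _grid_layout(cfg: ScenarioConfig, tube_ids) -> list[RoiSpec]:
    per_row = int(np.ceil(np.sqrt(len(tube_ids))))
    rois = []
    for i, tid in enumerate(tube_ids):
        row, col = divmod(i, per_row)
        rois.append(
            RoiSpec(
                disk_id=tid,
                center_x=cfg.disk_spacing_px * (col + 0.5),
                center_y=cfg.disk_spacing_px * (row + 0.5),
                radius=cfg.disk_radius_px,
            )
        )
    return rois


def simulate_campaign(cfg: ScenarioConfig, out_dir=None) -> CampaignResult:
    """Simulate a campaign; optionally write the full artifact set to disk.

    With ``out_dir`` given, writes ``frames/frame_NNNN.tif``, ``manifest.csv``
    (time_min, path), ``roi_layout.csv``, ``registry.json`` (truth
    calibrations), ``truth_concentrations.csv`` and ``truth_kinetics.csv``.
    Identical config and seed produce byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    tube_truths = cfg.tube_truths or _default_truths(cfg, rng)
    tube_ids = sorted(tube_truths)
    cal_truths = cfg.cal_truths or _default_cals(cfg, tube_ids, rng)
    if set(cal_truths) < set(tube_ids):
        raise InputError("every tube needs a calibration truth")

    library = default_reactor_library()
    if cfg.reactor_type not in library:
        raise InputError(
            f"unknown reactor_type {cfg.reactor_type!r}; known: {sorted(library)}"
        )
    reactors = {tid: library[cfg.reactor_type] for tid in tube_ids}

    n_frames = int(np.floor(cfg.duration_min / cfg.cadence_min)) + 1
    times = np.arange(n_frames) * cfg.cadence_min
    euler_step = cfg.cadence_min / 10.0

    conc = {
        tid: simulate_tube(tube_truths[tid], reactors[tid], cfg.env, times, euler_step)
        for tid in tube_ids
    }

    layout = _grid_layout(cfg, tube_ids)
    sol = o2_solubility(cfg.env)
    frames = []
    for j, t in enumerate(times):
        truth_sat = {tid: max(conc[tid][j] / sol * 100.0, 0.0) for tid in tube_ids}
        frames.append(
            render_synthetic_frame(
                layout,
                truth_sat,
                cal_truths,
                green_level=cfg.green_level,
                noise_sd=cfg.pixel_noise_sd,
                bit_depth=cfg.bit_depth,
                seed=rng,  # one generator threads through all frames
            )
        )

    truth_conc = pd.DataFrame(
        [
            {"tube_id": tid, "time_min": float(t), "conc_mg_L": float(conc[tid][j])}
            for tid in tube_ids
            for j, t in enumerate(times)
        ]
    )

    result = CampaignResult(
        config=cfg,
        layout=layout,
        cal_truths=cal_truths,
        tube_truths=tube_truths,
        reactors=reactors,
        times_min=times,
        truth_conc=truth_conc,
        frames=frames,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "frames").mkdir(parents=True, exist_ok=True)
        records = []
        for j, (t, frame) in enumerate(zip(times, frames)):
            rel = f"frames/frame_{j:04d}.tif"
            tifffile.imwrite(out_dir / rel, frame, photometric="rgb")
            records.append({"time_min": float(t), "path": rel})
        manifest = pd.DataFrame(records)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        write_roi_layout(out_dir / "roi_layout.csv", layout)
        save_registry(out_dir / "registry.json", cal_truths)
        truth_conc.to_csv(out_dir / "truth_concentrations.csv", index=False)
        pd.DataFrame(
            [{"tube_id": tid, **dataclasses.asdict(tube_truths[tid])} for tid in tube_ids]
        ).to_csv(out_dir / "truth_kinetics.csv", index=False)
        with open(out_dir / "scenario.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "n_tubes": cfg.n_tubes,
                    "cadence_min": cfg.cadence_min,
                    "duration_min": cfg.duration_min,
                    "reactor_type": cfg.reactor_type,
                    "ratio_def": cfg.ratio_def,
                    "pixel_noise_sd": cfg.pixel_noise_sd,
                    "bit_depth": cfg.bit_depth,
                    "seed": cfg.seed,
                },
                fh,
                sort_keys=True,
            )
        result.out_dir = out_dir
        result.manifest = manifest

    return result
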