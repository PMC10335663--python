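"""ROI extraction from RGB optode frames, and the synthetic forward model.

The measurement chain is deliberately simple: each optode disk is a circular
region of interest in a time-lapse RGB frame; the oxygen signal is the mean
red intensity over the ROI and the reference is the mean green intensity.
Two ratio definitions are supported and always both computed:

* ``ratio_larsen = (red - green) / green`` -- the form used with cameras
  whose internal IR-blocking filter has been removed;
* ``ratio_simple = red / green`` -- used with the IR filter intact, where
  the Larsen form can go negative and break curve fitting.

They differ by exactly 1 (``larsen == simple - 1``), so either can drive a
Stern-Volmer calibration as long as calibration and measurement agree.

``render_synthetic_frame`` is the testable forward model: given per-disk
truth concentrations and calibrations it paints disks whose quantised pixel
ratios reproduce the Stern-Volmer response before noise, then adds i.i.d.
Gaussian camera noise.  Everything downstream (extraction, inversion,
segmentation) can therefore be validated end-to-end without hardware.

Conventions: 0-based pixel indices, origin at the top-left, x rightward,
y downward.  A pixel belongs to an ROI when its center lies strictly inside
the circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationCurve, invert_calibration, stern_volmer_forward
from .errors import GeometryError, InputError, RenderError
from .gas_exchange import EnvironmentConditions, ReactorSpec, sat_to_conc
from .kinetics import OxygenTimeSeries

__all__ = [
    "RoiSpec",
    "RatioSample",
    "FrameManifest",
    "extract_roi_ratios",
    "render_synthetic_frame",
    "build_timeseries",
    "read_roi_layout",
    "write_roi_layout",
    "samples_to_frame",
    "read_manifest_csv",
    "load_frame",
]

DEFAULT_SATURATION_QC_THRESHOLD = 0.01  # fraction of ROI pixels at full scale


@dataclass(frozen=True)
class RoiSpec:
    """A circular region of interest over one optode disk."""

    disk_id: str
    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 3:
            raise GeometryError(f"disk {self.disk_id!r}: radius must be >= 3 px")


@dataclass
class RatioSample:
    """Channel statistics and ratios for one disk in one frame."""

    disk_id: str
    time_min: float
    mean_red: float
    mean_green: float
    n_pixels: int
    ratio_larsen: float
    ratio_simple: float
    saturated_fraction: float
    qc_pass: bool


@dataclass
class FrameManifest:
    """Ordered (time_min, image_path) records for a capture sequence."""

    frames: list[tuple[float, str]]
    bit_depth: int = 16
    notes: str = ""

    def __post_init__(self) -> None:
        times = [t for t, _ in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InputError("manifest times must be strictly increasing")
        if self.bit_depth not in (8, 16):
            raise InputError("bit_depth must be 8 or 16")


def _max_dn(image: np.ndarray) -> int:
    if image.dtype == np.uint8:
        return 255
    if image.dtype == np.uint16:
        return 65535
    raise InputError(f"expected 8- or 16-bit integer image, got dtype {image.dtype}")


def _roi_mask(image_shape: tuple[int, int], roi: RoiSpec) -> np.ndarray:
    h, w = image_shape
    if (
        roi.center_x - roi.radius < -0.5
        or roi.center_y - roi.radius < -0.5
        or roi.center_x + roi.radius > w - 0.5
        or roi.center_y + roi.radius > h - 0.5
    ):
        raise GeometryError(f"ROI {roi.disk_id!r} extends outside the image bounds")
    yy, xx = np.ogrid[:h, :w]
    return (xx - roi.center_x) ** 2 + (yy - roi.center_y) ** 2 < roi.radius**2


def extract_roi_ratios(
    image: np.ndarray,
    rois: Sequence[RoiSpec],
    time_min: float,
    saturation_threshold: float = DEFAULT_SATURATION_QC_THRESHOLD,
) -> list[RatioSample]:
    """Mean red/green statistics and both ratio definitions per ROI.

    ``saturated_fraction`` is the fraction of ROI pixels with red or green at
    full scale; QC passes while it stays below ``saturation_threshold``.  A
    disk whose mean green is zero yields NaN ratios and a failed QC flag;
    other disks are unaffected.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise InputError("image must be H x W x (>=3 channels)")
    max_dn = _max_dn(image)
    red = image[..., 0].astype(float)
    green = image[..., 1].astype(float)

    samples = []
    for roi in rois:
        mask = _roi_mask(image.shape[:2], roi)
        n_pix = int(mask.sum())
        if n_pix == 0:
            raise GeometryError(f"ROI {roi.disk_id!r} covers no pixel centers")
        mr = float(red[mask].mean())
        mg = float(green[mask].mean())
        sat_frac = float(((red[mask] >= max_dn) | (green[mask] >= max_dn)).mean())
        if mg > 0:
            simple = mr / mg
            larsen = simple - 1.0
            qc = sat_frac < saturation_threshold
        else:
            warnings.warn(
                f"disk {roi.disk_id!r}: mean green is zero, ratios undefined", stacklevel=2
            )
            simple = larsen = float("nan")
            qc = False
        samples.append(
            RatioSample(
                disk_id=roi.disk_id,
                time_min=time_min,
                mean_red=mr,
                mean_green=mg,
                n_pixels=n_pix,
                ratio_larsen=larsen,
                ratio_simple=simple,
                saturated_fraction=sat_frac,
                qc_pass=qc,
            )
        )
    return samples


def render_synthetic_frame(
    layout: Sequence[RoiSpec],
    truth: Mapping[str, float],
    cals: Mapping[str, CalibrationCurve],
    green_level: float = 20000.0,
    noise_sd: float = 0.0,
    bit_depth: int = 16,
    seed: int | np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render an RGB frame whose disk ratios follow the Stern-Volmer model.

    Inside each disk the green channel is set to ``green_level`` and the red
    channel to the level that makes the disk's configured ratio definition
    reproduce ``stern_volmer_forward(truth[disk])`` exactly before noise
    (``red = green*(1+R)`` for the Larsen definition, ``red = green*R`` for
    the simple one).  i.i.d. Gaussian noise of ``noise_sd`` DN is then added
    to every channel, and the image is clipped and quantised to the
    requested bit depth.  Background is black.  Reproducible for a fixed
    ``seed``.
    """
    if bit_depth not in (8, 16):
        raise InputError("bit_depth must be 8 or 16")
    max_dn = 2**bit_depth - 1
    missing = [r.disk_id for r in layout if r.disk_id not in truth or r.disk_id not in cals]
    if missing:
        raise InputError(f"no truth/calibration for disks: {missing}")

    if shape is None:
        w = int(np.ceil(max(r.center_x + r.radius for r in layout))) + 4
        h = int(np.ceil(max(r.center_y + r.radius for r in layout))) + 4
        shape = (h, w)

    img = np.zeros((*shape, 3), dtype=float)
    for roi in layout:
        cal = cals[roi.disk_id]
        R = stern_volmer_forward(truth[roi.disk_id], cal)
        red_level = green_level * (1.0 + R) if cal.ratio_def == "larsen" else green_level * R
        if red_level > max_dn:
            raise RenderError(
                f"disk {roi.disk_id!r}: red level {red_level:.0f} exceeds {max_dn}; "
                "lower green_level"
            )
        mask = _roi_mask(shape, roi)
        img[..., 0][mask] = red_level
        img[..., 1][mask] = green_level

    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, max_dn)
    return img.astype(np.uint8 if bit_depth == 8 else np.uint16)


def build_timeseries(
    samples: Iterable[RatioSample],
    cal_registry: Mapping[str, CalibrationCurve],
    ratio_def: str = "larsen",
    env: EnvironmentConditions | None = None,
    reactors: Mapping[str, ReactorSpec] | None = None,
) -> dict[str, OxygenTimeSeries]:
    """Invert ratio samples through per-disk calibrations into DO series.

    Concentrations are back-calculated in % air saturation and converted to
    mg/L under ``env`` (default 21 degC, 1013.25 mbar, fresh water).
    QC-failed samples are carried with NaN concentration and a False mask
    entry.  Unknown disks raise an error listing every missing id.
    """
    if env is None:
        env = EnvironmentConditions(temperature_C=21.0)
    samples = list(samples)
    if not samples:
        return {}
    missing = sorted({s.disk_id for s in samples} - set(cal_registry))
    if missing:
        raise InputError(f"disk ids missing from the calibration registry: {missing}")

    by_disk: dict[str, list[RatioSample]] = {}
    for s in samples:
        by_disk.setdefault(s.disk_id, []).append(s)

    out = {}
    for disk_id, group in sorted(by_disk.items()):
        group.sort(key=lambda s: s.time_min)
        cal = cal_registry[disk_id]
        if cal.ratio_def != ratio_def:
            raise InputError(
                f"disk {disk_id!r}: calibration uses ratio_def={cal.ratio_def!r}, "
                f"requested {ratio_def!r}"
            )
        times, concs, mask = [], [], []
        for s in group:
            ratio = s.ratio_larsen if ratio_def == "larsen" else s.ratio_simple
            times.append(s.time_min)
            if s.qc_pass and np.isfinite(ratio):
                sat = float(invert_calibration(ratio, cal))
                concs.append(sat_to_conc(sat, env))
                mask.append(True)
            else:
                concs.append(float("nan"))
                mask.append(False)
        reactor = reactors.get(disk_id) if reactors else None
        out[disk_id] = OxygenTimeSeries(
            tube_id=disk_id,
            times_min=np.asarray(times),
            conc_mg_L=np.asarray(concs),
            env=env,
            reactor=reactor,
            qc_mask=np.asarray(mask),
        )
    return out


# ---------------------------------------------------------------------------
# I/O helpers


def read_roi_layout(path) -> list[RoiSpec]:
    """Read an ROI layout from CSV or YAML (disk_id, center_x, center_y, radius)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rows = raw if isinstance(raw, list) else raw.get("rois", [])
    else:
        rows = pd.read_csv(path).to_dict("records")
    rois = []
    for row in rows:
        try:
            rois.append(
                RoiSpec(
                    disk_id=str(row["disk_id"]),
                    center_x=float(row["center_x"]),
                    center_y=float(row["center_y"]),
                    radius=float(row["radius"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"malformed ROI record {row!r}") from exc
    return rois


def write_roi_layout(path, rois: Sequence[RoiSpec]) -> None:
    pd.DataFrame(
        [
            {
                "disk_id": r.disk_id,
                "center_x": r.center_x,
                "center_y": r.center_y,
                "radius": r.radius,
            }
            for r in rois
        ]
    ).to_csv(path, index=False)


_SAMPLE_COLUMNS = [
    "disk_id", "time_min", "mean_red", "mean_green", "n_pixels",
    "ratio_larsen", "ratio_simple", "saturated_fraction", "qc_pass",
]


def samples_to_frame(samples: Iterable[RatioSample]) -> pd.DataFrame:
    """Flatten RatioSamples into the extraction CSV layout (headers kept even
    when there are no samples)."""
    return pd.DataFrame(
        columns=_SAMPLE_COLUMNS,
        data=[
            {
                "disk_id": s.disk_id,
                "time_min": s.time_min,
                "mean_red": s.mean_red,
                "mean_green": s.mean_green,
                "n_pixels": s.n_pixels,
                "ratio_larsen": s.ratio_larsen,
                "ratio_simple": s.ratio_simple,
                "saturated_fraction": s.saturated_fraction,
                "qc_pass": s.qc_pass,
            }
            for s in samples
        ]
    )


def read_manifest_csv(path, bit_depth: int = 16) -> FrameManifest:
    """Read a frame manifest CSV with columns time_min, path."""
    df = pd.read_csv(path)
    missing = {"time_min", "path"} - set(df.columns)
    if missing:
        raise InputError(f"manifest CSV missing columns: {sorted(missing)}")
    frames = [(float(r["time_min"]), str(r["path"])) for _, r in df.iterrows()]
    return FrameManifest(frames=frames, bit_depth=bit_depth)


def load_frame(path) -> np.ndarray:
    """Read a PNG/TIFF RGB frame as an integer array."""
    return iio.imread(path)
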