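"""Stern-Volmer calibration of ratiometric oxygen optodes.

A platinum-porphyrin optode reports oxygen through collisional quenching of
its red emission; the green reference emission is oxygen-insensitive.  The
ratio R (either the Larsen ``(red-green)/green`` or the simple ``red/green``
form, depending on the camera's IR-filter configuration) follows a modified
Stern-Volmer law with a nonquenchable signal fraction alpha:

    R(C) = R0 * [ alpha + (1 - alpha) / (1 + Ksv * C) ]

where C is dissolved oxygen in % air saturation, R0 the zero-oxygen ratio,
and Ksv the quenching constant per % saturation.  This module fits, stores,
inverts and compares such curves, and computes LOD/LOQ metrology from the
noise and slope of the response in its linear range.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateCalibrationError,
    DomainError,
    FitError,
    InputError,
    MetrologyError,
    NormalizationError,
    OutOfRangeError,
    SuperSaturationWarning,
)

__all__ = [
    "CalibrationCurve",
    "CalibrationPoint",
    "DetectionLimits",
    "stern_volmer_forward",
    "invert_calibration",
    "fit_calibration",
    "back_calculate",
    "compute_detection_limits",
    "summarize_lods",
    "compare_calibrations",
    "normalize_ratios",
    "load_registry",
    "save_registry",
    "read_points_csv",
]

LOQ_LOD_RATIO = 10.0 / 3.3

_RATIO_DEFS = ("larsen", "simple")


@dataclass
class CalibrationCurve:
    """Fitted modified Stern-Volmer response of one optode disk.

    ``ratio_def`` records which ratio the curve was fitted on: ``"larsen"``
    for (red-green)/green (IR filter removed) or ``"simple"`` for red/green
    (IR filter intact).  Concentrations are always % air saturation.
    """

    disk_id: str
    R0: float
    Ksv: float
    alpha: float = 0.0
    ratio_def: str = "larsen"
    conc_units: str = "pct_air_saturation"
    r_squared: float = float("nan")
    resid_sd: float = float("nan")
    temperature_C: float = float("nan")
    created_at: str = ""

    def __post_init__(self) -> None:
        if not self.R0 > 0:
            raise DomainError(f"R0 must be positive, got {self.R0}")
        if self.Ksv < 0:
            raise DomainError(f"Ksv must be nonnegative, got {self.Ksv}")
        if not (0.0 <= self.alpha < 1.0):
            raise DomainError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.ratio_def not in _RATIO_DEFS:
            raise InputError(f"ratio_def must be one of {_RATIO_DEFS}, got {self.ratio_def!r}")
        if not self.created_at:
            self.created_at = _dt.datetime.now(_dt.timezone.utc).isoformat()


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation: known saturation and the measured ratio."""

    true_saturation: float  # % air saturation
    ratio: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.true_saturation < 0:
            raise DomainError(f"true_saturation must be >= 0, got {self.true_saturation}")
        if not np.isfinite(self.ratio):
            raise DomainError(f"ratio must be finite, got {self.ratio}")


@dataclass(frozen=True)
class DetectionLimits:
    """LOD/LOQ metrology: LOD = |3.3*sigma/m|, LOQ = |10*sigma/m|.

    sigma is the (population) standard deviation of repeated back-calculated
    measurements at one probe concentration; m is the slope of the response
    over its linear range.  By construction ``loq == lod * (10/3.3)``.
    """

    sigma: float
    slope_m: float
    lod: float  # % air saturation
    loq: float  # % air saturation
    linear_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lod < 0 or self.loq < 0:
            raise DomainError("lod and loq must be nonnegative")
        if self.loq != self.lod * LOQ_LOD_RATIO:
            raise DomainError("loq must equal lod * (10/3.3) exactly")


# ---------------------------------------------------------------------------
# Forward model and inversion


def stern_volmer_forward(C, cal: CalibrationCurve):
    """Predicted ratio at oxygen concentration ``C`` [% air saturation].

    ``R = R0 * (alpha + (1-alpha)/(1 + Ksv*C))``; strictly decreasing in C
    while Ksv > 0 and alpha < 1, approaching the nonquenchable floor
    ``alpha*R0`` at high oxygen.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise DomainError("oxygen concentration C must be nonnegative")
    out = cal.R0 * (cal.alpha + (1.0 - cal.alpha) / (1.0 + cal.Ksv * C))
    return float(out) if out.ndim == 0 else out


def invert_calibration(R, cal: CalibrationCurve):
    """Back-calculate % air saturation from a measured ratio.

    Closed-form inverse of :func:`stern_volmer_forward` on the quenchable
    band ``alpha*R0 < R <= R0``.  Ratios above R0 indicate a reading beyond
    the zero-oxygen baseline (super-saturated signal or drift) and are
    clamped to C = 0 with a :class:`SuperSaturationWarning`; ratios at or
    below the nonquenchable floor are unrecoverable and raise.
    """
    if cal.Ksv == 0:
        raise DegenerateCalibrationError(
            f"disk {cal.disk_id!r}: Ksv == 0, ratio carries no oxygen information"
        )
    R_arr = np.asarray(R, dtype=float)
    scalar = R_arr.ndim == 0
    R_arr = np.atleast_1d(R_arr).astype(float)

    floor = cal.alpha * cal.R0
    below = R_arr <= floor
    if np.any(below):
        raise OutOfRangeError(
            f"disk {cal.disk_id!r}: ratio <= nonquenchable floor alpha*R0 = {floor:.6g}"
        )
    over = R_arr > cal.R0
    if np.any(over):
        warnings.warn(
            f"disk {cal.disk_id!r}: ratio above R0 (super-saturated indication); "
            "clamping to C = 0",
            SuperSaturationWarning,
            stacklevel=2,
        )
    C = np.empty_like(R_arr)
    ok = ~over
    C[ok] = ((1.0 - cal.alpha) / (R_arr[ok] / cal.R0 - cal.alpha) - 1.0) / cal.Ksv
    C[over] = 0.0
    # guard tiny negative round-off at R ~= R0
    C[np.abs(C) < 1e-15] = 0.0
    return float(C[0]) if scalar else C


# ---------------------------------------------------------------------------
# Fitting


def fit_calibration(
    points: Iterable[CalibrationPoint],
    fix_alpha_zero: bool = True,
    disk_id: str = "",
    ratio_def: str = "larsen",
    temperature_C: float = float("nan"),
) -> CalibrationCurve:
    """Nonlinear least-squares fit of the modified Stern-Volmer curve.

    With ``fix_alpha_zero`` (the default) the two-parameter form is fitted,
    which is what per-disk coefficient tables (R0, Ksv) report; freeing alpha
    fits the full three-parameter model and needs >= 4 distinct
    concentrations.

    The starting point is deterministic: R0 from the ratio at the lowest
    concentration, Ksv from a two-point estimate between the lowest and
    highest concentrations, alpha from 0.  No random restarts.
    """
    pts = list(points)
    if not pts:
        raise InputError("no calibration points supplied")
    C = np.array([p.true_saturation for p in pts], dtype=float)
    R = np.array([p.ratio for p in pts], dtype=float)
    n_distinct = np.unique(C).size
    n_params = 2 if fix_alpha_zero else 3
    min_distinct = 3 if fix_alpha_zero else 4
    if n_distinct < min_distinct:
        raise InputError(
            f"need >= {min_distinct} distinct concentrations for {n_params} parameters, "
            f"got {n_distinct}"
        )

    order = np.argsort(C)
    c_lo, c_hi = C[order[0]], C[order[-1]]
    R0_init = max(R[order[0]], 1e-6)
    R_hi = max(R[order[-1]], 1e-9)
    if c_hi > c_lo and R0_init > R_hi:
        Ksv_init = max((R0_init / R_hi - 1.0) / (c_hi - c_lo), 1e-9)
    else:
        Ksv_init = 1e-3
    init = [R0_init, Ksv_init] if fix_alpha_zero else [R0_init, Ksv_init, 0.0]

    if fix_alpha_zero:
        def model(c, R0, Ksv):
            return R0 / (1.0 + Ksv * c)
        bounds = ([1e-12, 0.0], [np.inf, np.inf])
    else:
        def model(c, R0, Ksv, alpha):
            return R0 * (alpha + (1.0 - alpha) / (1.0 + Ksv * c))
        bounds = ([1e-12, 0.0, 0.0], [np.inf, np.inf, 1.0 - 1e-9])

    try:
        popt, _ = optimize.curve_fit(model, C, R, p0=init, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(
            f"calibration fit for disk {disk_id!r} did not converge: {exc}",
            init=init,
            residuals=R - model(C, *init),
        ) from exc

    pred = model(C, *popt)
    resid = R - pred
    rss = float(np.sum(resid**2))
    tss = float(np.sum((R - R.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else 1.0
    dof = max(len(pts) - n_params, 1)
    resid_sd = float(np.sqrt(rss / dof))

    if fix_alpha_zero:
        R0_hat, Ksv_hat, alpha_hat = float(popt[0]), float(popt[1]), 0.0
    else:
        R0_hat, Ksv_hat, alpha_hat = (float(v) for v in popt)

    return CalibrationCurve(
        disk_id=disk_id,
        R0=R0_hat,
        Ksv=Ksv_hat,
        alpha=alpha_hat,
        ratio_def=ratio_def,
        r_squared=r_squared,
        resid_sd=resid_sd,
        temperature_C=temperature_C,
    )


# ---------------------------------------------------------------------------
# Detection-limit metrology


def back_calculate(
    points: Iterable[CalibrationPoint], cal: CalibrationCurve
) -> list[tuple[float, float]]:
    """Map calibration points through the inverted curve.

    Returns ``(true_saturation, back_calculated_saturation)`` pairs, the
    input the LOD slope regression and probe-replicate sigma work on.
    """
    return [(p.true_saturation, float(invert_calibration(p.ratio, cal))) for p in points]


def _split_replicates(probe_replicates) -> np.ndarray:
    reps = list(probe_replicates)
    if len(reps) < 2:
        raise InputError("need >= 2 probe replicates")
    first = reps[0]
    if np.ndim(first) == 0:
        return np.asarray(reps, dtype=float)
    pairs = np.asarray(reps, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise InputError("paired replicates must be (true_saturation, value) tuples")
    if np.unique(pairs[:, 0]).size != 1:
        raise InputError("probe replicates must all be at a single concentration")
    return pairs[:, 1]


def compute_detection_limits(
    probe_replicates,
    linear_points: Sequence[tuple[float, float]],
    linear_range: tuple[float, float] = (0.4, 40.0),
) -> DetectionLimits:
    """LOD/LOQ from replicate noise and the linear-range response slope.

    Parameters
    ----------
    probe_replicates
        Repeated back-calculated saturations at one probe concentration,
        either bare values or ``(true_saturation, value)`` pairs (the paired
        form lets mixed-concentration input be rejected).
    linear_points
        ``(true_saturation, back_calculated_saturation)`` pairs spanning the
        linear dynamic range (see :func:`back_calculate`).
    linear_range
        ``(low, high)`` % saturation; points outside are excluded from the
        slope regression.  Default 0.4-40 %.

    Returns
    -------
    DetectionLimits with sigma the population (n-divisor) standard deviation
    of the replicates, m the OLS slope of back-calculated vs true saturation,
    LOD = |3.3*sigma/m| and LOQ = LOD*(10/3.3).
    """
    values = _split_replicates(probe_replicates)
    sigma = float(np.std(values))  # population sd

    lin = np.asarray(list(linear_points), dtype=float)
    if lin.ndim != 2 or lin.shape[1] != 2:
        raise InputError("linear_points must be (true, back_calculated) pairs")
    lo, hi = linear_range
    keep = (lin[:, 0] >= lo) & (lin[:, 0] <= hi)
    lin = lin[keep]
    if lin.shape[0] < 2 or np.unique(lin[:, 0]).size < 2:
        raise InputError("need >= 2 distinct concentrations inside the linear range")
    slope, _ = np.polyfit(lin[:, 0], lin[:, 1], 1)
    slope = float(slope)
    # flat response: a slope indistinguishable from zero at float precision
    scale = max(np.max(np.abs(lin[:, 1])), 1.0) / max(np.max(np.abs(lin[:, 0])), 1.0)
    if not np.isfinite(slope) or abs(slope) < 1e-12 * scale:
        raise MetrologyError("zero response slope over the linear range")

    lod = abs(3.3 * sigma / slope)
    return DetectionLimits(
        sigma=sigma,
        slope_m=slope,
        lod=lod,
        loq=lod * LOQ_LOD_RATIO,
        linear_range=(float(lo), float(hi)),
    )


def summarize_lods(per_disk_lods: Sequence[float]) -> tuple[float, float]:
    """Mean and population standard deviation of per-disk detection limits."""
    vals = np.asarray(list(per_disk_lods), dtype=float)
    if vals.size < 2:
        raise InputError("need >= 2 per-disk LOD values to summarize")
    return float(np.mean(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# Comparison and normalisation


def compare_calibrations(
    samples_a: Sequence[float], samples_b: Sequence[float], alpha_level: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sample Kolmogorov-Smirnov comparison of two calibrations.

    The samples are typically back-calculated concentrations evaluated over a
    shared grid of ratio values spanning both calibrations.  Returns
    ``(ks_statistic, p_value, reject)`` with ``reject = p < alpha_level``.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("need >= 2 samples on each side")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha_level)


def normalize_ratios(ratios: Sequence[float]) -> np.ndarray:
    """Scale a list of ratios so its maximum is exactly 1."""
    vals = np.asarray(list(ratios), dtype=float)
    if vals.size == 0 or np.nanmax(vals) <= 0:
        raise NormalizationError("normalization requires at least one positive value")
    return vals / np.nanmax(vals)


# ---------------------------------------------------------------------------
# Persistence


def save_registry(path, curves: dict[str, CalibrationCurve], provenance: dict | None = None) -> None:
    """Write a calibration registry (JSON keyed by disk_id); lossless round trip."""
    payload = {}
    for disk_id, cal in curves.items():
        entry = asdict(cal)
        if provenance:
            entry["provenance"] = provenance
        payload[disk_id] = entry
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_registry(path) -> dict[str, CalibrationCurve]:
    """Read a calibration registry written by :func:`save_registry`."""
    with open(path) as fh:
        payload = json.load(fh)
    curves = {}
    for disk_id, entry in payload.items():
        entry = dict(entry)
        entry.pop("provenance", None)
        curves[disk_id] = CalibrationCurve(**entry)
    return curves


def read_points_csv(path) -> dict[str, list[CalibrationPoint]]:
    """Read calibration points grouped by disk.

    Expected columns: ``disk_id, true_saturation_pct, ratio, replicate_id``
    (``replicate_id`` optional).
    """
    df = pd.read_csv(path)
    required = {"disk_id", "true_saturation_pct", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"calibration CSV missing columns: {sorted(missing)}")
    if "replicate_id" not in df.columns:
        df["replicate_id"] = 0
    out: dict[str, list[CalibrationPoint]] = {}
    for i, row in df.iterrows():
        try:
            pt = CalibrationPoint(
                true_saturation=float(row["true_saturation_pct"]),
                ratio=float(row["ratio"]),
                replicate_id=int(row["replicate_id"]),
            )
        except (TypeError, ValueError, DomainError) as exc:
            raise InputError(f"malformed calibration CSV row {i + 2}: {exc}") from exc
        out.setdefault(str(row["disk_id"]), []).append(pt)
    return out
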