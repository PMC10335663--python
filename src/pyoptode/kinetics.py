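"""Phase segmentation and oxygen-consumption rate estimation.

A sealed-reactor incubation typically shows up to three successive regimes
in its dissolved-oxygen trace: an early nonlinear (first-order-to-oxygen)
decline, a linear (zero-order) decline once the fast processes stop, and a
flat near-zero tail once the system goes anoxic and consumption becomes
oxygen-limited.  This module masks outliers, finds the phase boundaries by
an exhaustive changepoint search scored with a small-sample information
criterion, and fits per-phase rates:

* first-order phase: ``C(t) = B + A*exp(-k*(t-t0))``, reporting k [1/min];
* zero-order phase: straight-line fit, reporting consumption [mg/(L*hr)]
  as a positive number;
* anoxic phase: onset time, reported only when the tail really sits below
  the detection/quantification threshold.

Because reactors are not gas tight, the observed decline understates the
true metabolic consumption: oxygen leaks in while the interior is below
ambient equilibrium.  With ``correct_diffusion`` the pointwise metabolic
rate ``u = -dC/dt + influx(C)`` is formed (central differences, then the
reactor's permeability model) and the per-phase rates are fitted on ``u``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .calibration import DetectionLimits
from .errors import InputError, MaskFractionWarning
from .gas_exchange import (
    EnvironmentConditions,
    ReactorSpec,
    ambient_o2_pressure,
    influx_rate,
    o2_solubility,
    sat_to_conc,
)

__all__ = [
    "OxygenTimeSeries",
    "PhaseSegmentation",
    "RateEstimate",
    "mask_outliers",
    "segment_phases",
    "estimate_rates",
    "read_timeseries_csv",
]

PHASE_FIRST_ORDER = "first_order"
PHASE_ZERO_ORDER = "zero_order"
PHASE_ANOXIC = "anoxic"

# candidate ordered phase sequences (oxic decline can only move toward anoxia)
_LABEL_SETS = {
    0: [(PHASE_FIRST_ORDER,), (PHASE_ZERO_ORDER,), (PHASE_ANOXIC,)],
    1: [
        (PHASE_FIRST_ORDER, PHASE_ZERO_ORDER),
        (PHASE_FIRST_ORDER, PHASE_ANOXIC),
        (PHASE_ZERO_ORDER, PHASE_ANOXIC),
    ],
    2: [(PHASE_FIRST_ORDER, PHASE_ZERO_ORDER, PHASE_ANOXIC)],
}

_N_PARAMS = {PHASE_FIRST_ORDER: 3, PHASE_ZERO_ORDER: 2, PHASE_ANOXIC: 1}


@dataclass
class OxygenTimeSeries:
    """Per-reactor dissolved-oxygen trace with its environment and QC mask.

    ``qc_mask`` is True for valid points; masked points are carried but
    ignored by segmentation and rate fitting.
    """

    tube_id: str
    times_min: np.ndarray
    conc_mg_L: np.ndarray
    env: EnvironmentConditions
    reactor: ReactorSpec | None = None
    qc_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.conc_mg_L = np.asarray(self.conc_mg_L, dtype=float)
        if self.times_min.shape != self.conc_mg_L.shape:
            raise InputError("times_min and conc_mg_L must have equal length")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise InputError("times_min must be strictly increasing")
        if self.qc_mask is None:
            self.qc_mask = np.isfinite(self.conc_mg_L)
        else:
            self.qc_mask = np.asarray(self.qc_mask, dtype=bool)
            if self.qc_mask.shape != self.times_min.shape:
                raise InputError("qc_mask must match series length")
        if np.any(self.conc_mg_L[self.qc_mask] < -1e-9):
            raise InputError("unmasked concentrations must be nonnegative")

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations at unmasked points."""
        return self.times_min[self.qc_mask], self.conc_mg_L[self.qc_mask]


@dataclass
class PhaseSegmentation:
    """Recovered phase structure: 0-2 breakpoints and ordered phase labels."""

    breakpoints: tuple[float, ...]
    phase_labels: tuple[str, ...]
    ic_score: float = float("nan")
    fallback: bool = False

    def __post_init__(self) -> None:
        if len(self.phase_labels) != len(self.breakpoints) + 1:
            raise InputError("need exactly one more phase label than breakpoints")
        if len(self.breakpoints) > 1 and self.breakpoints[1] <= self.breakpoints[0]:
            raise InputError("breakpoints must be increasing")


@dataclass
class RateEstimate:
    """Per-phase kinetic parameters; absent phases are None, never zero."""

    tube_id: str = ""
    zero_order_slope: float | None = None  # mg/(L*hr), consumption positive
    first_order_k: float | None = None  # 1/min
    anoxia_onset_min: float | None = None
    diffusion_corrected: bool = False
    phase_rmse: dict = field(default_factory=dict)  # label -> mg/L


# ---------------------------------------------------------------------------
# Outlier masking


def mask_outliers(series: OxygenTimeSeries, window: int = 5, k_mad: float = 3.5) -> np.ndarray:
    """Rolling-median / MAD outlier mask.  Returns True for points to keep.

    Hampel-style filter: a point is rejected when its deviation from the
    centered rolling median exceeds ``k_mad`` times the rolling MAD (median
    absolute deviation within the same window).  The local MAD keeps steep
    but smooth stretches of a curve from being flagged wholesale.  Windows
    with MAD 0 (locally constant data) mask nothing.  A warning is emitted
    if more than 20 % of points would be dropped.
    """
    if window < 3 or window % 2 == 0:
        raise InputError("window must be odd and >= 3")
    n = series.times_min.size
    if n < window:
        raise InputError(f"series of {n} points shorter than window {window}")
    c = pd.Series(series.conc_mg_L)
    roll = c.rolling(window, center=True, min_periods=1)
    rolling_med = roll.median().to_numpy()
    rolling_mad = roll.apply(lambda w: np.nanmedian(np.abs(w - np.nanmedian(w))), raw=True)
    rolling_mad = rolling_mad.to_numpy()
    dev = np.abs(series.conc_mg_L - rolling_med)
    keep = series.qc_mask.copy()
    with np.errstate(invalid="ignore"):
        keep &= ~((rolling_mad > 0) & (dev > k_mad * rolling_mad))
    frac_removed = 1.0 - keep.sum() / max(series.qc_mask.sum(), 1)
    if frac_removed > 0.20:
        warnings.warn(
            f"outlier mask removed {frac_removed:.0%} of points (> 20%); "
            "inspect the series before trusting downstream rates",
            MaskFractionWarning,
            stacklevel=2,
        )
    return keep


# ---------------------------------------------------------------------------
# Segment models


def _fit_constant(t: np.ndarray, c: np.ndarray) -> tuple[float, np.ndarray]:
    mu = float(np.mean(c))
    return mu, c - mu


def _fit_linear(t: np.ndarray, c: np.ndarray) -> tuple[tuple[float, float], np.ndarray]:
    slope, icpt = np.polyfit(t, c, 1)
    return (float(slope), float(icpt)), c - (slope * t + icpt)


def _fit_exponential(t: np.ndarray, c: np.ndarray) -> tuple[tuple[float, float, float], np.ndarray]:
    """Fit C = B + A*exp(-k*(t - t[0])); raises on failure."""
    t0 = t[0]
    B0 = float(np.min(c))
    A0 = max(float(c[0] - B0), 1e-9)
    span = max(t[-1] - t0, 1e-9)
    # decay-rate guess from the fraction of the drop completed at mid-span
    k0 = 2.0 / span
    popt, _ = optimize.curve_fit(
        lambda tt, A, k, B: B + A * np.exp(-k * (tt - t0)),
        t,
        c,
        p0=[A0, k0, B0],
        bounds=([0.0, 0.0, -np.inf], [np.inf, 10.0, np.inf]),
        maxfev=1500,
    )
    A, k, B = (float(v) for v in popt)
    resid = c - (B + A * np.exp(-k * (t - t0)))
    return (A, k, B), resid


def _segment_rss(label: str, t: np.ndarray, c: np.ndarray) -> float:
    try:
        if label == PHASE_ANOXIC:
            _, resid = _fit_constant(t, c)
        elif label == PHASE_ZERO_ORDER:
            _, resid = _fit_linear(t, c)
        else:
            _, resid = _fit_exponential(t, c)
    except (RuntimeError, ValueError):
        return np.inf
    return float(np.sum(resid**2))


def _aicc(rss: float, n: int, k_params: int, rss_floor: float = 1e-300) -> float:
    """Gaussian AICc; k_params counts model parameters incl. breakpoints.

    ``rss_floor`` clamps numerically-perfect fits to a common value so that
    on noiseless data the tie is broken by the parameter-count penalty
    (fewest parameters wins) instead of floating-point residue.
    """
    k = k_params + 1  # + noise variance
    if n - k - 1 <= 0 or not np.isfinite(rss):
        return np.inf
    rss = max(rss, rss_floor)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def segment_phases(
    series: OxygenTimeSeries, min_seg_points: int = 4, max_breakpoints: int = 2
) -> PhaseSegmentation:
    """Exhaustive changepoint search over 0-2 breakpoints on observation times.

    Every admissible (breakpoints, phase-label) combination is fitted by
    least squares segment-by-segment and scored with AICc; the best score
    wins.  Deterministic: grid search over observed times, no randomness.
    Falls back to a single flagged linear phase when no multi-segment
    candidate leaves >= ``min_seg_points`` points per segment.
    """
    t, c = series.valid()
    n = t.size
    if n < 8:
        raise InputError(f"need >= 8 unmasked points to segment, got {n}")

    scale = max(float(np.max(np.abs(c))), 1.0)
    rss_floor = n * (1e-10 * scale) ** 2

    cache: dict[tuple[str, int, int], float] = {}

    def rss(label: str, i0: int, i1: int) -> float:
        key = (label, i0, i1)
        if key not in cache:
            cache[key] = _segment_rss(label, t[i0:i1], c[i0:i1])
        return cache[key]

    best = None  # (score, breakpoints, labels)
    for labels in _LABEL_SETS[0]:
        score = _aicc(rss(labels[0], 0, n), n, _N_PARAMS[labels[0]], rss_floor)
        if best is None or score < best[0]:
            best = (score, (), labels)

    if max_breakpoints >= 1:
        for i in range(min_seg_points, n - min_seg_points + 1):
            for labels in _LABEL_SETS[1]:
                total = rss(labels[0], 0, i) + rss(labels[1], i, n)
                k_params = _N_PARAMS[labels[0]] + _N_PARAMS[labels[1]] + 1
                score = _aicc(total, n, k_params, rss_floor)
                if score < best[0]:
                    best = (score, (float(t[i]),), labels)

    if max_breakpoints >= 2 and n >= 3 * min_seg_points:
        labels = _LABEL_SETS[2][0]
        k_params = sum(_N_PARAMS[lab] for lab in labels) + 2
        for i in range(min_seg_points, n - 2 * min_seg_points + 1):
            rss_fo = rss(PHASE_FIRST_ORDER, 0, i)
            if not np.isfinite(rss_fo):
                continue
            for j in range(i + min_seg_points, n - min_seg_points + 1):
                total = (
                    rss_fo
                    + rss(PHASE_ZERO_ORDER, i, j)
                    + rss(PHASE_ANOXIC, j, n)
                )
                score = _aicc(total, n, k_params, rss_floor)
                if score < best[0]:
                    best = (score, (float(t[i]), float(t[j])), labels)

    score, bps, labels = best
    if not np.isfinite(score):
        # nothing fit cleanly: single-phase linear with a flag
        return PhaseSegmentation(
            breakpoints=(), phase_labels=(PHASE_ZERO_ORDER,), ic_score=score, fallback=True
        )
    return PhaseSegmentation(breakpoints=bps, phase_labels=labels, ic_score=score)


# ---------------------------------------------------------------------------
# Rate estimation


def _phase_slices(seg: PhaseSegmentation, t: np.ndarray) -> list[tuple[str, np.ndarray]]:
    edges = (-np.inf, *seg.breakpoints, np.inf)
    out = []
    for label, lo, hi in zip(seg.phase_labels, edges[:-1], edges[1:]):
        out.append((label, (t >= lo) & (t < hi)))
    return out


def _central_differences(t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """dC/dt [mg/(L*min)] by central differences (one-sided at the ends)."""
    return np.gradient(c, t)


def estimate_rates(
    series: OxygenTimeSeries,
    seg: PhaseSegmentation,
    correct_diffusion: bool = False,
    detection_limits: DetectionLimits | None = None,
) -> RateEstimate:
    """Fit per-phase kinetic parameters for a segmented series.

    Zero-order consumption is the least-squares slope of the linear phase
    (sign-flipped so consumption is positive, in mg/(L*hr)); the first-order
    constant k comes from an exponential fit to the first phase.  With
    ``correct_diffusion`` the pointwise metabolic rate
    ``u = -dC/dt + influx(C)`` is formed first and the rates are fitted on
    it: the zero-order rate as the mean of u over the linear phase, k by
    regressing u on C through the origin.  Anoxia onset is the start of the
    constant phase, reported only if that phase's mean concentration is
    below the LOQ (when supplied) or below 5 % air saturation otherwise.
    """
    if correct_diffusion and series.reactor is None:
        raise InputError("diffusion correction requires the series to reference a reactor")
    t, c = series.valid()
    est = RateEstimate(tube_id=series.tube_id, diffusion_corrected=bool(correct_diffusion))

    if detection_limits is not None:
        anoxia_thresh = sat_to_conc(detection_limits.loq, series.env)
    else:
        anoxia_thresh = sat_to_conc(5.0, series.env)

    # series entirely below the detection threshold: anoxic from the start,
    # no rates are meaningful
    if t.size and np.all(c < anoxia_thresh):
        est.anoxia_onset_min = float(t[0])
        _, resid = _fit_constant(t, c)
        est.phase_rmse[PHASE_ANOXIC] = float(np.sqrt(np.mean(resid**2)))
        return est

    for label, sl in _phase_slices(seg, t):
        ts, cs = t[sl], c[sl]
        if ts.size < 2:
            continue
        if correct_diffusion:
            # per-segment differences: a global gradient would straddle the
            # kinks at phase boundaries and bleed one phase's rate into the next
            dcdt = _central_differences(ts, cs)
            influx = np.array(
                [influx_rate(ci, series.env, series.reactor) / 60.0 for ci in cs]
            )  # mg/(L*min)
            useg = -dcdt + influx  # metabolic consumption, mg/(L*min)
        if label == PHASE_ZERO_ORDER:
            (slope, icpt), resid = _fit_linear(ts, cs)
            if correct_diffusion:
                us = useg
                est.zero_order_slope = float(np.mean(us) * 60.0)
                resid = us - np.mean(us)
            else:
                est.zero_order_slope = float(-slope * 60.0)
            est.phase_rmse[label] = float(np.sqrt(np.mean(resid**2)))
        elif label == PHASE_FIRST_ORDER:
            if correct_diffusion:
                us = useg
                denom = float(np.sum(cs**2))
                if denom > 0:
                    est.first_order_k = float(np.sum(us * cs) / denom)
                    resid = us - est.first_order_k * cs
                    est.phase_rmse[label] = float(np.sqrt(np.mean(resid**2)))
            else:
                try:
                    (A, k, B), resid = _fit_exponential(ts, cs)
                except (RuntimeError, ValueError):
                    continue
                est.first_order_k = k
                est.phase_rmse[label] = float(np.sqrt(np.mean(resid**2)))
        elif label == PHASE_ANOXIC:
            mu, resid = _fit_constant(ts, cs)
            if mu < anoxia_thresh:
                est.anoxia_onset_min = float(ts[0])
                est.phase_rmse[label] = float(np.sqrt(np.mean(resid**2)))
    return est


# ---------------------------------------------------------------------------
# I/O


def read_timeseries_csv(
    path,
    env: EnvironmentConditions,
    reactor: ReactorSpec | None = None,
) -> dict[str, OxygenTimeSeries]:
    """Read per-tube series from CSV with columns tube_id, time_min, conc_mg_L."""
    df = pd.read_csv(path)
    required = {"tube_id", "time_min", "conc_mg_L"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"time-series CSV missing columns: {sorted(missing)}")
    out = {}
    for tube_id, grp in df.groupby("tube_id", sort=True):
        grp = grp.sort_values("time_min")
        out[str(tube_id)] = OxygenTimeSeries(
            tube_id=str(tube_id),
            times_min=grp["time_min"].to_numpy(dtype=float),
            conc_mg_L=grp["conc_mg_L"].to_numpy(dtype=float),
            env=env,
            reactor=reactor,
        )
    return out
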