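"""Oxygen solubility, unit conversions, and reactor gas-exchange modelling.

Dissolved-oxygen bookkeeping is done in two unit systems: % air saturation
(what a ratiometric optode reports after calibration) and mg/L (what rate
estimates are expressed in).  The bridge between them is the equilibrium
solubility of oxygen in fresh water at the ambient temperature and pressure,
computed with the Benson-Krause virial formulation that standard solubility
tables (e.g. USGS) are built on.

Sealed reactors are not perfectly gas tight: oxygen leaks in through tube
walls, cap and O-ring at a rate proportional to the partial-pressure
difference between room air and the water inside.  With the membrane area
and thickness absorbed into a single whole-tube permeability ``r``
[mg/(min*bar)], the interior partial pressure ``p_i`` obeys

    dp_i/dt = r * (p_a - p_i) / (H * V)

whose solution, written in concentration units (C = p*H), is an exponential
approach to ambient equilibrium:

    C(t) = p_a*H - (p_a - p_0)*H * exp(-r*t / (H*V))

``fit_permeability`` estimates ``r`` (with the initial pressure ``p_0`` and
Henry solubility ``H`` co-fitted as nuisance parameters) from a tube-flush
experiment: fill with deoxygenated water, seal, and watch oxygen creep back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize, stats

from .errors import DomainError, ExtrapolationWarning, FitError, IdentifiabilityWarning, InputError

__all__ = [
    "EnvironmentConditions",
    "ReactorSpec",
    "DiffusionFit",
    "o2_solubility",
    "sat_to_conc",
    "conc_to_sat",
    "salinity_correct",
    "ambient_o2_pressure",
    "diffusion_model",
    "fit_permeability",
    "influx_rate",
    "compare_permeability_groups",
    "default_reactor_library",
    "load_reactor_library",
    "dump_reactor_library",
]

#: Mole fraction of O2 in dry air.
O2_MOLE_FRACTION = 0.2095

#: Reference atmospheric pressure [mbar] for the solubility formula.
REFERENCE_PRESSURE_MBAR = 1013.25

# Benson & Krause virial coefficients for O2 solubility in fresh water
# (mg/L at 1 atm moist air), T in kelvin.
_BK_COEFFS = (-139.34411, 1.575701e5, -6.642308e7, 1.243800e10, -8.621949e11)


@dataclass(frozen=True)
class EnvironmentConditions:
    """Ambient conditions a measurement was made under.

    Parameters
    ----------
    temperature_C : float
        Water/room temperature in deg C; the solubility formula is applied
        within 0-40 deg C.
    pressure_mbar : float
        Barometric pressure in millibar.
    salinity_pct : float
        NaCl content in % m/v; the salinity correction is calibrated over
        0-3.5 % m/v.
    """

    temperature_C: float
    pressure_mbar: float = REFERENCE_PRESSURE_MBAR
    salinity_pct: float = 0.0

    def __post_init__(self) -> None:
        if not self.pressure_mbar > 0:
            raise DomainError(f"pressure_mbar must be positive, got {self.pressure_mbar}")
        if not (0.0 <= self.temperature_C <= 40.0):
            raise DomainError(
                f"temperature_C={self.temperature_C} outside the supported 0-40 degC range"
            )
        if self.salinity_pct < 0:
            raise DomainError(f"salinity_pct must be nonnegative, got {self.salinity_pct}")


@dataclass
class ReactorSpec:
    """A reactor tube: its type, water volume, and whole-tube O2 permeability."""

    reactor_type: str
    volume_L: float
    permeability_r: float  # mg/(min*bar), whole tube

    def __post_init__(self) -> None:
        if not self.volume_L > 0:
            raise DomainError(f"volume_L must be positive, got {self.volume_L}")
        if self.permeability_r < 0:
            raise DomainError(f"permeability_r must be nonnegative, got {self.permeability_r}")


@dataclass
class DiffusionFit:
    """Result of fitting the gas-ingress model to a tube-flush time series."""

    r: float  # mg/(min*bar)
    p0: float  # bar
    H: float  # mg/(L*bar)
    rmse: float  # mg/L
    n_points: int
    r_identifiable: bool = True

    def __post_init__(self) -> None:
        if self.r < 0:
            raise DomainError(f"r must be nonnegative, got {self.r}")
        if not self.H > 0:
            raise DomainError(f"H must be positive, got {self.H}")
        if self.rmse < 0:
            raise DomainError(f"rmse must be nonnegative, got {self.rmse}")


# ---------------------------------------------------------------------------
# Solubility and unit conversions


def o2_solubility(env: EnvironmentConditions) -> float:
    """Equilibrium DO concentration [mg/L] at 100 % air saturation.

    Benson-Krause fresh-water solubility at ``env.temperature_C``, scaled
    linearly by ``pressure_mbar / 1013.25``.  Salinity is handled separately
    by :func:`salinity_correct`.
    """
    t_K = env.temperature_C + 273.15
    a0, a1, a2, a3, a4 = _BK_COEFFS
    ln_c = a0 + a1 / t_K + a2 / t_K**2 + a3 / t_K**3 + a4 / t_K**4
    return float(np.exp(ln_c) * env.pressure_mbar / REFERENCE_PRESSURE_MBAR)


def sat_to_conc(pct_sat: float, env: EnvironmentConditions) -> float:
    """Convert % air saturation to mg/L under ``env``."""
    pct = np.asarray(pct_sat, dtype=float)
    if np.any(pct < 0):
        raise DomainError("pct_sat must be nonnegative")
    out = pct / 100.0 * o2_solubility(env)
    return float(out) if out.ndim == 0 else out


def conc_to_sat(mg_per_L: float, env: EnvironmentConditions) -> float:
    """Convert mg/L to % air saturation under ``env``. Inverse of :func:`sat_to_conc`."""
    conc = np.asarray(mg_per_L, dtype=float)
    out = conc / o2_solubility(env) * 100.0
    return float(out) if out.ndim == 0 else out


def salinity_correct(do_mg_L: float, env: EnvironmentConditions) -> float:
    """Salinity-corrected DO: ``DO_salt = DO - q*S``.

    ``q = -0.1903*t + 12.892`` with t in deg C, and S the NaCl mass fraction
    (``salinity_pct / 100``).  Calibrated over 0-3.5 % m/v; outside that
    range the linear form is extrapolated with a warning.
    """
    if env.salinity_pct > 3.5:
        warnings.warn(
            f"salinity {env.salinity_pct}% m/v outside the calibrated 0-3.5% range; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    q = -0.1903 * env.temperature_C + 12.892
    return do_mg_L - q * (env.salinity_pct / 100.0)


def ambient_o2_pressure(env: EnvironmentConditions) -> float:
    """Ambient O2 partial pressure [bar]: 0.2095 x total pressure."""
    return O2_MOLE_FRACTION * env.pressure_mbar / 1000.0


# ---------------------------------------------------------------------------
# Diffusion (gas-ingress) model


def diffusion_model(
    t: np.ndarray | float, pa: float, p0: float, H: float, V: float, r: float
) -> np.ndarray | float:
    """Interior DO concentration [mg/L] at time ``t`` [min] for a sealed tube.

    ``pa*H - (pa - p0)*H*exp(-r*t/(H*V))``: exponential approach from the
    initial concentration ``p0*H`` to ambient equilibrium ``pa*H``.
    """
    if not V > 0:
        raise DomainError(f"V must be positive, got {V}")
    if not H > 0:
        raise DomainError(f"H must be positive, got {H}")
    if r < 0:
        raise DomainError(f"r must be nonnegative, got {r}")
    t = np.asarray(t, dtype=float)
    out = pa * H - (pa - p0) * H * np.exp(-r * t / (H * V))
    return float(out) if out.ndim == 0 else out


def fit_permeability(
    times: Sequence[float],
    concs: Sequence[float],
    V: float,
    pa: float,
    init: tuple[float, float, float] | None = None,
) -> DiffusionFit:
    """Least-squares fit of the gas-ingress curve with ``r, p0, H`` free.

    Parameters
    ----------
    times, concs : sequences
        Elapsed minutes (strictly increasing) and DO in mg/L.
    V : float
        Tube water volume in litres (held fixed).
    pa : float
        Ambient O2 partial pressure in bar (held fixed).
    init : (r, p0, H), optional
        Starting point; a data-driven default is derived otherwise.

    Notes
    -----
    A series that never departs from its own mean carries no information
    about ``r``; such fits are returned with ``r_identifiable=False`` and a
    warning instead of an arbitrary rate.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise InputError("times and concs must be equal-length 1-D sequences")
    if t.size < 4:
        raise InputError(f"need >= 4 points to fit 3 parameters, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")

    if init is None:
        H0 = max(c.max() / pa, 1.0) if c.max() > 0 else 40.0
        H0 = max(H0, 40.0)
        p0_init = max(c[0] / H0, 0.0)
        # crude rate guess from the first-step slope of the exponential
        gap0 = pa - p0_init
        if gap0 > 0 and c.size > 1 and c[1] > c[0]:
            r0 = (c[1] - c[0]) / (t[1] - t[0]) / gap0 * V
        else:
            r0 = 1e-3
        init = (max(r0, 1e-6), p0_init, H0)

    flat = np.ptp(c) < 1e-3 * max(np.max(np.abs(c)), 1.0)

    def model(tt, r, p0, H):
        return pa * H - (pa - p0) * H * np.exp(-r * tt / (H * V))

    try:
        popt, pcov = optimize.curve_fit(
            model,
            t,
            c,
            p0=init,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(
            f"permeability fit did not converge: {exc}",
            init=init,
            residuals=c - model(t, *init),
        ) from exc

    r_hat, p0_hat, H_hat = (float(v) for v in popt)
    resid = c - model(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))

    identifiable = not flat
    with np.errstate(invalid="ignore"):
        r_sd = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.inf
    if r_hat > 0 and r_sd / r_hat > 10:
        identifiable = False
    if not identifiable:
        warnings.warn(
            "diffusion series is (nearly) flat: permeability r is not identifiable "
            "from these data",
            IdentifiabilityWarning,
            stacklevel=2,
        )

    return DiffusionFit(
        r=r_hat, p0=p0_hat, H=H_hat, rmse=rmse, n_points=int(t.size), r_identifiable=identifiable
    )


def influx_rate(
    conc_inside: float, env: EnvironmentConditions, reactor: ReactorSpec, H: float | None = None
) -> float:
    """Oxygen ingress rate [mg/(L*hr)] at the given interior concentration.

    ``60 * r * (pa - p_i) / V`` with ``p_i = conc_inside / H``.  Positive when
    the interior is below ambient equilibrium (oxygen leaking in), negative
    above it.  The worst case is a fully anoxic interior (``conc_inside=0``).
    """
    if H is None:
        H = o2_solubility(env) / ambient_o2_pressure(env)
    pa = ambient_o2_pressure(env)
    p_i = conc_inside / H
    return 60.0 * reactor.permeability_r * (pa - p_i) / reactor.volume_L


def compare_permeability_groups(
    fits_a: Sequence[DiffusionFit], fits_b: Sequence[DiffusionFit]
) -> tuple[float, float]:
    """Welch two-sample t-test on the fitted permeabilities of two groups.

    Used to decide whether, e.g., rolled and static tubes leak at different
    rates.  Returns ``(t_statistic, p_value)``.
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise InputError("need >= 2 fits per group")
    ra = np.array([f.r for f in fits_a], dtype=float)
    rb = np.array([f.r for f in fits_b], dtype=float)
    if np.ptp(ra) == 0 and np.ptp(rb) == 0:
        warnings.warn("both groups have zero variance; t-test is degenerate", stacklevel=2)
        return 0.0, 1.0
    res = stats.ttest_ind(ra, rb, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Reactor library

_DEFAULT_REACTORS = {
    "plastic_centrifuge_50ml": {"volume_L": 0.050, "permeability_r": 3.02e-3},
    "glass_voa_40ml": {"volume_L": 0.040, "permeability_r": 1.75e-3},
    "double_ended_voa_40ml": {"volume_L": 0.040, "permeability_r": 9.44e-4},
}


def default_reactor_library() -> dict[str, ReactorSpec]:
    """Built-in reactor types with their measured whole-tube permeabilities."""
    return {
        name: ReactorSpec(reactor_type=name, **params)
        for name, params in _DEFAULT_REACTORS.items()
    }


def load_reactor_library(path) -> dict[str, ReactorSpec]:
    """Read a reactor library from YAML ({name: {volume_L, permeability_r}})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InputError(f"reactor library {path} must be a mapping of reactor names")
    lib = {}
    for name, params in raw.items():
        try:
            lib[name] = ReactorSpec(
                reactor_type=name,
                volume_L=float(params["volume_L"]),
                permeability_r=float(params["permeability_r"]),
            )
        except (KeyError, TypeError) as exc:
            raise InputError(f"reactor {name!r}: expected volume_L and permeability_r") from exc
    return lib


def dump_reactor_library(path, library: dict[str, ReactorSpec] | None = None) -> None:
    """Write a reactor library (defaults if none given) to YAML."""
    if library is None:
        library = default_reactor_library()
    raw = {
        name: {"volume_L": spec.volume_L, "permeability_r": spec.permeability_r}
        for name, spec in library.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
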