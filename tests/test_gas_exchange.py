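"""Solubility, unit conversion, salinity, and the gas-ingress model."""

import warnings

import numpy as np
import pytest

from pyoptode import (
    DiffusionFit,
    EnvironmentConditions,
    ReactorSpec,
    ambient_o2_pressure,
    compare_permeability_groups,
    conc_to_sat,
    default_reactor_library,
    diffusion_model,
    fit_permeability,
    influx_rate,
    o2_solubility,
    salinity_correct,
    sat_to_conc,
)
from pyoptode.errors import DomainError, ExtrapolationWarning, IdentifiabilityWarning, InputError
from pyoptode.gas_exchange import dump_reactor_library, load_reactor_library

from conftest import PERMEABILITY

# Published fresh-water O2 solubility at 1 atm (USGS tables), mg/L
USGS_SOLUBILITY = {0.0: 14.621, 10.0: 11.288, 20.0: 9.092, 25.0: 8.263, 30.0: 7.559}


class TestSolubility:
    @pytest.mark.parametrize("temp, expected", sorted(USGS_SOLUBILITY.items()))
    def test_matches_published_tables(self, temp, expected):
        env = EnvironmentConditions(temperature_C=temp, pressure_mbar=1013.25)
        assert o2_solubility(env) == pytest.approx(expected, abs=5e-3)

    def test_nominal_lab_conditions(self, env21):
        assert o2_solubility(env21) == pytest.approx(8.9, abs=0.05)

    def test_linear_pressure_scaling(self):
        lo = o2_solubility(EnvironmentConditions(21.0, 900.0))
        hi = o2_solubility(EnvironmentConditions(21.0, 1800.0))
        assert hi == pytest.approx(2 * lo, rel=1e-12)

    def test_monotone_decreasing_in_temperature(self):
        s = [o2_solubility(EnvironmentConditions(t)) for t in np.linspace(0, 40, 9)]
        assert np.all(np.diff(s) < 0)

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(DomainError):
            EnvironmentConditions(temperature_C=55.0)


class TestUnitConversion:
    def test_low_saturation_equivalents(self, env21):
        assert round(sat_to_conc(3.0, env21), 2) == 0.27
        assert round(sat_to_conc(1.1, env21), 1) == 0.1

    def test_zero_maps_to_zero(self, env21):
        assert sat_to_conc(0.0, env21) == 0.0

    def test_mutual_inverses(self, env21):
        sats = np.linspace(0, 120, 25)
        back = conc_to_sat(sat_to_conc(sats, env21), env21)
        assert back == pytest.approx(sats, rel=1e-12)

    def test_negative_saturation_rejected(self, env21):
        with pytest.raises(DomainError):
            sat_to_conc(-1.0, env21)


class TestSalinity:
    def test_freshwater_identity(self):
        env = EnvironmentConditions(20.0, salinity_pct=0.0)
        assert salinity_correct(9.0, env) == 9.0

    def test_q_coefficient_at_20C(self):
        # q = -0.1903*20 + 12.892 = 9.086; at S=1% m/v the correction is q/100
        env = EnvironmentConditions(20.0, salinity_pct=1.0)
        assert 9.0 - salinity_correct(9.0, env) == pytest.approx(0.09086, rel=1e-9)

    def test_full_strength_correction(self):
        env = EnvironmentConditions(20.0, salinity_pct=3.5)
        assert salinity_correct(9.0, env) == pytest.approx(8.682, abs=5e-4)

    def test_extrapolation_warns(self):
        env = EnvironmentConditions(20.0, salinity_pct=5.0)
        with pytest.warns(ExtrapolationWarning):
            salinity_correct(9.0, env)


class TestDiffusionModel:
    PA, P0, H, V, R = 0.2123, 0.005, 43.0, 0.05, 3.02e-3

    def test_initial_condition(self):
        assert diffusion_model(0.0, self.PA, self.P0, self.H, self.V, self.R) == pytest.approx(
            self.P0 * self.H
        )

    def test_ambient_asymptote(self):
        assert diffusion_model(1e9, self.PA, self.P0, self.H, self.V, self.R) == pytest.approx(
            self.PA * self.H
        )

    def test_sealed_tube_limit(self):
        t = np.linspace(0, 1000, 11)
        c = diffusion_model(t, self.PA, self.P0, self.H, self.V, 0.0)
        assert c == pytest.approx(np.full_like(t, self.P0 * self.H))

    def test_satisfies_governing_ode(self):
        """dC/dt must equal r*(pa - p_i)/V along the solution."""
        t = np.linspace(0, 500, 20001)
        c = diffusion_model(t, self.PA, self.P0, self.H, self.V, self.R)
        dcdt = np.gradient(c, t)
        p_i = c / self.H
        expected = self.R * (self.PA - p_i) / self.V
        assert dcdt[1:-1] == pytest.approx(expected[1:-1], rel=1e-4)


class TestPermeabilityFit:
    def test_exact_recovery_of_published_plastic_tube_rate(self, env21):
        pa = ambient_o2_pressure(env21)
        t = np.arange(0, 24 * 60 + 1, 15.0)
        truth_r = PERMEABILITY["plastic_centrifuge_50ml"]
        c = diffusion_model(t, pa, 0.005, 43.0, 0.05, truth_r)
        fit = fit_permeability(t, c, V=0.05, pa=pa)
        assert fit.r == pytest.approx(truth_r, rel=1e-6)
        assert fit.p0 == pytest.approx(0.005, rel=1e-6)
        assert fit.H == pytest.approx(43.0, rel=1e-6)
        assert fit.r_identifiable

    def test_flat_series_flagged_unidentifiable(self, env21):
        pa = ambient_o2_pressure(env21)
        t = np.arange(0, 600, 15.0)
        c = np.full_like(t, pa * 43.0)
        with pytest.warns(IdentifiabilityWarning):
            fit = fit_permeability(t, c, V=0.05, pa=pa)
        assert not fit.r_identifiable

    def test_too_few_points_rejected(self, env21):
        with pytest.raises(InputError):
            fit_permeability([0, 1, 2], [1, 2, 3], V=0.05, pa=0.21)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(InputError):
            fit_permeability([0, 10, 5, 20], [1, 2, 3, 4], V=0.05, pa=0.21)


class TestInflux:
    def test_zero_gradient_at_equilibrium(self, env21):
        reactor = default_reactor_library()["plastic_centrifuge_50ml"]
        eq = o2_solubility(env21)  # 100% air saturation
        assert influx_rate(eq, env21, reactor) == pytest.approx(0.0, abs=1e-12)

    def test_worst_case_order_of_magnitude(self, env21):
        # anoxic interior, plastic tube: published framing value is 0.60 mg/(L*hr)
        reactor = default_reactor_library()["plastic_centrifuge_50ml"]
        rate = influx_rate(0.0, env21, reactor)
        assert 0.2 < rate < 2.0

    def test_doubling_volume_halves_rate(self, env21):
        r1 = ReactorSpec("custom", volume_L=0.05, permeability_r=3.02e-3)
        r2 = ReactorSpec("custom", volume_L=0.10, permeability_r=3.02e-3)
        assert influx_rate(0.0, env21, r1) == pytest.approx(2 * influx_rate(0.0, env21, r2))

    def test_antisymmetric_about_equilibrium(self, env21):
        reactor = default_reactor_library()["glass_voa_40ml"]
        eq = o2_solubility(env21)
        lo = influx_rate(eq - 2.0, env21, reactor)
        hi = influx_rate(eq + 2.0, env21, reactor)
        assert lo > 0 > hi
        assert lo == pytest.approx(-hi)


class TestGroupComparison:
    def _fits(self, rs):
        return [DiffusionFit(r=r, p0=0.005, H=43.0, rmse=0.05, n_points=97) for r in rs]

    def test_identical_groups(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = compare_permeability_groups(
                self._fits([3e-3, 3e-3]), self._fits([3e-3, 3e-3])
            )
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_extreme_separation(self):
        a = self._fits([3.0e-3, 3.1e-3, 2.9e-3])
        b = self._fits([1.0e-3, 1.1e-3, 0.9e-3])
        _, p = compare_permeability_groups(a, b)
        assert p < 1e-3

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            compare_permeability_groups(self._fits([3e-3]), self._fits([3e-3, 3e-3]))


class TestReactorLibrary:
    def test_published_defaults_preloaded(self):
        lib = default_reactor_library()
        for name, r in PERMEABILITY.items():
            assert lib[name].permeability_r == r

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "reactors.yaml"
        dump_reactor_library(path)
        lib = load_reactor_library(path)
        assert lib == default_reactor_library()
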