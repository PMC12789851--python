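"""Water-column physics: attenuation, growth, acclimation, stepping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from chromalight import optics
from chromalight.exceptions import (
    IncompatibleGridError,
    InvalidForcingError,
    InvalidOpticsError,
    InvalidParameterError,
    NoLightError,
)
from chromalight.spectra import AbsorptionSpectrum, build_endmember_spectrum
from chromalight.watercolumn import (
    ColumnState,
    EcoParams,
    Forcing,
    acclimation_exchange,
    acclimation_rate,
    acclimation_target,
    acclimation_timescale,
    attenuate,
    beer_lambert,
    growth_rate,
    initial_state,
    photosynthetically_absorbed,
    population_labels,
    run,
    seasonal_surface_spectrum,
    step,
)


class TestBeerLambert:
    def test_no_absorption_leaves_irradiance_constant(self, grid):
        e0 = np.linspace(1.0, 2.0, grid.n_bands)
        a = np.zeros((5, grid.n_bands))
        e = beer_lambert(e0, a, thickness=10.0)
        np.testing.assert_allclose(e, np.tile(e0, (5, 1)))

    def test_uniform_absorption_closed_form(self, grid):
        # one 20-m layer, midpoint at 10 m: E = E0 * exp(-0.1 * 10)
        e0 = np.full(grid.n_bands, 3.0)
        a = np.full((1, grid.n_bands), 0.1)
        e = beer_lambert(e0, a, thickness=20.0)
        np.testing.assert_allclose(e[0], 3.0 * np.exp(-1.0))

    def test_irradiance_non_increasing_with_depth(self, grid, rng):
        e0 = rng.uniform(0, 5, grid.n_bands)
        a = rng.uniform(0, 0.3, (8, grid.n_bands))
        e = beer_lambert(e0, a, thickness=25.0)
        assert np.all(np.diff(e, axis=0) <= 1e-15)

    def test_pure_water_makes_the_column_bluer_with_depth(self, grid, pigment_types):
        # a_w(545) > a_w(495), so E495/E545 grows with depth
        aw = optics.water_absorption(grid)
        assert aw[grid.index_of(545.0)] > aw[grid.index_of(495.0)]
        state = initial_state(n_layers=10, biomass0=0.0)
        e = attenuate(np.ones(grid.n_bands), state, pigment_types,
                      cdom=np.zeros(grid.n_bands))
        bg = e[:, grid.index_of(495.0)] / e[:, grid.index_of(545.0)]
        assert np.all(np.diff(bg) > 0)

    def test_negative_absorption_rejected(self, grid):
        a = np.full((2, grid.n_bands), -0.01)
        with pytest.raises(InvalidOpticsError):
            beer_lambert(np.ones(grid.n_bands), a, 10.0)


class TestAbsorbedQuanta:
    def test_zero_irradiance_absorbs_nothing(self, pigment_types, grid):
        bs = pigment_types["BS"].state_spectra[0]
        assert photosynthetically_absorbed(np.zeros(grid.n_bands), bs) == 0.0

    def test_blue_only_light_favors_the_blue_specialist(self, pigment_types, grid):
        e = np.zeros(grid.n_bands)
        e[grid.index_of(495.0)] = 1.0
        bs = pigment_types["BS"].state_spectra[0]
        gs = pigment_types["GS"].state_spectra[0]
        assert photosynthetically_absorbed(e, bs) > photosynthetically_absorbed(e, gs)

    def test_linear_in_irradiance(self, pigment_types, grid, rng):
        e = rng.uniform(0, 2, grid.n_bands)
        bs = pigment_types["BS"].state_spectra[0]
        one = photosynthetically_absorbed(e, bs)
        two = photosynthetically_absorbed(2 * e, bs)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_grid_mismatch_rejected(self, pigment_types):
        bs = pigment_types["BS"].state_spectra[0]
        with pytest.raises(IncompatibleGridError):
            photosynthetically_absorbed(np.ones(10), bs)


class TestGrowthRate:
    def test_no_nutrient_no_growth(self):
        assert growth_rate(5.0, 0.0, EcoParams()) == 0.0

    def test_saturates_at_mu_max(self):
        p = EcoParams()
        mu = growth_rate(1e9, 1e9, p)
        assert mu == pytest.approx(p.mu_max, rel=1e-6)
        assert mu < p.mu_max

    def test_half_saturation_identity(self):
        p = EcoParams()
        mu = growth_rate(1e9, p.half_saturation, p)
        assert mu == pytest.approx(p.mu_max / 2, rel=1e-6)

    def test_monotone_in_both_arguments(self, rng):
        p = EcoParams()
        a = np.sort(rng.uniform(0, 1, 10))
        n = np.sort(rng.uniform(0, 1, 10))
        mus_a = [growth_rate(x, 0.5, p) for x in a]
        mus_n = [growth_rate(0.5, x, p) for x in n]
        assert np.all(np.diff(mus_a) >= 0)
        assert np.all(np.diff(mus_n) >= 0)


class TestAcclimationTimescale:
    @pytest.mark.parametrize("par,days", [(20.0, 6.0), (75.0, 3.0), (47.5, 4.5)])
    def test_anchor_points_and_midpoint(self, par, days):
        assert acclimation_timescale(par) == pytest.approx(days)

    @pytest.mark.parametrize("par,days", [(0.0, 6.0), (5.0, 6.0), (500.0, 3.0)])
    def test_clamped_outside_the_anchors(self, par, days):
        assert acclimation_timescale(par) == days

    def test_negative_par_rejected(self):
        with pytest.raises(InvalidForcingError):
            acclimation_timescale(-1.0)


class TestAcclimationTarget:
    def test_pure_blue_light_selects_the_terminal_state(self, pigment_types, grid):
        e = np.zeros(grid.n_bands)
        e[grid.index_of(495.0)] = 1.0
        assert acclimation_target(e, pigment_types["CA"].state_spectra) == 6

    def test_pure_green_light_selects_state_one(self, pigment_types, grid):
        e = np.zeros(grid.n_bands)
        e[grid.index_of(545.0)] = 1.0
        assert acclimation_target(e, pigment_types["CA"].state_spectra) == 1

    def test_matches_exhaustive_enumeration(self, pigment_types, grid, rng):
        # independent oracle: loop over states scoring normalized products
        ca = pigment_types["CA"].state_spectra
        for _ in range(25):
            e = rng.uniform(0, 1, grid.n_bands)
            scores = []
            for s in ca:
                num = sum(float(a) * float(x) for a, x in zip(s.values, e))
                den = sum(float(a) for a in s.values)
                scores.append(num / den)
            expected = 1 + max(range(6), key=lambda i: scores[i])
            assert acclimation_target(e, ca) == expected

    def test_all_dark_is_an_error(self, pigment_types, grid):
        with pytest.raises(NoLightError):
            acclimation_target(np.zeros(grid.n_bands), pigment_types["CA"].state_spectra)


class TestAcclimationExchange:
    def test_target_only_occupied_state_is_a_fixed_point(self):
        b = np.array([0.0, 0.0, 5.0, 0.0, 0.0, 0.0])
        out = acclimation_exchange(b, 3, tau=4.0, dt=0.1)
        np.testing.assert_array_equal(out, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100), min_size=6, max_size=6),
        st.integers(1, 6),
    )
    def test_total_biomass_conserved(self, pools, target):
        b = np.array(pools)
        out = acclimation_exchange(b, target, tau=5.0, dt=0.05)
        assert out.sum() == pytest.approx(b.sum(), abs=1e-9 * max(1.0, b.sum()))
        assert np.all(out >= 0)

    def test_only_adjacent_states_exchange(self):
        b = np.array([1.0, 0, 0, 0, 0, 0])
        out = acclimation_exchange(b, 6, tau=6.0, dt=0.05)
        assert out[0] < 1.0 and out[1] > 0
        assert np.all(out[2:] == 0)

    @pytest.mark.parametrize("tau", [3.0, 6.0])
    def test_full_transition_takes_about_tau(self, tau):
        b = np.zeros(6)
        b[0] = 1.0
        t, dt = 0.0, 0.05
        while b[5] < 0.95:
            b = acclimation_exchange(b, 6, tau, dt)
            t += dt
        assert t == pytest.approx(tau, rel=0.1)

    def test_small_dt_euler_matches_matrix_exponential(self):
        # continuous oracle: generator of the 1 -> 6 hop chain
        tau, n = 6.0, 6
        r = acclimation_rate(tau, n)
        q = np.zeros((n, n))
        for i in range(n - 1):
            q[i, i] -= r
            q[i + 1, i] += r
        t_end = tau
        exact = expm(q * t_end) @ np.eye(n)[0]
        dt = 1e-3
        b = np.eye(n)[0]
        for _ in range(int(round(t_end / dt))):
            b = acclimation_exchange(b, n, tau, dt)
        assert np.max(np.abs(b - exact)) / np.max(exact) < 1e-3


def _dark_forcing(grid):
    return Forcing(
        surface_spectrum=lambda doy: np.zeros(grid.n_bands),
        nutrient_supply=lambda doy: 0.0,
        mixing_rate=0.0,
    )


class TestStep:
    def test_dark_no_loss_no_supply_keeps_all_pools_constant(self, grid, pigment_types):
        params = EcoParams(loss_rate=0.0)
        state = initial_state(n_layers=5)
        out = step(state, _dark_forcing(grid), params, pigment_types, dt=0.1)
        np.testing.assert_array_equal(out.biomass, state.biomass)
        np.testing.assert_array_equal(out.nutrient, state.nutrient)

    def test_nitrogen_mass_balance_per_step(self, grid, pigment_types):
        params = EcoParams()
        forcing = Forcing(
            surface_spectrum=seasonal_surface_spectrum(grid),
            nutrient_supply=lambda doy: 0.05,
            mixing_rate=0.5,
        )
        state = initial_state(n_layers=10, seed=3)
        dt, dz = 0.05, state.thickness
        for _ in range(50):
            before = dz * (
                state.nutrient.sum() + params.n_to_c * state.biomass.sum()
            )
            new = step(state, forcing, params, pigment_types, dt, )
            after = dz * (new.nutrient.sum() + params.n_to_c * new.biomass.sum())
            supply = dt * 0.05 * dz
            export = (
                dt * (1 - params.remin_frac) * params.loss_rate
                * params.n_to_c * state.biomass.sum() * dz
            )
            assert after - before == pytest.approx(supply - export, rel=1e-8, abs=1e-12)
            state = new

    def test_identical_seeds_are_bit_identical(self, pigment_types):
        forcing = Forcing(
            surface_spectrum=seasonal_surface_spectrum(),
            nutrient_supply=lambda doy: 0.02,
        )
        a = run(forcing, years=0.5, dt=0.1, seed=7, n_layers=6)
        b = run(forcing, years=0.5, dt=0.1, seed=7, n_layers=6)
        assert a.identical(b)

    def test_monthly_output_shapes_and_monotone_light(self, pigment_types):
        forcing = Forcing(
            surface_spectrum=seasonal_surface_spectrum(),
            nutrient_supply=lambda doy: 0.02,
        )
        ds = run(forcing, years=1.0, dt=0.1, seed=0, n_layers=8)
        assert ds.sizes == {"time": 12, "depth": 8, "population": 8}
        assert list(ds["population"].values) == population_labels()
        for v in ("E495", "E545"):
            assert np.all(np.diff(ds[v].values, axis=1) <= 1e-12)


class TestCompetition:
    def test_blue_light_excludes_the_green_specialist(self, grid, pigment_types):
        # constant strongly blue surface spectrum; single shared nutrient
        blue = np.exp(-0.5 * ((grid.wavelengths - 470.0) / 30.0) ** 2)
        blue = 120.0 * blue / (blue.sum() * grid.band_width)
        forcing = Forcing(
            surface_spectrum=lambda doy: blue,
            nutrient_supply=lambda doy: 0.02,
        )
        ds = run(forcing, years=3.0, dt=0.05, seed=2, n_layers=10)
        last = ds["biomass"].isel(time=slice(-12, None)).sum(("time", "depth"))
        bs = float(last.sel(population="BS"))
        gs = float(last.sel(population="GS"))
        assert bs > 100 * gs  # exclusion, not mere dominance
        # the acclimator converges onto its blue end state
        ca = last.sel(population=[f"CA{i}" for i in range(1, 7)]).values
        assert ca[-1] > 0.95 * ca.sum()
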