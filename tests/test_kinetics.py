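"""Marcus barriers, Eyring rates, diffusion limits and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radscav.kinetics import (
    DiffusionInputs,
    KineticContext,
    collins_kimball,
    eyring_rate,
    fit_reorganization_energy,
    fit_tunneling_factor,
    invert_eyring,
    marcus_barrier,
    marcus_parabola,
    smoluchowski_rate,
    stokes_einstein_diffusion,
)


class TestContext:
    def test_thermal_energy_and_prefactor_at_room_temperature(self, ctx):
        assert ctx.rt == pytest.approx(0.5925, abs=1e-4)
        assert ctx.boltzmann_over_planck == pytest.approx(6.212e12, rel=1e-3)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            KineticContext(temperature=-1.0)


class TestMarcusBarrier:
    def test_normal_region_table_value(self):
        # strongly endergonic electron transfer with a narrow parabola
        assert marcus_barrier(19.0, 9.3) == pytest.approx(21.5, abs=0.05)

    def test_apex_is_barrierless(self):
        assert marcus_barrier(-9.3, 9.3) == 0.0

    def test_inverted_region_value(self):
        # dG < -lambda: the barrier rises again on the inverted arm
        assert marcus_barrier(-16.8, 12.7) == pytest.approx(0.33, abs=0.01)

    def test_rejects_nonpositive_reorganization_energy(self):
        with pytest.raises(ValueError):
            marcus_barrier(0.0, -1.0)

    @given(
        dg=st.floats(-60.0, 60.0),
        lam=st.floats(0.5, 60.0),
    )
    def test_matches_expanded_quadratic(self, dg, lam):
        # independent re-derivation: lam/4 + dG/2 + dG^2/(4 lam)
        expanded = lam / 4.0 + dg / 2.0 + dg * dg / (4.0 * lam)
        assert marcus_barrier(dg, lam) == pytest.approx(expanded, rel=1e-12, abs=1e-12)
        assert marcus_barrier(dg, lam) >= -1e-12

    @given(lam=st.floats(1.0, 50.0), delta=st.floats(0.0, 40.0))
    def test_symmetric_about_apex(self, lam, delta):
        left = marcus_barrier(-lam - delta, lam)
        right = marcus_barrier(-lam + delta, lam)
        assert left == pytest.approx(right, rel=1e-10, abs=1e-10)

    def test_parabola_grid_and_apex_location(self):
        grid = np.linspace(-60, 10, 701)
        curve = marcus_parabola(25.0, grid)
        assert grid[np.argmin(curve)] == pytest.approx(-25.0, abs=0.1)
        assert marcus_parabola(10.0, [0.0])[0] == pytest.approx(2.5)

    def test_rate_monotone_on_each_arm(self, ctx):
        lam = 20.0
        descending = eyring_rate(marcus_barrier(np.linspace(-lam, 40, 50), lam), ctx)
        ascending = eyring_rate(marcus_barrier(np.linspace(-80, -lam, 50), lam), ctx)
        assert np.all(np.diff(descending) <= 0)
        assert np.all(np.diff(ascending) >= 0)


class TestEyring:
    def test_barrierless_rate_is_the_prefactor(self, ctx):
        assert eyring_rate(0.0, ctx) == pytest.approx(6.21e12, rel=2e-3)

    @pytest.mark.parametrize(
        "dg_act, reported",
        [(19.1, 6.51e-2), (34.1, 5.89e-13)],
    )
    def test_reproduces_reported_electron_transfer_rates(self, ctx, dg_act, reported):
        # barriers printed to 1 d.p. => up to ~10% exponential sensitivity
        assert eyring_rate(dg_act, ctx) == pytest.approx(reported, rel=0.10)

    def test_degeneracy_and_tunneling_multiply(self, ctx):
        base = eyring_rate(10.0, ctx)
        assert eyring_rate(10.0, ctx, sigma=3, kappa=2.0) == pytest.approx(6 * base)

    def test_rejects_invalid_sigma_kappa(self, ctx):
        with pytest.raises(ValueError):
            eyring_rate(1.0, ctx, sigma=0)
        with pytest.raises(ValueError):
            eyring_rate(1.0, ctx, kappa=0.5)

    @given(dg_act=st.floats(0.0, 40.0))
    def test_round_trips_through_inversion(self, dg_act):
        ctx = KineticContext()
        k = eyring_rate(dg_act, ctx)
        assert invert_eyring(k, ctx) == pytest.approx(dg_act, abs=1e-10)

    def test_fitted_tunneling_factor_reconciles_rate(self, ctx):
        kappa = fit_tunneling_factor(16.7, 3.77e3, ctx)
        assert kappa > 100  # hydrogen transfer needs a large correction
        assert eyring_rate(16.7, ctx, kappa=kappa) == pytest.approx(3.77e3, rel=1e-12)


class TestDiffusion:
    def test_stokes_einstein_reference_value(self):
        d = stokes_einstein_diffusion(2.0, 8.91e-4, 298.15)
        assert d == pytest.approx(1.23e-9, rel=0.01)

    def test_diffusion_coefficient_scales_inversely_with_radius(self):
        assert stokes_einstein_diffusion(4.0) == pytest.approx(
            stokes_einstein_diffusion(2.0) / 2.0
        )
        assert stokes_einstein_diffusion(1e12) < 1e-20

    def test_equal_radius_encounter_rate(self):
        d = DiffusionInputs(radius_a=2.0, radius_b=2.0, viscosity=8.91e-4)
        assert smoluchowski_rate(d) == pytest.approx(7.4e9, rel=0.01)

    def test_equal_radius_rate_is_radius_independent(self):
        k1 = smoluchowski_rate(DiffusionInputs(radius_a=2.0, radius_b=2.0))
        k2 = smoluchowski_rate(DiffusionInputs(radius_a=7.0, radius_b=7.0))
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_scales_linearly_with_temperature_over_viscosity(self):
        base = smoluchowski_rate(DiffusionInputs(viscosity=8.91e-4, temperature=298.15))
        halved = smoluchowski_rate(DiffusionInputs(viscosity=2 * 8.91e-4, temperature=298.15))
        assert halved == pytest.approx(base / 2.0, rel=1e-12)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            DiffusionInputs(radius_a=-1.0)
        with pytest.raises(ValueError):
            stokes_einstein_diffusion(1.0, viscosity=0.0)


class TestCollinsKimball:
    def test_fast_activation_plateaus_at_diffusion(self):
        assert collins_kimball(1e12, 4e9) == pytest.approx(3.98e9, rel=1e-2)

    def test_limits_and_symmetry(self):
        assert collins_kimball(0.0, 5e9) == 0.0
        assert collins_kimball(0.0, 0.0) == 0.0
        assert collins_kimball(3e9, 3e9) == pytest.approx(1.5e9)
        assert collins_kimball(2.0, 7.0) == collins_kimball(7.0, 2.0)

    @given(
        ka=st.floats(0.0, 1e13),
        kd=st.floats(0.0, 1e11),
    )
    def test_never_exceeds_either_rate(self, ka, kd):
        k = collins_kimball(ka, kd)
        assert k <= min(ka, kd) + 1e-6 * max(ka, kd, 1.0)
        assert k >= 0.0


class TestReorganizationRecovery:
    def test_recovers_lambda_from_noiseless_pairs(self):
        rng = np.random.default_rng(7)
        dg = rng.normal(0.0, 10.0, size=50)
        lam_hat, se = fit_reorganization_energy(dg, marcus_barrier(dg, 22.0))
        assert lam_hat == pytest.approx(22.0, abs=1e-6)
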