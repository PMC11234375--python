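import numpy as np
import pytest

from skinperm import (
    Environment,
    PermeantSpec,
    calibrate_to_hydration,
    combine_diffusion,
    combine_pmf,
    common_zero_shift,
    hh_shift,
    ionized_fraction_profile,
    neutral_fraction,
    state_probabilities,
)

from conftest import make_profile

KT = 0.0083144626 * 305.15  # kJ/mol at the simulation temperature


class TestSpecValidation:
    def test_unknown_acid_class_rejected(self):
        with pytest.raises(ValueError, match="acid_class"):
            PermeantSpec(name="x", pka=4.0, acid_class="zwitterion")

    def test_nonfinite_pka_rejected(self):
        with pytest.raises(ValueError, match="pKa"):
            PermeantSpec(name="x", pka=np.inf, acid_class="acid")


class TestCalibration:
    def test_subtracts_hydration_free_energy(self):
        p = make_profile([0, 1], [0.0, 0.0])
        out = calibrate_to_hydration(p, -10.0)
        np.testing.assert_array_equal(out.value, 10.0)

    def test_zero_hydration_energy_is_identity(self, rng):
        p = make_profile([0, 1], rng.normal(size=2))
        np.testing.assert_array_equal(
            calibrate_to_hydration(p, 0.0).value, p.value
        )

    def test_calibrate_then_uncalibrate_roundtrips(self, rng):
        p = make_profile([0, 1], rng.normal(size=2))
        back = calibrate_to_hydration(calibrate_to_hydration(p, -33.3), 33.3)
        np.testing.assert_allclose(back.value, p.value, atol=1e-12)


class TestHendersonHasselbalch:
    def test_no_shift_at_the_midpoint(self, acid, env):
        p = make_profile([0, 1], [5.0, 6.0])
        out = hh_shift(p, acid, ph=acid.pka, env=env)
        np.testing.assert_array_equal(out.value, p.value)

    def test_acid_shift_one_unit_above_pka(self, acid, env):
        p = make_profile([0], [0.0])
        out = hh_shift(p, acid, ph=acid.pka + 1, env=env)
        assert out.value[0] == pytest.approx(-5.8420, abs=5e-5)

    def test_base_shift_has_opposite_sign(self, base, env):
        p = make_profile([0], [0.0])
        out = hh_shift(p, base, ph=base.pka + 1, env=env)
        assert out.value[0] == pytest.approx(+5.8420, abs=5e-5)

    @pytest.mark.parametrize("cls,s", [("acid", 1), ("base", -1)])
    @pytest.mark.parametrize("dph", [-2.5, -1.0, 0.0, 0.7, 3.0])
    def test_bulk_population_ratio_is_henderson_hasselbalch(
        self, env, cls, s, dph
    ):
        """After the shift, charged:neutral in water = 10^(s (pH - pKa))."""
        spec = PermeantSpec(name="x", pka=5.0, acid_class=cls)
        pmf_n = make_profile([0], [0.0])  # calibrated: water value 0
        pmf_c = hh_shift(make_profile([0], [0.0]), spec, 5.0 + dph, env)
        p_n, p_c = state_probabilities(pmf_n, pmf_c, env)
        ratio = p_c[0] / p_n[0]
        assert ratio == pytest.approx(10.0 ** (s * dph), rel=1e-12)


class TestNeutralFraction:
    def test_midpoint_is_exactly_half(self, acid, base):
        assert neutral_fraction(acid, acid.pka) == 0.5
        assert neutral_fraction(base, base.pka) == 0.5

    def test_acid_one_unit_above(self, acid):
        assert neutral_fraction(acid, acid.pka + 1) == pytest.approx(1 / 11)

    def test_base_two_units_below(self, base):
        f = neutral_fraction(base, base.pka - 2)
        assert f == pytest.approx(1 / 101)
        assert 1 - f == pytest.approx(100 / 101)


class TestCommonZeroShift:
    def test_raises_both_when_minimum_negative(self):
        a = make_profile([0, 1], [-3.0, 2.0])
        b = make_profile([0, 1], [1.0, 4.0])
        sa, sb = common_zero_shift(a, b)
        assert min(sa.value.min(), sb.value.min()) == 0.0
        np.testing.assert_array_equal(sa.value, [0.0, 5.0])
        np.testing.assert_array_equal(sb.value, [4.0, 7.0])

    def test_noop_when_already_nonnegative(self):
        a = make_profile([0, 1], [0.5, 2.0])
        b = make_profile([0, 1], [1.0, 4.0])
        sa, sb = common_zero_shift(a, b)
        assert sa is a and sb is b

    def test_state_difference_invariant(self, rng):
        v = rng.normal(size=10) * 10
        w = rng.normal(size=10) * 10
        a = make_profile(np.arange(10.0), v)
        b = make_profile(np.arange(10.0), w)
        sa, sb = common_zero_shift(a, b)
        np.testing.assert_allclose(sb.value - sa.value, w - v, atol=1e-12)


class TestStateProbabilities:
    def test_probabilities_sum_to_one(self, env, rng):
        z = np.arange(50.0)
        a = make_profile(z, rng.normal(size=50) * 50)
        b = make_profile(z, rng.normal(size=50) * 50)
        p_n, p_c = state_probabilities(a, b, env)
        np.testing.assert_allclose(p_n + p_c, 1.0, rtol=0, atol=1e-12)

    def test_degenerate_states_split_evenly(self, env):
        a = make_profile([0], [3.0])
        p_n, p_c = state_probabilities(a, a, env)
        assert p_n[0] == p_c[0] == 0.5

    def test_kt_ln10_gap_gives_one_in_eleven(self, env):
        a = make_profile([0], [0.0])
        b = make_profile([0], [env.kT * np.log(10)])
        _, p_c = state_probabilities(a, b, env)
        assert p_c[0] == pytest.approx(1 / 11, rel=1e-12)

    def test_invariant_under_common_constant(self, env, rng):
        z = np.arange(10.0)
        a = make_profile(z, rng.normal(size=10))
        b = make_profile(z, rng.normal(size=10))
        p1 = state_probabilities(a, b, env)
        p2 = state_probabilities(a.shift(123.0), b.shift(123.0), env)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_no_overflow_with_extreme_barriers(self, env):
        a = make_profile([0, 1], [0.0, 900.0])
        b = make_profile([0, 1], [900.0, 0.0])
        p_n, p_c = state_probabilities(a, b, env)
        assert np.all(np.isfinite(p_n)) and np.all(np.isfinite(p_c))
        np.testing.assert_allclose(p_n + p_c, 1.0, atol=1e-12)


class TestCombinePmf:
    def test_excluded_state_limit(self, env):
        z = np.arange(5.0)
        g_n = make_profile(z, [1.0, 2.0, 3.0, 2.0, 1.0])
        g_c = g_n.shift(500.0)
        for mode in ("boltzmann", "weighted"):
            out = combine_pmf(g_n, g_c, env, mode=mode)
            np.testing.assert_allclose(out.value, g_n.value, atol=1e-9)

    def test_degenerate_states_expose_mode_difference(self, env):
        g = make_profile([0], [4.0])
        boltz = combine_pmf(g, g, env, mode="boltzmann")
        weight = combine_pmf(g, g, env, mode="weighted")
        assert boltz.value[0] == pytest.approx(4.0 - env.kT * np.log(2), rel=1e-12)
        assert weight.value[0] == pytest.approx(4.0, rel=1e-12)

    def test_boltzmann_below_min_below_weighted(self, env, rng):
        z = np.arange(200.0)
        a = make_profile(z, rng.uniform(0, 30, 200))
        b = make_profile(z, rng.uniform(0, 30, 200))
        boltz = combine_pmf(a, b, env, mode="boltzmann").value
        weight = combine_pmf(a, b, env, mode="weighted").value
        pointwise_min = np.minimum(a.value, b.value)
        assert np.all(boltz <= pointwise_min + 1e-12)
        assert np.all(pointwise_min <= weight + 1e-12)
        assert np.all(boltz >= pointwise_min - env.kT * np.log(2) - 1e-12)

    def test_unknown_mode_rejected(self, env):
        g = make_profile([0], [0.0])
        with pytest.raises(ValueError, match="mode"):
            combine_pmf(g, g, env, mode="geometric")

    def test_rezero_flag_lifts_minimum_to_zero(self, env):
        g = make_profile([0, 1], [0.0, 1.0])
        out = combine_pmf(g, g, env, mode="boltzmann", rezero=True)
        assert out.value.min() == pytest.approx(0.0, abs=1e-15)


class TestCombineDiffusion:
    def test_pure_neutral_limit(self):
        d_n = make_profile([0, 1], [1.0, 2.0], label="diffusion")
        d_c = make_profile([0, 1], [3.0, 4.0], label="diffusion")
        out = combine_diffusion(d_n, d_c, np.ones(2), np.zeros(2))
        np.testing.assert_array_equal(out.value, d_n.value)

    def test_identical_profiles_independent_of_probability(self):
        d = make_profile([0, 1], [1.5, 2.5], label="diffusion")
        out = combine_diffusion(d, d, np.array([0.3, 0.9]), np.array([0.7, 0.1]))
        np.testing.assert_allclose(out.value, d.value)

    def test_even_mixture_arithmetic(self):
        d_n = make_profile([0], [1.0], label="diffusion")
        d_c = make_profile([0], [3.0], label="diffusion")
        out = combine_diffusion(d_n, d_c, np.array([0.5]), np.array([0.5]))
        assert out.value[0] == 2.0

    def test_inconsistent_probabilities_rejected(self):
        d = make_profile([0], [1.0], label="diffusion")
        with pytest.raises(ValueError, match="sum to 1"):
            combine_diffusion(d, d, np.array([0.6]), np.array([0.6]))


class TestIonizedFraction:
    def test_half_at_midpoint_with_degenerate_states(self, acid, env):
        z = np.arange(0, 5.2, 0.1)
        g = make_profile(z, np.zeros_like(z))
        out = ionized_fraction_profile(g, g, acid, acid.pka, env)
        np.testing.assert_allclose(out.value, 0.5, atol=1e-12)

    def test_vanishes_when_charged_state_excluded(self, acid, env):
        z = np.arange(0, 5.2, 0.1)
        g_n = make_profile(z, np.zeros_like(z))
        g_c = make_profile(z, np.full_like(z, 400.0))
        out = ionized_fraction_profile(g_n, g_c, acid, acid.pka, env)
        assert out.value.max() < 1e-12

    def test_headgroup_well_boltzmann_arithmetic(self, acid, env):
        """A charged-state well 5 kJ/mol below neutral at z = 3.1 nm gives
        p_c = 1/(1 + exp(-5/kT)) ~ 0.878 at pH = pKa."""
        z = np.arange(0, 5.2, 0.1)
        g_n = make_profile(z, np.zeros_like(z))
        well = -5.0 * (np.abs(z - 3.1) < 0.05)
        g_c = make_profile(z, well)
        out = ionized_fraction_profile(g_n, g_c, acid, acid.pka, env)
        i = np.argmin(np.abs(z - 3.1))
        expected = 1.0 / (1.0 + np.exp(-5.0 / KT))
        assert out.value[i] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.878, abs=2e-3)
        assert out.meta["mean_ionized_fraction_headgroup"] > 0.5

    @pytest.mark.parametrize("cls,direction", [("acid", 1), ("base", -1)])
    def test_monotone_in_ph(self, env, rng, cls, direction):
        spec = PermeantSpec(name="x", pka=6.0, acid_class=cls)
        z = np.arange(0, 5.2, 0.1)
        g_n = make_profile(z, rng.uniform(0, 10, z.size))
        g_c = make_profile(z, rng.uniform(0, 10, z.size))
        prev = None
        for ph in np.arange(3.0, 9.1, 0.5):
            cur = ionized_fraction_profile(g_n, g_c, spec, ph, env).value
            if prev is not None:
                assert np.all(direction * (cur - prev) >= -1e-12)
            prev = cur
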