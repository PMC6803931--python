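"""Partition functions, TST, d-TST and tunneling corrections."""

import math

import numpy as np
import pytest

from ratekit import (
    CONST,
    DivergenceError,
    DomainError,
    Geometry,
    InputError,
    Regime,
    Species,
    Tunneling,
    corrected_rate,
    crossover_and_regime,
    crossover_temperature,
    dtst_rate,
    partition_functions,
    tst_rate,
    tunneling_kappa,
)
from ratekit.datasets import SystemTemplate, synth_reaction_system
from ratekit.tst import _st_high_T, _st_low_T, check_enthalpy_consistency

R = CONST.R_cal


class TestPartitionFunctions:
    def test_atom(self):
        ar = Species(name="Ar", mass_amu=39.95, geometry=Geometry.ATOM, degeneracy=1)
        q = partition_functions(ar, 298.15)
        assert q.q_rot == 1.0 and q.q_vib == 1.0 and q.g_elec == 1.0
        assert q.q_trans_per_volume > 1e30  # ~2.5e32 m^-3 for argon

    def test_linear_rotor_textbook_value(self):
        co = Species(name="CO", mass_amu=28.0, geometry=Geometry.LINEAR,
                     rotational_constants_cm1=(1.9313,), frequencies_cm1=(2143.0,))
        q = partition_functions(co, 298.15)
        assert q.q_rot == pytest.approx(107.3, rel=2e-3)
        assert q.q_vib == pytest.approx(1.00003, abs=2e-5)

    def test_symmetry_number_divides_rotation(self):
        kwargs = dict(name="X2", mass_amu=2.0, geometry=Geometry.LINEAR,
                      rotational_constants_cm1=(60.0,), frequencies_cm1=(4400.0,))
        q1 = partition_functions(Species(sigma=1, **kwargs), 300.0)
        q2 = partition_functions(Species(sigma=2, **kwargs), 300.0)
        assert q1.q_rot / q2.q_rot == pytest.approx(2.0)

    def test_vibrational_closed_form_vs_level_sum(self):
        """Geometric closed form vs brute-force sum over 200 harmonic levels."""
        # modes stiff enough that 200 levels converge the sum below 1e-10 at 2000 K
        freqs = (500.0, 900.0, 1500.0, 3100.0)
        sp = Species(name="toy", mass_amu=20.0, geometry=Geometry.NONLINEAR,
                     rotational_constants_cm1=(1.0, 2.0, 3.0), frequencies_cm1=freqs)
        for T in (150.0, 298.15, 1000.0, 2000.0):
            brute = 1.0
            for nu in freqs:
                theta = CONST.c2_cm_K * nu
                brute *= sum(math.exp(-n * theta / T) for n in range(200))
            assert partition_functions(sp, T).q_vib == pytest.approx(brute, rel=1e-10)

    def test_moments_constructor_matches_constants(self):
        # I = h/(8 pi^2 c B): a 1 cm^-1 rotor has I ~ 16.86 amu A^2
        I = CONST.h / (8 * math.pi**2 * CONST.c_cm_s * 1.0) / (CONST.amu_kg * 1e-20)
        sp = Species.from_moments(moments_amu_A2=(I,), name="X", mass_amu=10.0,
                                  geometry=Geometry.LINEAR, frequencies_cm1=(100.0,))
        assert sp.rotational_constants_cm1[0] == pytest.approx(1.0, rel=1e-12)

    def test_missing_rotations_rejected(self):
        with pytest.raises(InputError):
            Species(name="bad", mass_amu=10.0, geometry=Geometry.LINEAR,
                    frequencies_cm1=(100.0,))

    def test_atom_with_frequencies_rejected(self):
        with pytest.raises(InputError):
            Species(name="bad", mass_amu=10.0, geometry=Geometry.ATOM,
                    frequencies_cm1=(100.0,))


class TestTSTRate:
    def test_universal_frequency_factor(self):
        """Unit partition ratio, zero barrier: k = kB T/h ~ 6.21e12 s^-1."""
        system = synth_reaction_system(SystemTemplate.TOY_UNIMOLECULAR)
        object.__setattr__(system.ts, "electronic_energy", 0.0)
        assert tst_rate(system, 298.15) == pytest.approx(6.2124e12, rel=1e-4)

    def test_barrier_of_rt_ln10_costs_one_decade(self):
        system = synth_reaction_system(SystemTemplate.TOY_UNIMOLECULAR)
        object.__setattr__(system.ts, "electronic_energy", R * 298.15 * math.log(10.0))
        assert tst_rate(system, 298.15) == pytest.approx(6.2124e11, rel=1e-4)

    def test_toy_unimolecular_matches_hand_formula(self):
        system = synth_reaction_system(SystemTemplate.TOY_UNIMOLECULAR)
        T = 350.0
        hand = CONST.kB * T / CONST.h * math.exp(-5000.0 / (R * T))
        assert tst_rate(system, T) == pytest.approx(hand, rel=1e-12)

    def test_ts_degeneracy_scales_linearly(self):
        system = synth_reaction_system(SystemTemplate.TOY_BIMOLECULAR)
        k1 = tst_rate(system, 400.0)
        doubled = Species(**{**system.ts.__dict__, "degeneracy": system.ts.degeneracy * 2})
        from ratekit import ReactionSystem
        system2 = ReactionSystem(reactants=system.reactants, ts=doubled,
                                 nu_imag_cm1=system.nu_imag_cm1)
        assert tst_rate(system2, 400.0) == pytest.approx(2.0 * k1, rel=1e-12)

    def test_bimolecular_units_are_per_molecule(self):
        system = synth_reaction_system(SystemTemplate.TOY_BIMOLECULAR)
        k = tst_rate(system, 300.0)
        assert 1e-20 < k < 1e-8  # cm^3 molecule^-1 s^-1 scale

    def test_array_temperature_grid(self):
        system = synth_reaction_system(SystemTemplate.TOY_UNIMOLECULAR)
        grid = np.array([250.0, 300.0, 350.0])
        k = tst_rate(system, grid)
        assert k.shape == (3,) and np.all(np.diff(k) > 0.0)


class TestDTST:
    def test_deformation_forced_value(self):
        """h nu = eps forces d = -1/12."""
        system = synth_reaction_system(SystemTemplate.TOY_UNIMOLECULAR)
        nu_eq = 5000.0 / (R * CONST.c2_cm_K)  # wavenumber whose h*nu is the barrier
        from ratekit import ReactionSystem
        system = ReactionSystem(reactants=system.reactants, ts=system.ts, nu_imag_cm1=nu_eq)
        _, d = dtst_rate(system, 300.0)
        assert d == pytest.approx(-1.0 / 12.0, rel=1e-12)

    def test_deformed_factor_against_hand_arithmetic(self):
        # (1 + 1/12)^(-12) ~ 0.3827 vs e^-1 ~ 0.3679: enhancement ~ 1.040
        assert (1.0 + 1.0 / 12.0) ** (-12.0) / math.exp(-1.0) == pytest.approx(1.0403, rel=1e-3)

    def test_reduces_to_tst_for_vanishing_imaginary_mode(self):
        base = synth_reaction_system(SystemTemplate.TOY_UNIMOLECULAR)
        from ratekit import ReactionSystem
        system = ReactionSystem(reactants=base.reactants, ts=base.ts, nu_imag_cm1=1e-6)
        kd, d = dtst_rate(system, 300.0)
        assert kd == pytest.approx(tst_rate(system, 300.0), rel=1e-9)

    def test_sub_arrhenius_concavity(self):
        """d-TST with d < 0 bends the Arrhenius plot concave (sub-Arrhenius)."""
        system = synth_reaction_system(SystemTemplate.DEEP_TUNNEL)
        T = np.linspace(220.0, 400.0, 41)
        beta = (1.0 / (R * T))[::-1]
        lnk = np.log(dtst_rate(system, 1.0 / (R * beta))[0])
        second = np.gradient(np.gradient(lnk, beta), beta)[2:-2]
        assert np.all(second > 0.0)

    def test_negative_barrier_rejected(self):
        base = synth_reaction_system(SystemTemplate.TOY_UNIMOLECULAR)
        object.__setattr__(base.ts, "electronic_energy", -100.0)
        with pytest.raises(DomainError):
            dtst_rate(base, 300.0)


class TestTunnelingKappa:
    NU = 1000.0
    EPS = 5000.0

    def test_bell58_one_term_closed_form_at_2Tc(self):
        Tc = crossover_temperature(self.NU)
        kappa = tunneling_kappa(Tunneling.BELL58_1T, self.NU, self.EPS, 2.0 * Tc)
        assert kappa == pytest.approx((math.pi / 4.0) / math.sin(math.pi / 4.0), rel=1e-12)

    @pytest.mark.parametrize("method", [Tunneling.BELL35, Tunneling.BELL58_1T,
                                        Tunneling.BELL58_2T, Tunneling.ST])
    def test_high_temperature_limit_is_unity(self, method):
        # Bell35 converges like 1 + Tc/(2T), so the 1e-3 window needs T >> 500 Tc
        T = 1000.0 * crossover_temperature(self.NU)
        kappa = tunneling_kappa(method, self.NU, self.EPS, T, dH_cal_mol=0.0)
        assert kappa == pytest.approx(1.0, abs=1e-3)

    def test_bell58_pole_refused_naming_crossover(self):
        Tc = crossover_temperature(self.NU)
        with pytest.raises(DivergenceError, match="[0-9]"):
            tunneling_kappa(Tunneling.BELL58_1T, self.NU, self.EPS, 0.5 * Tc)

    def test_bell35_continuous_through_removable_point(self):
        Tc = crossover_temperature(self.NU)
        near = tunneling_kappa(Tunneling.BELL35, self.NU, self.EPS, 0.5 * Tc * (1.0 + 1e-7))
        at = tunneling_kappa(Tunneling.BELL35, self.NU, self.EPS, 0.5 * Tc)
        assert near == pytest.approx(at, rel=1e-4)

    def test_bell_corrections_enhance_below_2Tc(self):
        Tc = crossover_temperature(self.NU)
        for T in (1.9 * Tc, 1.2 * Tc):
            assert tunneling_kappa(Tunneling.BELL58_1T, self.NU, self.EPS, T) >= 1.0

    def test_st_requires_enthalpy(self):
        with pytest.raises(InputError):
            tunneling_kappa(Tunneling.ST, self.NU, self.EPS, 300.0)

    def test_st_positive_across_deep_regime(self):
        """The deep branch stays positive from Tc down through Tc/2 and below."""
        Tc = crossover_temperature(self.NU)
        for T in (0.9 * Tc, 0.55 * Tc, 0.5 * Tc, 0.3 * Tc):
            kappa = tunneling_kappa(Tunneling.ST, self.NU, self.EPS, T, dH_cal_mol=-3000.0)
            assert kappa > 0.0

    def test_st_branch_mismatch_finite_at_crossover(self):
        """Both branch formulas evaluated at beta = c: mismatch is finite
        (no pole), though the formulas are not continuous there."""
        Tc = crossover_temperature(self.NU)
        hnu = R * CONST.c2_cm_K * self.NU
        hbar_nu = hnu / (2.0 * math.pi)
        RT = R * Tc
        E = self.EPS - (-3000.0)
        u = hnu / (2.0 * RT)
        high = _st_high_T(u, hbar_nu, RT, E)
        low = _st_low_T(hbar_nu, RT, E)
        assert math.isfinite(high) and math.isfinite(low)
        assert high > 0.0 and low > 0.0

    def test_nonpositive_barrier_rejected(self):
        with pytest.raises(InputError):
            tunneling_kappa(Tunneling.BELL35, self.NU, -10.0, 300.0)


class TestRegimes:
    def test_crossover_temperature_value(self):
        assert crossover_temperature(1000.0) == pytest.approx(458.0, abs=0.1)

    @pytest.mark.parametrize(
        "factor,regime",
        [(3.0, Regime.NEGLIGIBLE), (2.0, Regime.NEGLIGIBLE), (1.5, Regime.SMALL),
         (1.0, Regime.SMALL), (0.7, Regime.MODERATE), (0.5, Regime.MODERATE),
         (0.4, Regime.DEEP), (0.05, Regime.DEEP)],
    )
    def test_window_membership(self, factor, regime):
        Tc = crossover_temperature(1200.0)
        assert crossover_and_regime(1200.0, factor * Tc)[1] is regime

    def test_windows_partition_axis(self):
        """Every temperature in (0, 10 Tc] belongs to exactly one window."""
        Tc = crossover_temperature(800.0)
        for T in np.linspace(1e-3, 10.0 * Tc, 997):
            _, regime = crossover_and_regime(800.0, T)
            expected = (Regime.NEGLIGIBLE if T >= 2 * Tc else
                        Regime.SMALL if T >= Tc else
                        Regime.MODERATE if T >= Tc / 2 else Regime.DEEP)
            assert regime is expected


class TestCorrectedRate:
    def test_none_is_plain_tst(self):
        system = synth_reaction_system(SystemTemplate.TOY_BIMOLECULAR)
        assert corrected_rate(system, 300.0, Tunneling.NONE) == tst_rate(system, 300.0)

    @pytest.mark.parametrize(
        "method,rel",
        [(Tunneling.BELL35, 0.06),  # approaches 1 as 1 + Tc/(2T): ~5% at 10 Tc
         (Tunneling.BELL58_1T, 0.02), (Tunneling.BELL58_2T, 0.02), (Tunneling.ST, 0.02)],
    )
    def test_negligible_regime_matches_tst(self, method, rel):
        system = synth_reaction_system(SystemTemplate.TOY_BIMOLECULAR)
        T = 10.0 * crossover_temperature(system.nu_imag_cm1)
        assert corrected_rate(system, T, method) == pytest.approx(
            tst_rate(system, T), rel=rel
        )

    def test_bell58_enhances_below_2Tc(self):
        system = synth_reaction_system(SystemTemplate.DEEP_TUNNEL)
        T = 1.5 * crossover_temperature(system.nu_imag_cm1)
        assert corrected_rate(system, T, Tunneling.BELL58_1T) >= tst_rate(system, T)

    def test_deep_tunnel_template_regime_at_room_temperature(self):
        system = synth_reaction_system(SystemTemplate.DEEP_TUNNEL)
        _, regime = crossover_and_regime(system.nu_imag_cm1, 298.0)
        assert regime in (Regime.MODERATE, Regime.DEEP)


class TestThermochemistry:
    def test_enthalpy_cross_check(self):
        system = synth_reaction_system(SystemTemplate.TOY_BIMOLECULAR)
        diff = check_enthalpy_consistency(system, tol_cal_mol=1000.0)
        assert abs(diff) < 1000.0

    def test_inconsistent_enthalpy_warns(self):
        base = synth_reaction_system(SystemTemplate.TOY_BIMOLECULAR)
        from ratekit import ReactionSystem
        system = ReactionSystem(reactants=base.reactants, ts=base.ts,
                                products=base.products, nu_imag_cm1=base.nu_imag_cm1,
                                dH_cal_mol=+10_000.0)
        with pytest.warns(UserWarning):
            check_enthalpy_consistency(system)
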