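"""Broadening, Boltzmann weights, averaging, equilibrium mixing, displacement."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from voapipe.spectra import (
    CompositeSpectrum,
    EquilibriumSpec,
    StickSpectrum,
    boltzmann_weights,
    broaden,
    displace_along_modes,
    equilibrium_fractions,
    make_grid,
    mix_monomer_dimer,
    read_sticks_csv,
    weighted_average,
    write_sticks_csv,
)
from voapipe.synth import make_ring_geometry, make_stick_spectrum

GAS_CONSTANT = 1.987204258640832e-3  # kcal/(mol K)


def single_stick(wn=1000.0, intensity=1.0, obs="ir"):
    return StickSpectrum("s", np.array([wn]), {obs: np.array([intensity])})


class TestBroaden:
    def test_unit_stick_peak_height_closed_form(self):
        grid = make_grid(500.0, 1500.0, 0.5)
        spec = broaden(single_stick(), bandwidth=6.0, grid=grid)
        assert spec.intensities["ir"].max() == pytest.approx(2.0 / (6.0 * math.pi), rel=1e-3)
        assert grid[np.argmax(spec.intensities["ir"])] == pytest.approx(1000.0)

    def test_integral_equals_stick_sum(self):
        stick = StickSpectrum(
            "s", np.array([900.0, 1100.0, 1300.0]), {"ir": np.array([2.0, 5.0, 3.0])}
        )
        # Lorentzian tails are heavy: conservation to 0.5% needs a window of
        # several hundred bandwidths around the sticks
        from voapipe.spectra import grid_for

        grid = grid_for(stick, bandwidth=6.0, margin_bandwidths=600.0)
        spec = broaden(stick, bandwidth=6.0, grid=grid)
        assert spec.integral("ir") == pytest.approx(10.0, rel=0.005)

    def test_scaling_moves_peak_position_only(self):
        grid = make_grid(500.0, 1500.0)
        spec = broaden(single_stick(1000.0, 3.0), bandwidth=6.0, scale=0.98, grid=grid)
        assert grid[np.argmax(spec.intensities["ir"])] == pytest.approx(980.0)
        assert spec.intensities["ir"].max() == pytest.approx(3.0 * 2.0 / (6.0 * math.pi), rel=1e-3)

    def test_uncovered_mode_is_named(self):
        grid = make_grid(500.0, 900.0)
        with pytest.raises(ValueError, match="1000"):
            broaden(single_stick(1000.0), grid=grid)

    def test_linearity(self):
        grid = make_grid(700.0, 1300.0)
        s1 = single_stick(950.0, 2.0)
        s2 = single_stick(1050.0, 4.0)
        both = StickSpectrum("s", np.array([950.0, 1050.0]), {"ir": np.array([2.0, 4.0])})
        direct = broaden(both, grid=grid).intensities["ir"]
        summed = broaden(s1, grid=grid).intensities["ir"] + broaden(s2, grid=grid).intensities["ir"]
        assert np.allclose(direct, summed, atol=1e-12)


class TestBoltzmann:
    def test_equal_energies_uniform(self):
        assert np.allclose(boltzmann_weights([3.0, 3.0, 3.0]), 1.0 / 3.0)

    def test_rt_ln2_gap_gives_two_to_one(self):
        gap = GAS_CONSTANT * 300.0 * math.log(2.0)
        w = boltzmann_weights([0.0, gap], temperature=300.0)
        assert w[0] == pytest.approx(2.0 / 3.0, abs=1e-9)
        assert w[1] == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_huge_gap_stable(self):
        w = boltzmann_weights([0.0, 50.0])
        assert w[0] == pytest.approx(1.0)
        assert 0.0 <= w[1] < 1e-30
        assert np.isfinite(w).all()

    def test_weights_sum_to_one(self, rng):
        w = boltzmann_weights(rng.uniform(0, 10, size=20))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestWeightedAverage:
    def test_identity(self):
        spec = broaden(single_stick(), grid=make_grid(500, 1500))
        out = weighted_average([spec], [1.0])
        assert np.array_equal(out.intensities["ir"], spec.intensities["ir"])

    def test_opposite_spectra_cancel(self):
        grid = make_grid(500, 1500)
        plus = broaden(single_stick(1000.0, 1.0, obs="vcd"), grid=grid)
        minus = broaden(single_stick(1000.0, -1.0, obs="vcd"), grid=grid)
        out = weighted_average([plus, minus], [0.5, 0.5])
        assert np.allclose(out.intensities["vcd"], 0.0, atol=1e-15)

    def test_population_weights_match_manual_summation(self, rng):
        grid = make_grid(600, 2100)
        sticks = [make_stick_spectrum("random", seed=i) for i in range(4)]
        spectra = [broaden(s, grid=grid) for s in sticks]
        w = np.array([0.4, 0.3, 0.2, 0.1])
        out = weighted_average(spectra, w)
        manual = sum(wi * s.intensities["vcd"] for wi, s in zip(w, spectra))
        assert np.allclose(out.intensities["vcd"], manual, atol=1e-12)

    def test_grid_mismatch_raises(self):
        a = broaden(single_stick(), grid=make_grid(500, 1500))
        b = broaden(single_stick(), grid=make_grid(400, 1500))
        with pytest.raises(ValueError, match="grid"):
            weighted_average([a, b], [0.5, 0.5])

    def test_off_unit_weights_renormalised_with_warning(self):
        spec = broaden(single_stick(), grid=make_grid(500, 1500))
        with pytest.warns(UserWarning, match="renormalising"):
            out = weighted_average([spec, spec], [1.0, 1.0])
        assert np.allclose(out.intensities["ir"], spec.intensities["ir"])


class TestEquilibrium:
    def test_no_association_limit(self):
        assert equilibrium_fractions(EquilibriumSpec(0.0, 0.05)) == (1.0, 0.0)

    def test_closed_form_matches_numeric_root(self):
        K, c = 10.0, 0.05
        f_m, f_d = equilibrium_fractions(EquilibriumSpec(K, c))
        m_closed = f_m * c
        assert m_closed == pytest.approx((-1.0 + math.sqrt(5.0)) / 40.0, abs=1e-12)
        assert f_m == pytest.approx(0.6180, abs=1e-4)
        m_numeric = brentq(lambda m: m + 2.0 * K * m * m - c, 0.0, c, xtol=1e-15)
        assert abs(m_closed - m_numeric) < 1e-10

    def test_mass_balance_over_grid(self):
        for K in (0.0, 1e-6, 0.1, 10.0, 1e4):
            for c in (1e-4, 0.05, 1.0):
                f_m, f_d = equilibrium_fractions(EquilibriumSpec(K, c))
                m = f_m * c
                d = K * m * m
                assert m + 2 * d == pytest.approx(c, abs=1e-12 * max(1.0, c))
                assert f_m + f_d == 1.0

    def test_monomer_fraction_monotone_in_K(self):
        fracs = [equilibrium_fractions(EquilibriumSpec(K, 0.05))[0]
                 for K in np.logspace(-3, 6, 40)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] < 0.01  # strong-association limit


class TestMixMonomerDimer:
    def grid(self):
        return make_grid(1500, 2000)

    def test_k_zero_returns_monomer(self):
        g = self.grid()
        mono = broaden(single_stick(1760.0, 1.0), grid=g)
        dim = broaden(single_stick(1700.0, 1.0), grid=g)
        out = mix_monomer_dimer(mono, dim, EquilibriumSpec(0.0, 0.05), "per-molecule")
        assert np.allclose(out.intensities["ir"], mono.intensities["ir"])

    def test_equal_fractions_of_opposite_spectra_cancel(self):
        g = self.grid()
        mono = broaden(single_stick(1760.0, 1.0, obs="vcd"), grid=g)
        dim = CompositeSpectrum(grid=g, intensities={"vcd": -mono.intensities["vcd"]})
        # K and c chosen so the monomer molecule fraction is exactly 1/2
        c = 0.05
        K = (c - c / 2) / (2 * (c / 2) ** 2)
        out = mix_monomer_dimer(mono, dim, EquilibriumSpec(K, c), "per-molecule")
        assert np.allclose(out.intensities["vcd"], 0.0, atol=1e-12)

    def test_per_molecule_weights_match_hand_computation(self):
        g = self.grid()
        mono = broaden(single_stick(1760.0, 1.0), grid=g)
        dim = broaden(single_stick(1700.0, 1.0), grid=g)
        out = mix_monomer_dimer(mono, dim, EquilibriumSpec(10.0, 0.05), "per-molecule")
        f_m = (-1.0 + math.sqrt(5.0)) / 40.0 / 0.05
        manual = f_m * mono.intensities["ir"] + (1 - f_m) * dim.intensities["ir"]
        assert np.allclose(out.intensities["ir"], manual, atol=1e-12)
        assert out.provenance["monomer_weight"] == pytest.approx(0.618034, abs=1e-6)

    def test_per_dimer_convention_halves_dimer_weight(self):
        g = self.grid()
        mono = broaden(single_stick(1760.0, 1.0), grid=g)
        dim = broaden(single_stick(1700.0, 1.0), grid=g)
        a = mix_monomer_dimer(mono, dim, EquilibriumSpec(10.0, 0.05), "per-molecule")
        b = mix_monomer_dimer(mono, dim, EquilibriumSpec(10.0, 0.05), "per-dimer")
        assert b.provenance["dimer_weight"] == pytest.approx(a.provenance["dimer_weight"] / 2)

    def test_normalization_must_be_declared(self):
        g = self.grid()
        mono = broaden(single_stick(1760.0), grid=g)
        with pytest.raises(ValueError, match="declared"):
            mix_monomer_dimer(mono, mono, EquilibriumSpec(10.0, 0.05))


class TestDisplaceAlongModes:
    def setup_method(self):
        self.frame = make_ring_geometry(-157.0, 42.0, oh_torsion=80.0)
        rng = np.random.default_rng(1)
        self.modes = [(30.0 * (k + 1), rng.normal(size=self.frame.coords.shape)) for k in range(3)]

    def test_zero_step_identity(self):
        out = displace_along_modes(self.frame, self.modes[:1], [0.0])
        assert np.array_equal(out[0].coords, self.frame.coords)

    def test_symmetric_steps_average_to_input(self):
        out = displace_along_modes(self.frame, self.modes, [-0.3, 0.3])
        mean = np.mean([f.coords for f in out], axis=0)
        assert np.allclose(mean, self.frame.coords, atol=1e-12)

    def test_three_modes_four_steps_give_twelve_structures(self):
        out = displace_along_modes(self.frame, self.modes, [-0.4, -0.2, 0.2, 0.4])
        assert len(out) == 12
        assert len({f.comment for f in out}) == 12

    def test_atom_count_mismatch_raises(self):
        bad = [(10.0, np.zeros((3, 3)))]
        with pytest.raises(ValueError, match="match"):
            displace_along_modes(self.frame, bad, [0.1])


class TestSticksIO:
    def test_csv_round_trip(self, tmp_path):
        sticks = [make_stick_spectrum("random", seed=i, energy=float(i)) for i in range(3)]
        path = tmp_path / "sticks.csv"
        write_sticks_csv(sticks, path)
        back = read_sticks_csv(path)
        assert len(back) == 3
        by_id = {s.structure_id: s for s in back}
        for orig in sticks:
            got = by_id[orig.structure_id]
            assert np.allclose(got.wavenumbers, orig.wavenumbers, rtol=1e-6)
            assert np.allclose(got.intensities["vcd"], orig.intensities["vcd"], rtol=1e-6)
            assert got.energy == orig.energy

    def test_negative_ir_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            StickSpectrum("s", np.array([100.0]), {"ir": np.array([-1.0])})

    def test_nonpositive_wavenumber_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            StickSpectrum("s", np.array([0.0]), {"ir": np.array([1.0])})
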