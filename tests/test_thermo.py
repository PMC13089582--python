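"""Ensemble estimators: compressibility, energies, solvation, free-energy assembly."""

import math

import numpy as np
import pandas as pd
import pytest

import piezorho as pz
from piezorho.thermo import (
    KB_J,
    MPA_A3_TO_KCAL_MOL,
    BlockEstimate,
    ConditionComponents,
)


def make_series(**columns):
    n = len(next(iter(columns.values())))
    frame = pd.DataFrame({"time": np.arange(n, dtype=float), **columns})
    return pz.EnsembleSeries(frame=frame)


class TestIsothermalCompressibility:
    def test_constant_volume_gives_zero(self):
        series = make_series(volume=np.full(100, 5e5), temperature=np.full(100, 300.0))
        est = pz.isothermal_compressibility(series)
        assert est.value == 0.0 and est.sd == 0.0

    def test_gaussian_oracle(self):
        """i.i.d. Gaussian volumes: kappa_T -> sigma^2 / (k_B T mu_V)."""
        spec = pz.EnsembleSimSpec(seed=3, n_frames=100_000, kappa_T=0.45,
                                  mean_volume=5e5)
        series = pz.simulate_volume_series(spec)
        est = pz.isothermal_compressibility(
            series, pz.ThermoConstants(tail_fraction=1.0))
        assert est.value == pytest.approx(0.45, rel=0.03)
        assert est.sd > 0

    def test_unit_scale_consistency(self):
        """Doubling all volumes doubles the estimator (var/mean scaling)."""
        spec = pz.EnsembleSimSpec(seed=9, n_frames=20_000, kappa_T=0.3,
                                  mean_volume=4e5)
        series = pz.simulate_volume_series(spec)
        doubled = make_series(volume=2 * series.frame["volume"].to_numpy(),
                              temperature=series.frame["temperature"].to_numpy())
        base = pz.isothermal_compressibility(series, pz.ThermoConstants(tail_fraction=1.0))
        scaled = pz.isothermal_compressibility(doubled, pz.ThermoConstants(tail_fraction=1.0))
        assert scaled.value == pytest.approx(2 * base.value, rel=1e-9)

    def test_two_condition_difference(self):
        low = pz.simulate_volume_series(pz.EnsembleSimSpec(
            seed=4, n_frames=60_000, kappa_T=0.30, mean_volume=5e5))
        high = pz.simulate_volume_series(pz.EnsembleSimSpec(
            seed=5, n_frames=60_000, kappa_T=0.45, mean_volume=5e5))
        constants = pz.ThermoConstants(tail_fraction=1.0)
        diff = (pz.isothermal_compressibility(high, constants).value
                - pz.isothermal_compressibility(low, constants).value)
        assert diff == pytest.approx(0.15, abs=0.02)

    def test_empty_window_rejected(self):
        series = make_series(volume=np.array([5e5]))
        with pytest.raises(ValueError, match="at least 2 frames"):
            pz.isothermal_compressibility(series, pz.ThermoConstants(tail_fraction=1.0))

    def test_missing_volume_column(self):
        series = make_series(temperature=np.full(10, 300.0))
        with pytest.raises(ValueError, match="volume"):
            pz.isothermal_compressibility(series)


class TestConformationalEnergy:
    def test_zero_terms_give_zero(self):
        series = make_series(bond=np.zeros(30), lj_sr=np.zeros(30))
        est = pz.conformational_energy(series, ("bond", "lj_sr"),
                                       pz.ThermoConstants(tail_fraction=1.0))
        assert est.value == 0.0

    def test_three_frame_hand_computation(self):
        series = make_series(bond=np.array([1.0, 2.0, 3.0]),
                             lj_sr=np.array([-0.5, 0.5, 0.0]),
                             coulomb_sr=np.array([10.0, 10.0, 10.0]))
        est = pz.conformational_energy(series, ("bond", "lj_sr", "coulomb_sr"),
                                       pz.ThermoConstants(tail_fraction=1.0))
        # frame sums: 10.5, 12.5, 13.0 -> mean 12.0
        assert est.value == pytest.approx(12.0)

    def test_missing_column_named_in_error(self):
        series = make_series(bond=np.zeros(5))
        with pytest.raises(ValueError, match="cmap"):
            pz.conformational_energy(series, ("bond", "cmap"))

    def test_default_term_list_covers_bonded_and_nonbonded(self):
        from piezorho.thermo import CONFORMATIONAL_TERMS

        assert {"bond", "urey_bradley", "proper_dihedral", "improper_dihedral",
                "cmap"} <= set(CONFORMATIONAL_TERMS)
        assert {"coulomb_sr", "lj_sr", "coulomb_14", "lj_14"} <= set(CONFORMATIONAL_TERMS)

    def test_kj_conversion_on_read(self, tmp_path):
        path = tmp_path / "obs.tsv"
        make_series(bond=np.array([4.184, 8.368]),
                    volume=np.array([1e5, 1e5])).to_file(path)
        series = pz.EnsembleSeries.from_file(path, energy_unit="kJ")
        assert series.frame["bond"].tolist() == pytest.approx([1.0, 2.0])
        assert series.frame["volume"].tolist() == [1e5, 1e5]  # not converted


class TestNonpolarSolvation:
    def test_zero_inputs_give_zero(self):
        assert pz.nonpolar_solvation(0.0, 123.0, 0.0) == 0.0

    def test_unit_conversion_oracle(self):
        """1 MPa * 1 A^3 = 1e-24 J -> N_A/4184 kcal/mol."""
        expected = 1e-24 * 6.02214076e23 / 4184.0
        constants = pz.ThermoConstants(surface_tension=0.1032)
        value = pz.nonpolar_solvation(1.0, 1.0, 0.0, constants)
        assert value == pytest.approx(expected, rel=1e-12)
        assert value == pytest.approx(1.439e-4, rel=1e-3)

    def test_surface_term_uses_default_tension(self):
        value = pz.nonpolar_solvation(0.0, 0.0, 100.0)
        assert value == pytest.approx(0.1032 * 100.0)
        assert pz.ThermoConstants().surface_tension == 0.1032

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            pz.nonpolar_solvation(-1.0, 1.0, 1.0)


def const(value, sd=0.0):
    return BlockEstimate(value=value, sd=sd, n_blocks=5)


class TestFreeEnergyAssembly:
    def test_zero_components_give_zero(self):
        low = ConditionComponents("low", const(0.0), 0.0, const(0.0))
        high = ConditionComponents("high", const(0.0), 0.0, const(0.0))
        decomp = pz.free_energy_shift(low, high)
        assert decomp.delta_g.value == 0.0

    @pytest.mark.parametrize("de,mtds,ddmu,dg", [
        (-56.0, 14.0, 285.0, 243.0),
        (98.0, -26.0, 274.0, 346.0),
        (2.0, -1.0, 251.0, 252.0),
        (-66.0, 17.0, 257.0, 208.0),
    ])
    def test_reported_decompositions_are_additive(self, de, mtds, ddmu, dg):
        """The four published component triplets assemble exactly."""
        assert pz.assemble_free_energy(de, mtds, ddmu) == pytest.approx(dg)

    def test_assembly_identity_exact_for_any_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            de, s_low, s_high, mu_l, mu_h = rng.normal(size=5) * 100
            T = 300.0
            low = ConditionComponents("low", const(0.0), s_low / T, const(mu_l))
            high = ConditionComponents("high", const(de), s_high / T, const(mu_h))
            decomp = pz.free_energy_shift(low, high)
            assert decomp.delta_g.value == pytest.approx(
                decomp.delta_e_conf.value + decomp.minus_t_delta_s.value
                + decomp.delta_delta_mu.value, abs=1e-9)

    def test_uncertainty_propagates_in_quadrature(self):
        low = ConditionComponents("low", const(10.0, 3.0), 0.0, const(5.0, 4.0))
        high = ConditionComponents("high", const(12.0, 4.0), 0.0, const(9.0, 3.0))
        decomp = pz.free_energy_shift(low, high)
        assert decomp.delta_e_conf.sd == pytest.approx(5.0)
        assert decomp.delta_delta_mu.sd == pytest.approx(5.0)
        assert decomp.delta_g.sd == pytest.approx(math.hypot(5.0, 0.0, 5.0))

    def test_summary_prints_all_components(self):
        low = ConditionComponents("low", const(1.0), 0.001, const(2.0))
        high = ConditionComponents("high", const(3.0), 0.002, const(4.0))
        text = pz.free_energy_shift(low, high).summary()
        for token in ("dE_conf", "-T dS", "ddmu", "dG_p"):
            assert token in text


class TestSolvationFreeEnergy:
    def test_polar_plus_nonpolar_composition(self):
        series = make_series(volume=np.full(10, 1000.0), area=np.full(10, 200.0))
        constants = pz.ThermoConstants(tail_fraction=1.0)
        est = pz.solvation_free_energy(series, 30.0, constants, polar=-50.0)
        expected = -50.0 + 30.0 * 1000.0 * MPA_A3_TO_KCAL_MOL + 0.1032 * 200.0
        assert est.value == pytest.approx(expected)

    def test_missing_polar_input_rejected(self):
        series = make_series(volume=np.full(10, 1000.0), area=np.full(10, 200.0))
        with pytest.raises(ValueError, match="polar"):
            pz.solvation_free_energy(series, 30.0)


class TestWindowing:
    def test_tail_window_selects_final_fraction(self):
        series = make_series(volume=np.arange(1.0, 101.0))
        win = series.window(0.5)
        assert len(win) == 50
        assert win.frame["volume"].iloc[0] == 51.0

    def test_constants_validation(self):
        with pytest.raises(ValueError):
            pz.ThermoConstants(temperature=-1.0)
        with pytest.raises(ValueError):
            pz.ThermoConstants(tail_fraction=1.5)
        defaults = pz.ThermoConstants()
        assert (defaults.dielectric_low, defaults.dielectric_high) == (77.75, 78.83)
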