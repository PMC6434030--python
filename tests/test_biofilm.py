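import numpy as np
import pytest

from biofilm_assembly.biofilm import (
    BiofilmConfig,
    BiofilmModel,
    GuildKinetics,
    penetration_depth_um,
    z400_config,
    z50_config,
)


def zero_order_config(**overrides) -> BiofilmConfig:
    """Single solute (DO), near-zero-order kinetics, no boundary layer."""
    kw = dict(
        thickness_um=400,
        n_nodes=400,
        boundary_layer_um=0.0,
        bulk={"do": 8.0, "nh4": 0.0, "no2": 0.0, "cod": 0.0},
        density_profile=50.0,
        guild_fractions={"zero": 1.0},
        kinetics={
            "zero": GuildKinetics("do", q_max=10.0, K_sub=1e-6, K_o2=1e-6, gamma_o2=0.0)
        },
        active_fraction=1.0,
    )
    kw.update(overrides)
    return BiofilmConfig(**kw)


def mass_balance_error(profile, solute):
    j = profile.interface_flux[solute]
    c = profile.integrated_consumption[solute]
    return abs(j - c) / max(abs(j), abs(c), 1e-12)


class TestSolver:
    def test_no_reaction_limit_is_flat_at_bulk(self):
        cfg = z400_config(density_profile=0.0)
        p = BiofilmModel(cfg).solve_profile()
        np.testing.assert_allclose(p.concentrations["do"], 5.5, atol=1e-9)
        assert p.anoxic_fraction == 0.0
        assert abs(p.interface_flux["do"]) < 1e-9

    def test_zero_order_penetration_depth(self):
        cfg = zero_order_config()
        p = BiofilmModel(cfg).solve_profile()
        k0 = 10.0 * 1.0 * 50e3  # q * f * X, g O2/m3/d
        delta_um = np.sqrt(2 * cfg.diffusivity_film["do"] * 8.0 / k0) / 1e-6
        measured = penetration_depth_um(p, threshold=8.0 * 1e-5)
        assert measured == pytest.approx(delta_um, rel=0.01)

    def test_fully_penetrated_parabola(self):
        # thin film, zero-order: S(z) = S_L - (k0/2D)(L^2 - z^2)
        cfg = zero_order_config(
            thickness_um=50,
            n_nodes=200,
            kinetics={
                "zero": GuildKinetics("do", q_max=2.0, K_sub=1e-6, K_o2=1e-6,
                                      gamma_o2=0.0)
            },
        )
        p = BiofilmModel(cfg).solve_profile()
        k0 = 2.0 * 50e3
        D = cfg.diffusivity_film["do"]
        z = p.depth_um * 1e-6
        L = 50e-6
        analytic = 8.0 - (k0 / (2 * D)) * (L**2 - z**2)
        assert np.max(np.abs(p.concentrations["do"] - analytic) / 8.0) < 0.005

    @pytest.mark.parametrize("preset", [z50_config, z400_config])
    @pytest.mark.parametrize("f", [0.2, 0.8])
    def test_mass_balance_all_solutes(self, preset, f):
        cfg = preset(active_fraction=f)
        p = BiofilmModel(cfg).solve_profile()
        for solute in ("do", "nh4", "no2", "cod"):
            assert mass_balance_error(p, solute) < 1e-3

    def test_concentrations_bounded_by_bulk_do(self):
        p = BiofilmModel(z400_config()).solve_profile()
        do = p.concentrations["do"]
        assert (do >= 0).all() and (do <= 5.5 + 1e-9).all()

    def test_grid_convergence_of_anoxic_depth(self):
        d = {}
        for n in (200, 400):
            cfg = z400_config(n_nodes=n)
            d[n] = BiofilmModel(cfg).solve_profile().anoxic_depth_um()
        assert abs(d[400] - d[200]) / d[400] < 0.01

    def test_stoichiometric_nitrite_balance_without_nob(self):
        # AOB only: areal NO2-N production must equal areal NH4-N consumption
        cfg = z400_config(
            guild_fractions={"aob": 0.3},
            bulk={"do": 5.5, "nh4": 19.6, "no2": 0.0, "cod": 0.0},
        )
        p = BiofilmModel(cfg).solve_profile()
        nh4_in = p.interface_flux["nh4"]
        no2_out = -p.interface_flux["no2"]  # production leaves the biofilm
        assert no2_out == pytest.approx(nh4_in, rel=0.005)


class TestCalibration:
    def test_round_trip_recovers_boundary_layer(self):
        m = BiofilmModel(z400_config())
        target = m.nh4_areal_rate(100.0)
        assert m.calibrate_boundary_layer(target) == pytest.approx(100.0, abs=1.0)

    def test_unattainable_target_reports_range(self):
        m = BiofilmModel(z400_config())
        too_high = m.nh4_areal_rate(1.0) * 2
        with pytest.raises(ValueError, match="attainable"):
            m.calibrate_boundary_layer(too_high)

    def test_flux_monotone_in_bulk_ammonium(self):
        fluxes = []
        for nh4 in (19.6, 15.0, 10.0, 5.0, 2.5):
            cfg = z400_config()
            cfg.bulk["nh4"] = nh4
            fluxes.append(BiofilmModel(cfg).solve_profile().interface_flux["nh4"])
        assert all(a > b for a, b in zip(fluxes, fluxes[1:]))


class TestSweep:
    def test_monotone_do_envelope(self):
        res = BiofilmModel(z50_config()).scenario_sweep([0.2, 0.8])
        do_low = res.profiles[0.2].concentrations["do"]
        do_high = res.profiles[0.8].concentrations["do"]
        assert (do_high <= do_low + 1e-9).all()
        assert res.monotone

    def test_thick_film_always_partially_anoxic(self):
        res = BiofilmModel(z400_config()).scenario_sweep([0.2, 0.4, 0.6, 0.8])
        assert all(v > 0 for v in res.anoxic_fractions.values())

    def test_thin_film_straddles_full_oxygenation(self):
        res = BiofilmModel(z50_config()).scenario_sweep([0.2, 0.4, 0.6, 0.8])
        vals = list(res.anoxic_fractions.values())
        assert any(v == 0 for v in vals) and any(v > 0 for v in vals)

    def test_needs_two_scenarios(self):
        with pytest.raises(ValueError):
            BiofilmModel(z50_config()).scenario_sweep([0.5])


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = z400_config()
        cfg.to_yaml(tmp_path / "m.yaml")
        cfg2 = BiofilmConfig.from_yaml(tmp_path / "m.yaml")
        p1 = BiofilmModel(cfg).solve_profile()
        p2 = BiofilmModel(cfg2).solve_profile()
        np.testing.assert_allclose(
            p1.concentrations["do"], p2.concentrations["do"], atol=1e-12
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            BiofilmConfig(thickness_um=-1)
        with pytest.raises(ValueError):
            BiofilmConfig(active_fraction=0.0)
        with pytest.raises(ValueError):
            BiofilmConfig(guild_fractions={"het": 1.5})
        with pytest.raises(ValueError):
            GuildKinetics("do", q_max=1, K_sub=0.0, K_o2=1, gamma_o2=1)
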