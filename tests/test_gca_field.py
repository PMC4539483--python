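"""Linearization, geometry, spectral field solver and its FD oracle."""

import dataclasses

import numpy as np
import pytest

from astroca.gca import (
    CellGeometry,
    GreensFieldSolver,
    PhysiologicalParams,
    calibrate_channel_flux,
    fd_oracle,
    field_solve,
    generate_geometry,
    linearize,
)


class TestLinearize:
    def test_leak_balances_pump_at_rest(self):
        p = PhysiologicalParams()
        # resting balance: sigma_l (E0 - Ca0) = P_p Ca0
        assert p.sigma_leak(150.0) == pytest.approx(0.0103, abs=2e-4)
        assert p.sigma_leak(0.0) == 0.0

    def test_resting_state_is_exact_fixed_point(self):
        c = linearize(PhysiologicalParams(), 86.0)
        assert np.allclose(c.reaction @ np.zeros(4), 0.0)
        # the gamma-weighted total is conserved by the reaction matrix
        assert np.abs(c.conserved_weights @ c.reaction).max() < 1e-10
        assert c.conserved_weights @ c.source_vec == pytest.approx(0.0)

    def test_pump_rate_scan_changes_only_rates(self):
        p = PhysiologicalParams()
        c1, c2 = linearize(p, 22.0), linearize(p, 152.0)
        # buffer kinetics blocks are pump-independent
        assert np.allclose(c1.reaction[2:], c2.reaction[2:])
        assert c1.sigma_l < c2.sigma_l

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PhysiologicalParams(radius=-1.0)


class TestGeometry:
    def test_default_geometry_satisfies_invariants(self):
        geo = generate_geometry(rng_seed=1)
        assert geo.n_clusters == 31
        d = np.linalg.norm(geo.positions[:, None] - geo.positions[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 1.5
        assert np.linalg.norm(geo.positions, axis=1).max() <= 8.0
        assert geo.channels.min() >= 2 and geo.channels.max() <= 16

    def test_single_cluster(self):
        geo = generate_geometry(n_clusters=1, rng_seed=0)
        assert np.linalg.norm(geo.positions[0]) <= 8.0

    def test_mean_total_channels_matches_expectation(self):
        # E[uniform{2..16}] = 9 per cluster, 31 clusters -> 279
        totals = [
            generate_geometry(rng_seed=s).n_channels_total for s in range(150)
        ]
        assert np.mean(totals) == pytest.approx(279.0, abs=5.0)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            generate_geometry(n_clusters=500, radius=3.0, rng_seed=0)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            CellGeometry(positions=[[0, 0, 0], [0.5, 0, 0]], channels=[4, 4])
        with pytest.raises(ValueError, match="placement"):
            CellGeometry(positions=[[9.5, 0, 0]], channels=[4])


class TestSpectralSolver:
    def test_empty_history_zero_everywhere(self, small_coeffs, small_cell):
        _, geo = small_cell
        dev = field_solve(small_coeffs, geo, [], np.array([[0.0, 0.0, 0.0]]), 5.0)
        assert np.allclose(dev, 0.0)

    def test_mean_grows_linearly_without_reactions(self, small_coeffs, small_cell):
        """Always-on source, no reactions: conservation with the no-flux
        boundary forces the spatial mean to grow at (flux)/(volume)."""
        _, geo = small_cell
        pure = dataclasses.replace(small_coeffs, reaction=np.zeros((4, 4)))
        solver = GreensFieldSolver(pure, geo)
        q = 123.0
        solver.set_source(0, q)
        solver.advance(3.0)
        expected = q * 3.0 / solver.volume
        assert solver.mean_ca_dev() == pytest.approx(expected, rel=1e-9)

    def test_gamma_weighted_total_is_conserved_with_pump_off(self, small_cell):
        params, geo = small_cell
        coeffs = linearize(params, 0.0)  # no pump, hence no leak
        solver = GreensFieldSolver(coeffs, geo)
        solver.set_source(0, 500.0)
        solver.advance(2.0)
        solver.set_source(0, 0.0)
        solver.advance(3.0)
        injected_cyt = 500.0 * 2.0  # equal and opposite amount left the ER
        assert abs(solver.total_conserved()) < 1e-3 * injected_cyt

    def test_resting_state_stays_at_rest(self, small_coeffs, small_cell):
        _, geo = small_cell
        solver = GreensFieldSolver(small_coeffs, geo)
        solver.advance(10.0)
        assert solver.local_ca_dev() == pytest.approx(np.zeros(3), abs=1e-15)
        assert solver.mean_ca_dev() == 0.0


class TestOracleAgreement:
    def test_cluster_sites_agree_within_5_percent(self, oracle_setup):
        spec, fd = oracle_setup
        for t in (1.5, 4.0):
            rel = np.abs(spec[t]["sites"] - fd[t]["sites"]) / np.abs(fd[t]["sites"])
            assert rel.max() < 0.05, f"t={t}: {rel}"

    def test_probe_2um_from_source_agrees_within_5_percent(self, oracle_setup):
        spec, fd = oracle_setup
        rel = abs(spec[1.5]["probe"][0] - fd[1.5]["probe"][0]) / abs(
            fd[1.5]["probe"][0]
        )
        assert rel < 0.05

    def test_fd_zero_sources_zero_field(self, small_coeffs, small_cell):
        _, geo = small_cell
        sol = fd_oracle(small_coeffs, geo, [], grid_spacing=0.5, t=0.5, dt=5e-3)
        assert np.allclose(sol.x, 0.0)

    def test_fd_grid_must_resolve_separation(self, small_coeffs, small_cell):
        _, geo = small_cell
        with pytest.raises(ValueError, match="resolve"):
            fd_oracle(small_coeffs, geo, [], grid_spacing=2.0, t=0.1)


class TestFdConservation:
    def test_pure_diffusion_pulse_conserves_mass(self, small_cell):
        from astroca.gca import _FDSolver

        params, geo = small_cell
        coeffs = dataclasses.replace(
            linearize(params, 0.0), reaction=np.zeros((4, 4))
        )
        sol = _FDSolver(coeffs, geo, h=0.5, dt=5e-3, channel_flux=0.0)
        # off-center pulse in the cytosolic field
        d = np.linalg.norm(sol.centers - np.array([1.5, 0.0, 0.0]), axis=1)
        sol.x[0] = np.exp(-0.5 * (d / 0.6) ** 2)
        before = sol.total_component(0)
        sol.run_until(2.0)
        after = sol.total_component(0)
        assert after == pytest.approx(before, rel=1e-3)

    def test_source_history_conserves_weighted_total_with_pump_off(
        self, small_cell
    ):
        params, geo = small_cell
        coeffs = linearize(params, 0.0)
        sol = fd_oracle(coeffs, geo, [(0, 6, (0.0, 1.0))], grid_spacing=0.5,
                        t=2.0, channel_flux=50.0, dt=5e-3)
        injected = 50.0 * 6 * (coeffs.er_rest - coeffs.ca_rest) * 1.0
        assert abs(sol.total_conserved()) < 1e-3 * injected


class TestCalibration:
    def test_target_at_rest_needs_no_flux(self, small_cell):
        params, geo = small_cell
        assert calibrate_channel_flux(params, geo,
                                      target_local_peak=params.ca_rest) == 0.0

    def test_wider_regularization_lowers_the_peak(self, small_cell):
        params, geo = small_cell
        coeffs = linearize(params, 86.0)
        peaks = []
        for reg in (0.05, 0.1):
            p2 = dataclasses.replace(params, regularization_radius=reg)
            c2 = linearize(p2, 86.0)
            solver = GreensFieldSolver(c2, geo)
            solver.set_source(0, 1000.0)
            for _ in range(20):
                solver.advance(0.5)
            peaks.append(solver.local_ca_dev()[0])
        assert peaks[1] < peaks[0]

    def test_calibration_stable_across_geometry_seeds(self):
        params = PhysiologicalParams()
        pcs = []
        for seed in (11, 12):
            geo = generate_geometry(rng_seed=seed)
            pcs.append(calibrate_channel_flux(params, geo))
        assert pcs[0] == pytest.approx(pcs[1], rel=0.02)

    def test_calibrated_flux_hits_target(self, small_cell):
        params, geo = small_cell
        pc = calibrate_channel_flux(params, geo, target_local_peak=100.0)
        coeffs = linearize(params, params.pump_rate)
        ref = 1  # cluster with count closest to the reference count 9
        solver = GreensFieldSolver(coeffs, geo,
                                   eval_points=geo.positions[[ref]])
        solver.set_source(ref, pc * 9 * (coeffs.er_rest - coeffs.ca_rest))
        for _ in range(60):
            solver.advance(0.5)
        peak = coeffs.ca_rest + solver.local_ca_dev()[0]
        assert peak == pytest.approx(100.0, rel=0.05)
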