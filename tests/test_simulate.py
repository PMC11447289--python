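"""Synthetic-data generators: statistical structure and determinism."""

import numpy as np
import pytest

from bbbkit import (
    AssaySimConfig,
    ImageSimConfig,
    TrackSimConfig,
    analyze_record,
    compute_msd,
    endothelial_permeability,
    fold_change,
    furth_msd,
    ou_velocity_series,
    simulate_assay,
    simulate_count_table,
    simulate_image_batch,
    simulate_images,
    simulate_tracks,
    system_permeability,
    transmigration_ratio,
    z_profile,
)
from bbbkit.io import tracks_to_frame


class TestTrackGenerator:
    def test_zero_speed_cells_are_stationary(self):
        cfg = TrackSimConfig(n_cells=5, true_speed=0.0, n_frames=50, seed=1)
        for tr in simulate_tracks(cfg):
            assert np.all(tr.x == tr.x[0])
            assert np.all(tr.y == tr.y[0])

    def test_seed_determinism_bit_identical(self):
        cfg = TrackSimConfig(n_cells=8, n_frames=60, responder_fraction=0.5,
                             falloff_hazard=0.1, seed=7)
        a = tracks_to_frame(simulate_tracks(cfg))
        b = tracks_to_frame(simulate_tracks(cfg))
        assert a.equals(b)

    def test_velocity_stationary_variance(self):
        # time-average of |v|² matches S² within 3%
        v = ou_velocity_series(speed=15.0, persistence=30.0, dt=4.0,
                               n_steps=200_000, seed=11)
        s2 = (15.0 / 60.0) ** 2
        assert np.mean(np.sum(v * v, axis=1)) == pytest.approx(s2, rel=0.03)

    def test_population_msd_matches_furth(self):
        # ensemble MSD at lags dt..50dt within 5% RMS relative error
        cfg = TrackSimConfig(n_cells=600, true_speed=15.0, true_persistence=20.0,
                             n_frames=201, fov_size=(1e6, 1e6), seed=5)
        curve = compute_msd(simulate_tracks(cfg), max_lag_fraction=0.25)
        theory = furth_msd(curve.lag, 15.0 / 60.0, 20.0)
        rel = (curve.msd - theory) / theory
        assert np.sqrt(np.mean(rel ** 2)) < 0.05

    def test_ballistic_and_diffusive_limits(self):
        s_um_s, p = 15.0 / 60.0, 30.0
        # short-lag limit: msd/(S²τ²) → 1; long-lag: msd/τ → n·S²·P
        cfg = TrackSimConfig(n_cells=800, true_speed=15.0, true_persistence=p,
                             dt=1.0, n_frames=1201, fov_size=(1e6, 1e6), seed=9)
        curve = compute_msd(simulate_tracks(cfg), max_lag_fraction=0.5,
                            min_track_length=2)
        short = curve.msd[0] / (s_um_s * curve.lag[0]) ** 2
        assert short == pytest.approx(1.0, rel=0.10)
        long_idx = curve.lag >= 20 * p
        diffusive = np.mean(curve.msd[long_idx] / curve.lag[long_idx])
        assert diffusive == pytest.approx(2 * s_um_s**2 * p, rel=0.10)

    def test_boundary_reflection_keeps_cells_in_fov(self):
        cfg = TrackSimConfig(n_cells=30, true_speed=20.0, true_persistence=60.0,
                             fov_size=(50.0, 50.0), n_frames=200, seed=3)
        tracks = simulate_tracks(cfg)
        for tr in tracks:
            assert np.all((tr.x >= 0) & (tr.x <= 50.0))
            assert np.all((tr.y >= 0) & (tr.y <= 50.0))
        # a tight FOV at this speed must reflect someone, and flag it
        assert any(tr.boundary_flag for tr in tracks)

    def test_zero_persistence_rejected(self):
        with pytest.raises(ValueError, match="persistence"):
            TrackSimConfig(true_persistence=0.0)

    def test_nonfinite_speed_rejected(self):
        with pytest.raises(ValueError):
            TrackSimConfig(true_speed=float("nan"))


class TestCountGenerator:
    def test_no_responders_no_transmigration(self):
        cfg = TrackSimConfig(n_cells=50, responder_fraction=0.0, seed=2)
        table = simulate_count_table(cfg, cadence=30)
        assert np.all(table.transmigrated == 0)
        assert np.all(table.lost == 0)

    def test_conservation_at_every_sampled_frame(self):
        cfg = TrackSimConfig(n_cells=120, responder_fraction=0.6,
                             falloff_hazard=0.2, reverse_hazard=0.05, seed=8)
        table = simulate_count_table(cfg, cadence=10)
        assert np.all(table.total == 120)

    def test_no_falloff_keeps_fov_population_constant(self):
        cfg = TrackSimConfig(n_cells=80, responder_fraction=0.5,
                             falloff_hazard=0.0, seed=4)
        table = simulate_count_table(cfg, cadence=30)
        assert np.all(table.lost == 0)
        assert np.all(table.luminal + table.transmigrated == 80)

    def test_plateau_equals_responder_fraction(self):
        # with no reverse migration the late-window transmigrated fraction
        # converges to the responder fraction
        ratios = []
        for seed in range(20):
            cfg = TrackSimConfig(n_cells=200, responder_fraction=0.5,
                                 diapedesis_hazard=0.3, seed=seed)
            table = simulate_count_table(cfg, cadence=30)
            ratios.append(transmigration_ratio(table).ratio)
        assert np.mean(ratios) == pytest.approx(50.0, abs=3.0)

    def test_cadence_bounds(self):
        cfg = TrackSimConfig(n_cells=5, n_frames=50, seed=1)
        with pytest.raises(ValueError):
            simulate_count_table(cfg, cadence=0)
        with pytest.raises(ValueError):
            simulate_count_table(cfg, cadence=60)

    def test_seed_determinism(self):
        cfg = TrackSimConfig(n_cells=40, responder_fraction=0.4, seed=7)
        a = simulate_count_table(cfg, cadence=30).to_frame()
        b = simulate_count_table(cfg, cadence=30).to_frame()
        assert a.equals(b)


class TestAssayGenerator:
    def test_noiseless_round_trip_recovers_true_pe(self):
        cfg = AssaySimConfig(true_Pe=0.41e-3, noise_cv=0.0, n_devices=3, seed=0)
        for rec in simulate_assay(cfg):
            res = analyze_record(rec)
            assert res.Pe == pytest.approx(0.41e-3, rel=1e-12)

    def test_sink_estimate_close_to_ode_truth(self):
        # when Ct/Ci < 0.05 the linear sink estimator is within 5% of the
        # two-compartment solution
        cfg = AssaySimConfig(true_Pe=0.6e-3, noise_cv=0.0, n_devices=1,
                             transport_model="two_compartment_ode", seed=0)
        rec = simulate_assay(cfg)[0]
        assert rec.Ct / rec.Ci < 0.05
        ps = system_permeability(rec)
        pe = endothelial_permeability(ps, cfg.membrane_Pm)
        assert pe == pytest.approx(0.6e-3, rel=0.05)

    def test_ode_solution_matches_scipy_integration(self):
        # closed-form equilibration equals a numerical solve_ivp oracle
        from scipy.integrate import solve_ivp

        cfg = AssaySimConfig(true_Pe=5e-3, membrane_Pm=2e-2, noise_cv=0.0,
                             n_devices=1, duration=240.0,
                             transport_model="two_compartment_ode", seed=0)
        rec = simulate_assay(cfg)[0]
        ps, a = cfg.true_Ps, cfg.area
        vt, vb, ci = cfg.top_volume, cfg.bottom_volume, cfg.Ci

        def rhs(t, y):
            cb = y[0]
            ctop = (ci * vt - cb * vb) / vt
            return [ps * a * (ctop - cb) / vb]

        sol = solve_ivp(rhs, (0, cfg.duration), [0.0], rtol=1e-10, atol=1e-12)
        assert rec.Ct == pytest.approx(sol.y[0, -1], rel=1e-6)

    def test_noisy_recovery_unbiased(self):
        # plate-reader noise at 5% CV leaves the mean recovered Pe within 2%
        pes = []
        for seed in range(50):
            cfg = AssaySimConfig(true_Pe=0.41e-3, noise_cv=0.05, n_devices=11,
                                 seed=seed)
            recs = simulate_assay(cfg)
            mean_ps = np.mean([system_permeability(r) for r in recs])
            pes.append(endothelial_permeability(mean_ps, cfg.membrane_Pm))
        assert np.mean(pes) == pytest.approx(0.41e-3, rel=0.02)

    def test_membrane_slower_than_cells_rejected(self):
        with pytest.raises(ValueError, match="membrane_Pm"):
            AssaySimConfig(true_Pe=1e-2, membrane_Pm=5e-3)

    def test_generated_concentration_below_loading(self):
        cfg = AssaySimConfig(true_Pe=1e-2, membrane_Pm=0.5, noise_cv=0.3,
                             n_devices=50, seed=6)
        for rec in simulate_assay(cfg):
            assert 0 <= rec.Ct < rec.Ci


class TestImageGenerator:
    def test_unit_fold_no_noise_matches_control(self):
        cfg = ImageSimConfig(shape=(16, 16), fold_change=1.0, noise_sigma=0.0,
                             seed=0)
        treated = simulate_images(cfg)
        control = simulate_images(ImageSimConfig(shape=(16, 16), seed=1))
        np.testing.assert_array_equal(treated, control)

    def test_mean_intensity_scales_with_fold(self):
        cfg = ImageSimConfig(shape=(16, 16), fold_change=2.3, noise_sigma=0.0)
        assert simulate_images(cfg).mean() == pytest.approx(2300.0)

    def test_single_layer_at_membrane_peaks_at_zero(self):
        cfg = ImageSimConfig(shape=(21, 8, 8), layer_centers=[0.0],
                             membrane_index=10, noise_sigma=0.0)
        prof = z_profile(simulate_images(cfg), membrane_index=10)
        assert prof.peak_z == pytest.approx(0.0)

    def test_fold_change_pipeline_recovers_truth(self):
        # 12+12 images, 5% noise, 20 seeds: recovered fold within 5% of 2.3
        means = []
        for seed in range(20):
            cfg = ImageSimConfig(shape=(64, 64), fold_change=2.3,
                                 noise_sigma=50.0, seed=seed)
            controls, treated = simulate_image_batch(cfg, 12, 12)
            means.append(fold_change(treated, controls).mean_treated)
        assert np.mean(means) == pytest.approx(2.3, rel=0.05)

    def test_batch_determinism(self):
        cfg = ImageSimConfig(shape=(8, 8), fold_change=1.4, noise_sigma=20.0,
                             seed=3)
        c1, t1 = simulate_image_batch(cfg, 2, 2)
        c2, t2 = simulate_image_batch(cfg, 2, 2)
        for a, b in zip(c1 + t1, c2 + t2):
            np.testing.assert_array_equal(a, b)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            ImageSimConfig(shape=(0, 5))
        with pytest.raises(ValueError):
            ImageSimConfig(shape=(4,))
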