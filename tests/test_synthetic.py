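import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats as sps

from magnetoguide import geometry, stats
from magnetoguide.synthetic import (
    MMP_IGG,
    MMP_SA,
    ExperimentConfig,
    LabelingModel,
    generate_experiment,
    sample_cells,
    sample_positions,
    synth_tracks,
)


class TestLabelingModel:
    def test_presets_match_observed_calibration(self):
        assert MMP_SA.p_bind == 0.823
        assert MMP_SA.overall_mean == pytest.approx(2.8)
        assert MMP_IGG.p_bind == 0.127
        assert MMP_IGG.overall_mean == pytest.approx(0.2)

    def test_infeasible_mean_rejected(self):
        with pytest.raises(ValueError):
            LabelingModel.from_overall_mean(0.8, 0.5)  # mean < p_bind

    def test_zero_binding_gives_all_zero_counts(self):
        cells = sample_cells(500, LabelingModel(0.0, 0.0), seed=3)
        assert (cells.n_particles == 0).all()

    def test_sa_preset_bound_fraction(self):
        cells = sample_cells(10_000, MMP_SA, seed=11)
        frac = (cells.n_particles >= 1).mean()
        se = np.sqrt(0.823 * 0.177 / 10_000)
        assert abs(frac - 0.823) <= 3 * se

    def test_sa_preset_mean_count(self):
        cells = sample_cells(10_000, MMP_SA, seed=11)
        sem = cells.n_particles.std(ddof=1) / 100.0
        assert abs(cells.n_particles.mean() - 2.8) <= 3 * sem

    def test_igg_preset_bound_fraction(self):
        cells = sample_cells(10_000, MMP_IGG, seed=5)
        se = np.sqrt(0.127 * 0.873 / 10_000)
        assert abs((cells.n_particles >= 1).mean() - 0.127) <= 3 * se

    def test_count_distribution_chi_square(self):
        """Draws follow the zero-inflated shifted Poisson (GOF at alpha=0.01)."""
        cells = sample_cells(10_000, MMP_SA, seed=21)
        counts = cells.n_particles.to_numpy()
        kmax = 9
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        lam = MMP_SA.lambda_cond
        pk = np.zeros(kmax + 1)
        pk[0] = 1 - MMP_SA.p_bind
        for k in range(1, kmax):
            pk[k] = MMP_SA.p_bind * sps.poisson.pmf(k - 1, lam)
        pk[kmax] = 1.0 - pk.sum()
        res = sps.chisquare(obs, 10_000 * pk)
        assert res.pvalue > 0.01

    def test_moment_matching_recovery(self):
        cells = sample_cells(10_000, MMP_SA, seed=31)
        counts = cells.n_particles.to_numpy()
        p_hat = (counts >= 1).mean()
        lam_hat = counts.mean() / p_hat - 1.0
        assert abs(p_hat - MMP_SA.p_bind) <= 3 * np.sqrt(0.823 * 0.177 / 10_000)
        # conditional-mean SE via the bound subsample
        bound = counts[counts >= 1]
        se_lam = bound.std(ddof=1) / np.sqrt(len(bound))
        assert abs(lam_hat - MMP_SA.lambda_cond) <= 3 * se_lam

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            sample_cells(10, MMP_SA)


class TestPositions:
    def test_fraction_in_dilated_footprint_matches_null(self):
        p = geometry.build_bar_array()
        p0 = stats.uniform_null_fraction(p, 10.0)
        pos = sample_positions(100_000, (0.0, 350.0, 0.0, 250.0), seed=7)
        geom = geometry._buffered_geometry(p, 10.0, "disk")
        import shapely
        frac = shapely.contains_xy(geom, pos.x_um.to_numpy(), pos.y_um.to_numpy()).mean()
        se = np.sqrt(p0 * (1 - p0) / 100_000)
        assert abs(frac - p0) <= 3 * se

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            sample_positions(10, (5.0, 5.0, 0.0, 1.0), seed=1)

    def test_marginals_uniform(self):
        pos = sample_positions(5_000, (0.0, 350.0, 0.0, 250.0), seed=13)
        assert sps.kstest(pos.x_um / 350.0, "uniform").pvalue > 0.01
        assert sps.kstest(pos.y_um / 250.0, "uniform").pvalue > 0.01

    def test_full_region_containment(self):
        pos = sample_positions(100, (2.0, 4.0, -1.0, 1.0), seed=2)
        assert pos.x_um.between(2, 4).all() and pos.y_um.between(-1, 1).all()


class TestTracks:
    def test_noiseless_displacement_matches_speed(self):
        tracks, truth = synth_tracks(1, speed_um_s=10.0, duration_s=5.0,
                                     noise_sigma_um=0.0, seed=1)
        d = np.hypot(tracks.x_um.iloc[-1] - tracks.x_um.iloc[0],
                     tracks.y_um.iloc[-1] - tracks.y_um.iloc[0])
        assert d == pytest.approx(50.0)
        assert truth.speed_um_s.iloc[0] == 10.0

    def test_zero_speed_is_noise_around_start(self):
        tracks, _ = synth_tracks(3, speed_um_s=0.0, duration_s=10.0,
                                 noise_sigma_um=0.5, seed=4, starts=np.full((3, 2), 7.0))
        assert np.all(np.abs(tracks.x_um - 7.0) < 3.0)
        assert tracks.groupby("track_id").size().eq(11).all()

    def test_frame_interval_one_second(self):
        tracks, _ = synth_tracks(1, duration_s=5.0, seed=1)
        np.testing.assert_allclose(np.diff(tracks.t_s), 1.0)

    def test_speed_recovered_by_velocity_fit(self):
        hits = 0
        for seed in range(100):
            tracks, _ = synth_tracks(1, speed_um_s=10.0, duration_s=59.0,
                                     noise_sigma_um=0.5, seed=1000 + seed)
            fit = stats.estimate_velocity(tracks)
            if abs(fit.slope_um_s - 10.0) <= 3 * fit.stderr_um_s:
                hits += 1
        assert hits >= 95


class TestExperimentBundle:
    def test_byte_identical_reruns(self, tmp_path: Path):
        cfg = ExperimentConfig(seed=42, n_cells=50)
        generate_experiment(cfg, out_dir=tmp_path / "a")
        generate_experiment(cfg, out_dir=tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in files:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_provenance_embeds_config_hash_and_seed(self, tmp_path: Path):
        cfg = ExperimentConfig(seed=9, n_cells=20)
        generate_experiment(cfg, out_dir=tmp_path / "exp")
        prov = json.loads((tmp_path / "exp" / "provenance.json").read_text())
        assert prov["seed"] == 9
        assert prov["config_hash"] == cfg.hash

    def test_igg_bundle_labeled_fraction(self):
        bundle = generate_experiment(ExperimentConfig(seed=17, n_cells=10_000,
                                                      labeling="MMP-IgG"))
        frac = (bundle.cells.n_particles >= 1).mean()
        se = np.sqrt(0.127 * 0.873 / 10_000)
        assert abs(frac - 0.127) <= 3 * se

    def test_uniform_null_closure_end_to_end(self):
        """Unlabeled cells settled over the bar array land on the pattern at
        the uniform-null rate."""
        from magnetoguide.forces import pattern_force_map
        from magnetoguide.kinetics import settle_population

        bundle = generate_experiment(ExperimentConfig(seed=23, n_cells=2_000,
                                                      labeling="unlabeled"))
        fm = pattern_force_map(bundle.pattern, z_um=2.0, spacing_um=4.0, pad_um=10.0)
        endpoints = settle_population(bundle.cells, bundle.positions, fm.evaluator)
        rep = stats.occupancy(endpoints, bundle.pattern, [], touch_radius_um=10.0)
        p0 = rep.null_fraction_p0
        se = np.sqrt(p0 * (1 - p0) / 2_000)
        assert abs(rep.fraction_touching - p0) <= 3 * se
        res = stats.proportion_test(rep.n_touching_pattern, rep.n_cells, p0)
        assert res["p_value"] > 0.05
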