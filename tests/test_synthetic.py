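"""Generators: determinism, ground-truth structure, and statistical marginals."""

import numpy as np
import pandas as pd
import pytest

from dermaquant import synthetic
from dermaquant.axial import axial_difference


class TestSlides:
    def test_degenerate_mixture_all_angles_at_mu1(self):
        spec = synthetic.OrientationMixtureSpec(
            mu1=0.0, mu2=0.0, kappa=1e6, w=1.0, unimodal=True
        )
        rng = np.random.default_rng(0)
        theta = synthetic.sample_orientations(spec, 200, rng)
        assert np.all(axial_difference(theta, 0.0) < 0.5)

    def test_same_seed_bit_identical(self):
        spec = synthetic.OrientationMixtureSpec(mu1=45, mu2=135, kappa=8, w=0.6)
        a = synthetic.generate_slide(spec, n_bundles=40, seed=5)
        b = synthetic.generate_slide(spec, n_bundles=40, seed=5)
        assert np.array_equal(a.image, b.image)
        pd.testing.assert_frame_equal(a.truth_bundles, b.truth_bundles)
        assert np.array_equal(a.epidermis_polyline, b.epidermis_polyline)

    def test_balanced_mixture_nearest_peak_fraction(self):
        """Brute-force nearest-peak assignment on 2000 truth angles ≈ w."""
        spec = synthetic.OrientationMixtureSpec(mu1=45, mu2=135, kappa=8, w=0.5)
        rng = np.random.default_rng(123)
        theta = synthetic.sample_orientations(spec, 2000, rng)
        near_45 = axial_difference(theta, 45.0) < axial_difference(theta, 135.0)
        assert np.mean(near_45) == pytest.approx(0.5, abs=0.03)

    def test_truth_bundles_inside_dermis(self):
        spec = synthetic.OrientationMixtureSpec(mu1=45, mu2=135, kappa=8, w=0.6)
        slide = synthetic.generate_slide(spec, n_bundles=40, seed=5)
        cx = slide.truth_bundles["cx"].round().astype(int)
        cy = slide.truth_bundles["cy"].round().astype(int)
        assert slide.dermis_mask[cy, cx].all()
        assert slide.image.shape == slide.dermis_mask.shape

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            synthetic.OrientationMixtureSpec(mu1=45, mu2=135, kappa=0.0, w=0.5)
        spec = synthetic.OrientationMixtureSpec(mu1=45, mu2=135, kappa=8, w=0.5)
        with pytest.raises(ValueError):
            synthetic.generate_slide(spec, n_bundles=1, canvas=(60, 60), seed=0)


class TestCounts:
    @staticmethod
    def _metrics(n=12, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(2 * n)]
        metrics = pd.DataFrame(
            {"alignment": np.r_[rng.normal(0.6, 0.05, n), rng.normal(0.8, 0.05, n)]},
            index=samples,
        )
        groups = pd.Series(["a"] * n + ["b"] * n, index=samples)
        return metrics, groups

    def test_zero_slope_planted_indistinguishable_from_background(self):
        from dermaquant import signature

        metrics, groups = self._metrics()
        spec = synthetic.SignatureSpec(
            n_genes=400,
            planted_genes={f"p{i}": ("alignment", 0.0, 0.0) for i in range(100)},
        )
        m, _, _ = synthetic.generate_counts(spec, metrics, groups, seed=3)
        norm, _ = signature.normalize_counts(m)
        r2 = signature.correlate_to_metric(norm, metrics["alignment"])
        planted = r2.loc[[f"p{i}" for i in range(100)], "r2"]
        background = r2.loc[[g for g in m.genes if g.startswith("bg")], "r2"]
        # same null distribution of r²: medians agree within Monte-Carlo slack
        assert abs(planted.median() - background.median()) < 0.08

    def test_noiseless_high_count_limit_r2_near_one(self):
        from dermaquant import signature

        metrics, groups = self._metrics()
        spec = synthetic.SignatureSpec(
            n_genes=10,
            planted_genes={"p0": ("alignment", 2.0, 0.0)},
            baseline_mean=5e4,
            dispersion=1e-4,
            size_factor_spread=0.0,
        )
        m, _, _ = synthetic.generate_counts(spec, metrics, groups, seed=4)
        norm, _ = signature.normalize_counts(m)
        r2 = signature.correlate_to_metric(norm, metrics["alignment"])
        assert r2.loc["p0", "r2"] > 0.98

    def test_monte_carlo_median_r2_matches_target(self):
        """Planted-gene r² designed at 0.8 lands within ±0.1 over replicates."""
        from dermaquant import signature

        slope = synthetic.slope_for_target_r2(0.8, noise_sd=0.3)
        planted_ids = [f"p{i}" for i in range(50)]
        medians = []
        for rep in range(200):
            metrics, groups = self._metrics(seed=rep)
            # background genes anchor the size-factor estimate, as in any
            # realistic matrix where most genes are unrelated to the metric
            spec = synthetic.SignatureSpec(
                n_genes=500,
                planted_genes={g: ("alignment", slope, 0.3) for g in planted_ids},
            )
            m, _, _ = synthetic.generate_counts(spec, metrics, groups, seed=1000 + rep)
            norm, _ = signature.normalize_counts(m)
            r2 = signature.correlate_to_metric(norm, metrics["alignment"])
            medians.append(r2.loc[planted_ids, "r2"].median())
        assert np.median(medians) == pytest.approx(0.8, abs=0.1)

    def test_background_nb_marginals_match_dispersion(self):
        """Background mean/variance follow var = μ + αμ² at the set dispersion."""
        rng = np.random.default_rng(9)
        n = 100
        samples = [f"s{i}" for i in range(2 * n)]
        metrics = pd.DataFrame({"m": rng.normal(0, 1, 2 * n)}, index=samples)
        groups = pd.Series(["a"] * n + ["b"] * n, index=samples)
        spec = synthetic.SignatureSpec(
            n_genes=300,
            baseline_mean=200.0,
            dispersion=0.1,
            gene_spread_log2=0.0,
            size_factor_spread=0.0,
        )
        m, _, _ = synthetic.generate_counts(spec, metrics, groups, seed=9)
        counts = m.counts.to_numpy(dtype=float)
        mu = counts.mean(axis=1)
        excess = counts.var(axis=1, ddof=1) - mu
        alpha_hat = np.median(excess / mu**2)
        assert alpha_hat == pytest.approx(0.1, rel=0.2)

    def test_rejects_unknown_metric_and_empty_table(self):
        metrics, groups = self._metrics()
        bad = synthetic.SignatureSpec(
            n_genes=10, planted_genes={"p0": ("bogus", 1.0, 0.1)}
        )
        with pytest.raises(ValueError, match="bogus"):
            synthetic.generate_counts(bad, metrics, groups, seed=0)
        ok = synthetic.SignatureSpec(n_genes=10)
        with pytest.raises(ValueError):
            synthetic.generate_counts(ok, metrics.iloc[:0], groups, seed=0)


class TestTrajectories:
    def test_zero_speed_is_stationary(self):
        params = synthetic.TrajectoryParams(n_cells=5, speed_mean=0.0, duration=80.0)
        frames = synthetic.generate_trajectories(params, seed=0)
        for _, track in frames.groupby("cell_id"):
            assert track["x_px"].nunique() == 1
            assert track["y_px"].nunique() == 1

    def test_position_count_matches_duration(self):
        params = synthetic.TrajectoryParams(n_cells=3, dt=8.0, duration=240.0)
        frames = synthetic.generate_trajectories(params, seed=0)
        assert all(
            len(t) == 240 // 8 + 1 for _, t in frames.groupby("cell_id")
        )

    def test_ballistic_limit_directionality_near_one(self):
        from dermaquant import migration

        params = synthetic.TrajectoryParams(
            n_cells=50,
            persistence=0.999,
            substrate="aligned",
            alignment_bias=0.9,
            duration=272.0,
        )
        frames = synthetic.generate_trajectories(params, seed=1)
        stats = migration.compute_stats(frames)
        assert stats.per_group["mean_directionality"].iloc[0] > 0.95

    def test_aligned_substrate_increases_net_displacement(self):
        from dermaquant import migration

        common = dict(n_cells=500, duration=272.0, speed_mean=3.0)
        fa = synthetic.generate_trajectories(
            synthetic.TrajectoryParams(substrate="aligned", **common), seed=21
        )
        fr = synthetic.generate_trajectories(
            synthetic.TrajectoryParams(substrate="random", **common), seed=22
        )
        mean_aligned = migration.compute_stats(fa).per_group["mean_displacement"].iloc[0]
        mean_random = migration.compute_stats(fr).per_group["mean_displacement"].iloc[0]
        assert mean_aligned > mean_random

    def test_doubling_speed_doubles_accumulated_distance(self):
        from dermaquant import migration

        f1 = synthetic.generate_trajectories(
            synthetic.TrajectoryParams(n_cells=500, speed_mean=2.0, duration=272.0),
            seed=3,
        )
        f2 = synthetic.generate_trajectories(
            synthetic.TrajectoryParams(n_cells=500, speed_mean=4.0, duration=272.0),
            seed=4,
        )
        a1 = migration.compute_stats(f1).per_group["mean_accumulated"].iloc[0]
        a2 = migration.compute_stats(f2).per_group["mean_accumulated"].iloc[0]
        assert a2 / a1 == pytest.approx(2.0, rel=0.05)

    def test_rejects_persistence_out_of_range(self):
        with pytest.raises(ValueError):
            synthetic.TrajectoryParams(n_cells=1, persistence=1.0)

    def test_determinism(self):
        params = synthetic.TrajectoryParams(n_cells=10, duration=80.0)
        a = synthetic.generate_trajectories(params, seed=8)
        b = synthetic.generate_trajectories(params, seed=8)
        pd.testing.assert_frame_equal(a, b)
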