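import numpy as np
import pytest

from memdot.mesh import field_of_view
from memdot.simulate import (
    GridConfig,
    canonical_hrf,
    grow_generator,
    mix_at_snr,
    place_seeds,
    realize_trial,
    run_grid,
    simulate_hemodynamics,
    snr_eq,
    synth_resting_noise,
)
from memdot.preprocess import ChannelTimeSeries


class TestPlaceSeeds:
    def test_band_membership(self, phantom):
        cfg, mesh, _, sens = phantom
        fov = field_of_view(sens, cfg.fov_threshold)
        seeds = place_seeds(mesh, 1, 0, 0, rng_seed=0, fov_mask=fov)
        assert len(seeds) == 1
        v, band = seeds[0]
        assert band == "superficial" and mesh.vertex_depth[v] < 10

    def test_paper_scale_counts(self, phantom):
        cfg, mesh, _, sens = phantom
        fov = field_of_view(sens, cfg.fov_threshold)
        seeds = place_seeds(mesh, 100, 100, 50, rng_seed=1, fov_mask=fov)
        assert len(seeds) == 250
        bands = [b for _, b in seeds]
        assert bands.count("superficial") == 100
        assert bands.count("middle") == 100
        assert bands.count("deep") == 50

    def test_determinism(self, phantom):
        cfg, mesh, _, sens = phantom
        fov = field_of_view(sens, cfg.fov_threshold)
        s1 = place_seeds(mesh, 5, 5, 3, rng_seed=9, fov_mask=fov)
        s2 = place_seeds(mesh, 5, 5, 3, rng_seed=9, fov_mask=fov)
        assert s1 == s2

    def test_empty_band_reports_occupancy(self, small_mesh):
        only_deep = small_mesh.vertex_depth >= 99.0
        with pytest.raises(ValueError, match="occupancy"):
            place_seeds(small_mesh, 1, 0, 0, fov_mask=only_deep)


class TestGrowGenerator:
    def test_order_zero_is_seed_only(self, small_mesh):
        g = grow_generator(small_mesh, 17, 0)
        np.testing.assert_array_equal(g.vertex_set, [17])

    def test_matches_bfs_oracle(self, small_mesh):
        seed, Se = 44, 3
        g = grow_generator(small_mesh, seed, Se)
        # independent breadth-first enumeration
        seen = {seed}
        frontier = {seed}
        for _ in range(Se):
            frontier = {
                int(u) for v in frontier for u in small_mesh.neighbors[v]
            } - seen
            seen |= frontier
        assert set(g.vertex_set.tolist()) == seen

    def test_nestedness_and_area_growth(self, phantom):
        cfg, mesh, _, sens = phantom
        fov = field_of_view(sens, cfg.fov_threshold)
        seed = int(np.flatnonzero(fov)[100])
        gens = [grow_generator(mesh, seed, se, fov_mask=fov) for se in (3, 5, 7, 9)]
        for a, b in zip(gens, gens[1:]):
            assert set(a.vertex_set.tolist()) < set(b.vertex_set.tolist())
            assert a.area_cm2 < b.area_cm2


class TestHemodynamics:
    def test_causal_and_zero_outside_generator(self, small_mesh):
        g = grow_generator(small_mesh, 10, 2)
        times = np.arange(-60, 80, 0.25)
        hbo, hbr, tc, _ = simulate_hemodynamics(g, small_mesh.n_vertices, times)
        assert np.all(hbo[:, times < 0] == 0.0)
        outside = np.setdiff1d(np.arange(small_mesh.n_vertices), g.vertex_set)
        assert np.all(hbo[outside] == 0.0)
        assert tc.max() == pytest.approx(1.0)

    def test_hbr_ratio(self, small_mesh):
        g = grow_generator(small_mesh, 5, 1)
        times = np.arange(-10, 60, 0.25)
        _, _, hbo_tc, hbr_tc = simulate_hemodynamics(g, small_mesh.n_vertices, times)
        np.testing.assert_allclose(hbr_tc, -hbo_tc / 3.0)

    def test_peak_latency_matches_convolution_oracle(self):
        dt = 0.25
        times = np.arange(-60, 80, dt)
        boxcar = ((times >= 0) & (times < 20)).astype(float)
        h = canonical_hrf(np.arange(0, 32 + dt, dt))
        oracle = np.convolve(boxcar, h)[: len(times)]
        from memdot.simulate import GeneratorSpec

        g = GeneratorSpec(0, "superficial", 0, np.array([0]), 0.0)
        _, _, tc, _ = simulate_hemodynamics(g, 1, times)
        assert np.argmax(tc) == np.argmax(oracle)
        # peak sits after HRF peak (6 s) and before block end + HRF peak
        t_peak = times[np.argmax(tc)]
        assert 6.0 < t_peak < 26.0

    def test_empty_generator_zero_map(self):
        from memdot.simulate import GeneratorSpec

        g = GeneratorSpec(0, "superficial", 0, np.array([], dtype=int), 0.0)
        hbo, hbr, tc, _ = simulate_hemodynamics(g, 5, np.arange(-5, 10, 0.5))
        assert np.all(hbo == 0.0)


class TestRestingNoise:
    def test_spectral_peaks(self, dd_montage):
        noise = synth_resting_noise(dd_montage, duration=600, sampling_rate=4.0, rng_seed=0)
        from scipy.signal import welch

        f, p = welch(noise.values.mean(axis=0), fs=4.0, nperseg=1024)
        def band_power(lo, hi):
            return p[(f >= lo) & (f <= hi)].max()
        # local maxima near the physiological frequencies vs neighbors
        assert band_power(0.07, 0.13) > band_power(0.15, 0.25)
        assert band_power(0.25, 0.36) > band_power(0.4, 0.6)
        assert band_power(0.85, 1.15) > band_power(0.6, 0.8)

    def test_proximity_channels_carry_more_shared_signal(self, dd_montage):
        noise = synth_resting_noise(dd_montage, duration=600, sampling_rate=4.0, rng_seed=1)
        prox = dd_montage.proximity_channel_ids
        long_ids = np.setdiff1d(np.arange(noise.n_channels), prox)
        shared = noise.values.mean(axis=0)
        def mean_corr(ids):
            return np.mean([np.corrcoef(noise.values[i], shared)[0, 1] for i in ids])
        assert mean_corr(prox) > mean_corr(long_ids)

    def test_independent_seeds_uncorrelated(self, dd_montage):
        # the slow systemic drift leaves only ~1 effective sample per
        # record, so test independence on the differenced (fast) component
        # where thousands of effective samples make the bound sharp
        n1 = synth_resting_noise(dd_montage, 600, 4.0, rng_seed=2)
        n2 = synth_resting_noise(dd_montage, 600, 4.0, rng_seed=3)
        d1 = np.diff(n1.values, axis=1)
        d2 = np.diff(n2.values, axis=1)
        rs = [np.corrcoef(d1[c], d2[c])[0, 1] for c in range(n1.n_channels)]
        assert np.max(np.abs(rs)) < 0.1

    def test_minimum_duration(self, dd_montage):
        with pytest.raises(ValueError):
            synth_resting_noise(dd_montage, duration=60, sampling_rate=4.0)


class TestMixAtSnr:
    def _clean(self, fs=4.0):
        times = np.arange(-60, 80, 1 / fs)
        vals = np.zeros((3, len(times)))
        resp = (times >= 5) & (times < 25)
        vals[0, resp] = 2.0 * np.sin(np.linspace(0, np.pi, resp.sum()))
        return ChannelTimeSeries(values=vals, sampling_rate=fs, channel_ids=np.arange(3),
                                 t0=-60.0, baseline_window=(-60.0, 0.0))

    def _noise(self, montage, n_epochs, nt, fs=4.0, seed=0):
        return synth_resting_noise(montage, duration=n_epochs * nt / fs + 1, sampling_rate=fs,
                                   rng_seed=seed)

    def test_snr_round_trip_exact(self, dd_montage):
        clean = self._clean()
        mont3 = None
        noise = synth_resting_noise(dd_montage, 10 * 140 + 5, 4.0, rng_seed=4)
        noise = noise.copy_with(values=noise.values[:3])
        for target in (5.0, 2.0, 1.0):
            noisy, _, scale, achieved = mix_at_snr(clean, noise, target)
            assert achieved == pytest.approx(target, rel=0.02)

    def test_scale_linear_in_inverse_target(self, dd_montage):
        clean = self._clean()
        noise = synth_resting_noise(dd_montage, 10 * 140 + 5, 4.0, rng_seed=5)
        noise = noise.copy_with(values=noise.values[:3])
        _, _, s1, _ = mix_at_snr(clean, noise, 1.0)
        _, _, s5, _ = mix_at_snr(clean, noise, 5.0)
        assert s1 / s5 == pytest.approx(5.0, rel=1e-9)

    def test_hand_snr_equation(self):
        # clean max-abs 2.0 in the response window, noise baseline std 0.4
        times = np.arange(-10, 70, 0.5)
        clean = np.zeros((2, len(times)))
        clean[0, (times >= 0) & (times < 30)] = 2.0
        noisy = clean.copy()
        rng = np.random.default_rng(0)
        base = times < 0
        noisy[:, base] += 0.4 * rng.standard_normal((2, base.sum()))
        # normalize realized std to exactly 0.4 per channel
        noisy[:, base] *= 0.4 / noisy[:, base].std(axis=1, ddof=0, keepdims=True)
        assert snr_eq(clean, noisy, times) == pytest.approx(5.0)

    def test_zero_clean_signal_rejected(self, dd_montage):
        times = np.arange(-60, 80, 0.25)
        clean = ChannelTimeSeries(values=np.zeros((3, len(times))), sampling_rate=4.0,
                                  channel_ids=np.arange(3), t0=-60.0)
        noise = synth_resting_noise(dd_montage, 10 * 140 + 5, 4.0, rng_seed=6)
        with pytest.raises(ValueError):
            mix_at_snr(clean, noise.copy_with(values=noise.values[:3]), 5.0)


class TestRunGrid:
    def test_paper_scale_inventory(self, phantom):
        cfg, mesh, _, sens = phantom
        grid = GridConfig()  # 100/100/50 seeds x 4 extents x 4 SNRs
        manifest = run_grid(mesh, sens, grid, fov_threshold=cfg.fov_threshold)
        assert len(manifest) == 4000
        assert len({e["trial"] for e in manifest}) == 4000

    def test_small_inventory(self, phantom):
        cfg, mesh, _, sens = phantom
        grid = GridConfig(n_superficial=2, n_middle=0, n_deep=0, extents=(5,), snrs=(5.0,))
        manifest = run_grid(mesh, sens, grid, fov_threshold=cfg.fov_threshold)
        assert len(manifest) == 2

    def test_master_seed_reproducibility(self, phantom):
        cfg, mesh, _, sens = phantom
        grid = GridConfig(n_superficial=3, n_middle=2, n_deep=1, master_seed=11)
        m1 = run_grid(mesh, sens, grid, fov_threshold=cfg.fov_threshold)
        m2 = run_grid(mesh, sens, grid, fov_threshold=cfg.fov_threshold)
        assert m1 == m2


class TestRealizeTrial:
    def test_forward_consistency_and_snr(self, phantom):
        cfg, mesh, montage, sens = phantom
        grid = GridConfig(n_superficial=1, n_middle=0, n_deep=0, extents=(5,), snrs=(5.0,))
        manifest = run_grid(mesh, sens, grid, fov_threshold=cfg.fov_threshold)
        trial = realize_trial(mesh, sens, montage, manifest[0], grid,
                              fov_threshold=cfg.fov_threshold)
        # clean OD is exactly A times the simulated absorption map
        for wl in sens.wavelengths:
            np.testing.assert_allclose(
                trial.clean_od[wl].values,
                sens.matrices[wl] @ trial.truth_maps[wl],
                rtol=1e-12,
            )
            assert trial.achieved_snr[wl] == pytest.approx(5.0, rel=0.02)
        g = trial.generator
        assert g.seed_vertex in set(g.vertex_set.tolist())
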