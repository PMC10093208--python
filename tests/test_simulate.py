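"""Generator contracts: determinism, photometry, bookkeeping, conservation."""

import numpy as np
import pytest
from skimage.measure import label, regionprops

from astromito.simulate import (
    AcquisitionConfig,
    FieldParams,
    LognormalComponent,
    MitoEvent,
    simulate_field,
    simulate_particle_sample,
    simulate_timepoint_series,
)

CLEAN = dict(shot_noise=False, read_noise=0.0, background=0.0, diffusion=0.0)


class TestSimulateField:
    def test_static_noise_free_frames_identical(self):
        cfg = AcquisitionConfig(n_frames=2, image_shape=(128, 128))
        p = FieldParams(n_mitochondria=1, **CLEAN)
        stack, gt = simulate_field(cfg, p, seed=0)
        assert np.array_equal(stack.green[0], stack.green[1])
        assert np.array_equal(stack.red[0], stack.red[1])
        for frame in (stack.green[0], stack.red[0]):
            assert label(frame > 1e-6).max() == 1

    def test_identical_seed_bit_identical_output(self, small_config):
        p = FieldParams(n_mitochondria=15, event_rate=0.002)
        a, gta = simulate_field(small_config, p, seed=11)
        b, gtb = simulate_field(small_config, p, seed=11)
        assert np.array_equal(a.green, b.green)
        assert np.array_equal(a.red, b.red)
        assert gta.events == gtb.events
        assert np.array_equal(gta.live_counts, gtb.live_counts)
        c, _ = simulate_field(small_config, p, seed=12)
        assert not np.array_equal(a.green, c.green)

    def test_degenerate_ratio_reproduced_per_object(self, small_config):
        # PSF off so object masks at a tiny threshold stay disjoint
        p = FieldParams(
            n_mitochondria=8, redox_ratio=(2.0, 0.0), psf_sigma_px=0.0, **CLEAN
        )
        stack, _ = simulate_field(small_config, p, seed=3)
        lab = label(stack.green[0] > 1e-6)
        assert lab.max() == 8
        for pr in regionprops(lab):
            m = lab == pr.label
            r = stack.red[0][m].mean() / stack.green[0][m].mean()
            assert r == pytest.approx(2.0, abs=1e-6)

    def test_photometric_ratio_matches_generating_ratio(self, small_config):
        # noise off: per-object measured red/green equals the drawn ratio
        p = FieldParams(
            n_mitochondria=6, redox_ratio=(1.3, 0.2), psf_sigma_px=0.0, **CLEAN
        )
        stack, gt = simulate_field(small_config, p, seed=9)
        lab = label(stack.green[0] > 1e-6)
        true_ratios = sorted(m.redox_ratio for m in gt.mitochondria)
        got = sorted(
            stack.red[0][lab == i].mean() / stack.green[0][lab == i].mean()
            for i in range(1, lab.max() + 1)
        )
        assert np.allclose(got, true_ratios, atol=1e-6)

    def test_count_bookkeeping_follows_schedule(self, small_config):
        sched = (
            MitoEvent(1, "fusion", (0, 1)),
            MitoEvent(3, "fission", (2,)),
            MitoEvent(5, "fission", (3,)),
        )
        cfg = AcquisitionConfig(n_frames=8, image_shape=(256, 256))
        p = FieldParams(n_mitochondria=6, event_schedule=sched, **CLEAN)
        _, gt = simulate_field(cfg, p, seed=4)
        expected = [6, 5, 5, 6, 6, 7, 7, 7]
        assert gt.live_counts.tolist() == expected

    def test_fusion_conserves_integrated_intensity(self):
        # without the PSF the image total is an exact photon-budget ledger
        cfg = AcquisitionConfig(n_frames=3, image_shape=(256, 256))
        p = FieldParams(
            n_mitochondria=4,
            event_schedule=(MitoEvent(1, "fusion", (0, 1)),),
            psf_sigma_px=0.0,
            **CLEAN,
        )
        stack, _ = simulate_field(cfg, p, seed=6)
        # conservation is exact analytically; rasterized sums carry a small
        # sub-pixel antialiasing jitter when the merged partner is translated
        before, after = stack.green[0].sum(), stack.green[1].sum()
        assert after == pytest.approx(before, rel=1e-3)
        assert stack.red[1].sum() == pytest.approx(stack.red[0].sum(), rel=1e-3)

    def test_fused_object_is_single_component(self):
        cfg = AcquisitionConfig(n_frames=3, image_shape=(256, 256))
        p = FieldParams(
            n_mitochondria=2,
            event_schedule=(MitoEvent(1, "fusion", (0, 1)),),
            **CLEAN,
        )
        stack, _ = simulate_field(cfg, p, seed=6)
        assert label(stack.green[0] > 1e-6).max() == 2
        assert label(stack.green[1] > 1e-6).max() == 1

    def test_stochastic_event_counts_match_poisson_mean(self):
        # empirical mean event count over many fields vs lambda * (T-1) * N
        lam, n0, T = 0.004, 20, 12
        cfg = AcquisitionConfig(n_frames=T, image_shape=(384, 384))
        p = FieldParams(n_mitochondria=n0, event_rate=lam, **CLEAN)
        counts, nbars = [], []
        for seed in range(100):
            _, gt = simulate_field(cfg, p, seed=seed)
            counts.append(len(gt.events))
            nbars.append(gt.live_counts.mean())
        mean_expected = lam * (T - 1) * np.mean(nbars)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - mean_expected) <= 3 * se + 1e-12

    def test_rejects_excessive_density(self):
        cfg = AcquisitionConfig(n_frames=2, image_shape=(64, 64))
        p = FieldParams(n_mitochondria=120, **CLEAN)
        with pytest.raises(ValueError, match="density"):
            simulate_field(cfg, p, seed=0)

    def test_rejects_unknown_event_participant(self, small_config):
        p = FieldParams(
            n_mitochondria=3,
            event_schedule=(MitoEvent(1, "fission", (99,)),),
            **CLEAN,
        )
        with pytest.raises(ValueError, match="unknown"):
            simulate_field(small_config, p, seed=0)

    def test_rejects_event_frame_out_of_range(self, small_config):
        p = FieldParams(
            n_mitochondria=3,
            event_schedule=(MitoEvent(0, "fission", (0,)),),
            **CLEAN,
        )
        with pytest.raises(ValueError, match="frame"):
            simulate_field(small_config, p, seed=0)

    def test_quantization_and_range(self, small_config):
        p = FieldParams(n_mitochondria=5)
        stack, _ = simulate_field(small_config, p, seed=1)
        assert stack.green.min() >= 0
        assert stack.green.max() <= small_config.max_dn
        assert np.array_equal(stack.green, np.rint(stack.green))


class TestTimepointSeries:
    def test_identity_shift_gives_zero_true_change(self, small_config):
        p = FieldParams(n_mitochondria=10, **CLEAN)
        series = simulate_timepoint_series(
            small_config, p, {"redox_ratio": {"6h": 1.0, "24h": 1.0}}, seed=5
        )
        assert [s.timepoint for s, _ in series] == ["BL", "6h", "24h"]
        meds = [gt.params.redox_ratio[0] for _, gt in series]
        assert meds == [1.0, 1.0, 1.0]

    def test_shift_moves_parameter_median_by_log_shift(self, small_config):
        p = FieldParams(n_mitochondria=10, **CLEAN)
        series = simulate_timepoint_series(
            small_config, p, {"redox_ratio": {"24h": 1.5}}, seed=5
        )
        by_tp = {s.timepoint: gt for s, gt in series}
        assert np.log(by_tp["24h"].params.redox_ratio[0]) - np.log(
            by_tp["BL"].params.redox_ratio[0]
        ) == pytest.approx(np.log(1.5))

    def test_population_mean_ratio_shifts_multiplicatively(self):
        cfg = AcquisitionConfig(n_frames=2)
        p = FieldParams(n_mitochondria=60, **CLEAN)
        series = simulate_timepoint_series(
            cfg, p, {"redox_ratio": {"24h": 1.5}}, seed=8,
            timepoints=("BL", "24h"),
        )
        by_tp = {s.timepoint: gt for s, gt in series}
        r_bl = by_tp["BL"].true_cell_means()["redox_ratio"]
        r_24 = by_tp["24h"].true_cell_means()["redox_ratio"]
        assert np.log(r_24 / r_bl) == pytest.approx(np.log(1.5), abs=0.08)

    def test_rejects_non_positive_shift(self, small_config):
        p = FieldParams(n_mitochondria=5, **CLEAN)
        with pytest.raises(ValueError):
            simulate_timepoint_series(
                small_config, p, {"length": {"24h": 0.0}}, seed=1
            )


class TestParticleSample:
    def test_degenerate_component_returns_mode(self):
        s = simulate_particle_sample(
            200, [LognormalComponent(100.0, 0.0, 1.0)], seed=0
        )
        assert np.allclose(s.diameters, 100.0)

    def test_balanced_mixture_splits_at_150(self):
        mix = [
            LognormalComponent(80.0, 0.10, 0.5),
            LognormalComponent(300.0, 0.10, 0.5),
        ]
        s = simulate_particle_sample(4000, mix, seed=1)
        frac_large = (s.diameters > 150).mean()
        # binomial 99.7% band around 0.5 at n = 4000
        assert abs(frac_large - 0.5) <= 3 * np.sqrt(0.25 / 4000)

    def test_non_positive_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_particle_sample(0, [LognormalComponent(100, 0.1, 1.0)], seed=0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simulate_particle_sample(
                10,
                [LognormalComponent(100, 0.1, 0.4), LognormalComponent(300, 0.1, 0.4)],
                seed=0,
            )

    def test_seeded_determinism(self):
        mix = [LognormalComponent(120.0, 0.3, 1.0)]
        a = simulate_particle_sample(50, mix, seed=7)
        b = simulate_particle_sample(50, mix, seed=7)
        assert np.array_equal(a.diameters, b.diameters)


def test_acquisition_config_validation():
    with pytest.raises(ValueError):
        AcquisitionConfig(n_frames=1)
    with pytest.raises(ValueError):
        AcquisitionConfig(pixel_size=0.0)
    with pytest.raises(ValueError):
        AcquisitionConfig(image_shape=(32, 128))
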