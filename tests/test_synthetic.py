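"""Generator behaviour: determinism, point-process statistics, rendering."""

import numpy as np
import pytest

from isletex import (
    FuraCalibration,
    SceneParams,
    classify_exocytosis,
    concentration_to_ratio,
    generate_calcium_trace,
    generate_cell_mask,
    generate_gtt_curve,
    generate_scene,
    ratio_to_concentration,
    sample_ground_truth,
)


class TestSceneGeneration:
    def test_zero_rates_give_background_only(self):
        params = SceneParams(field_width_um=20, field_height_um=20,
                             n_frames=10, primary_rate=0, cluster_rate=0,
                             noise_sd=0, seed=0)
        scene, truth = generate_scene(params)
        assert truth.events == []
        assert np.allclose(scene.frames, params.cell_interior_level)

    def test_same_seed_bit_identical(self):
        params = SceneParams(field_width_um=25, field_height_um=25,
                             n_frames=30, seed=11, cluster_rate=0.003)
        s1, t1 = generate_scene(params)
        s2, t2 = generate_scene(params)
        assert np.array_equal(s1.frames, s2.frames)
        assert [(e.x_um, e.y_um, e.t_s) for e in t1.events] == \
               [(e.x_um, e.y_um, e.t_s) for e in t2.events]

    def test_noise_stream_does_not_move_events(self):
        base = dict(field_width_um=25, field_height_um=25, n_frames=30, seed=3)
        _, t_lo = generate_scene(SceneParams(noise_sd=0.5, **base))
        _, t_hi = generate_scene(SceneParams(noise_sd=5.0, **base))
        assert [(e.x_um, e.y_um, e.t_s) for e in t_lo.events] == \
               [(e.x_um, e.y_um, e.t_s) for e in t_hi.events]

    def test_poisson_mean_primary_count(self):
        # lam = rate * area = 0.02 * 2500 = 50; sample mean over 200 seeds
        # must fall within 3 standard errors of 50
        rate, area_side, n_seeds = 0.02, 50.0, 200
        counts = []
        for seed in range(n_seeds):
            params = SceneParams(field_width_um=area_side,
                                 field_height_um=area_side,
                                 primary_rate=rate, cluster_rate=0, seed=seed)
            counts.append(len(sample_ground_truth(params).events))
        lam = rate * area_side ** 2
        se = np.sqrt(lam / n_seeds)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_compound_fraction_monotone_in_cluster_rate(self):
        rates = [0.0005, 0.002, 0.008]
        means = []
        for rate in rates:
            fracs = [sample_ground_truth(
                SceneParams(primary_rate=0.01, cluster_rate=rate,
                            seed=s)).true_compound_fraction
                for s in range(60)]
            means.append(np.mean(fracs))
        assert means[0] < means[1] < means[2]

    def test_compound_sites_have_at_least_two_events(self):
        truth = sample_ground_truth(SceneParams(
            cluster_rate=0.004, cluster_size_dist={2: 0.5, 5: 0.5}, seed=5))
        sites = {}
        for e in truth.events:
            if e.site_kind == "compound":
                sites.setdefault(e.site_id, []).append(e)
        assert sites and all(len(v) >= 2 for v in sites.values())

    def test_events_inside_field_and_recording(self):
        params = SceneParams(cluster_rate=0.003, seed=9)
        truth = sample_ground_truth(params)
        for e in truth.events:
            assert 0 <= e.x_um <= params.field_width_um
            assert 0 <= e.y_um <= params.field_height_um
            assert 0 <= e.t_s < params.duration_s
            assert 0 <= e.frame_index < params.n_frames

    def test_rendered_event_raises_centre_intensity(self):
        # noise-free: each event adds >= 0.5 * amplitude at its centre pixel
        # between the frames straddling its time
        params = SceneParams(field_width_um=30, field_height_um=30,
                             n_frames=60, noise_sd=0, primary_rate=0.01,
                             cluster_rate=0.001, seed=21)
        scene, truth = generate_scene(params)
        px = params.pixel_size_um
        for e in truth.events:
            i = int(round(e.y_um / px))
            j = int(round(e.x_um / px))
            i, j = min(i, scene.shape[0] - 1), min(j, scene.shape[1] - 1)
            before = scene.frames[e.frame_index - 1, i, j] if e.frame_index else 0
            after = scene.frames[e.frame_index, i, j]
            assert after - before >= 0.5 * params.event_amplitude

    def test_clustered_scene_classified_mostly_compound(self):
        # fixed 8-granule clusters at 0.2 um jitter: every cluster window
        # holds >= 8 >= 7 events, so the classifier must call > 50% compound
        params = SceneParams(primary_rate=0.002, cluster_rate=0.004,
                             cluster_size_dist=8, cluster_sd_um=0.2, seed=2)
        truth = sample_ground_truth(params)
        cls = classify_exocytosis(truth.events)
        assert cls.fraction_compound > 0.5

    def test_cell_mask_voronoi_and_event_placement(self):
        params = SceneParams(with_cell_mask=True, seed=4, cluster_rate=0.001)
        scene, truth = generate_scene(params)
        assert scene.cell_mask is not None
        assert scene.cell_mask.shape == scene.shape
        assert scene.cell_mask.max() >= 1
        px = params.pixel_size_um
        for e in truth.events:
            i = min(int(round(e.y_um / px)), scene.shape[0] - 1)
            j = min(int(round(e.x_um / px)), scene.shape[1] - 1)
            assert scene.cell_mask[i, j] > 0

    @pytest.mark.parametrize("bad", [
        dict(field_width_um=0),
        dict(n_frames=0),
        dict(pixel_size_um=-1),
        dict(cell_interior_level=200.0),
        dict(cluster_size_dist=1),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            SceneParams(**bad).validate()


class TestGTTGenerator:
    def test_flat_fasting_curve_auc(self):
        # constant 6.3 mmol/l over 120 min -> AUC 756
        curve = generate_gtt_curve(6.3, 6.3, peak_time_min=0, duration_min=120,
                                   decay_rate=0.0)
        from isletex import compute_auc
        assert compute_auc(curve) == pytest.approx(6.3 * 120)

    def test_rise_and_decay_shape(self):
        curve = generate_gtt_curve(6.0, 20.0, peak_time_min=30,
                                   duration_min=120, decay_rate=0.03)
        peak_idx = np.argmax(curve.glucose_mmol_l)
        assert curve.times_min[peak_idx] == 30
        assert np.all(np.diff(curve.glucose_mmol_l[:peak_idx + 1]) >= 0)
        assert np.all(np.diff(curve.glucose_mmol_l[peak_idx:]) <= 0)
        assert curve.glucose_mmol_l[-1] > 6.0  # decays toward, not below, fasting

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_gtt_curve(6.0, 20.0, duration_min=0)
        with pytest.raises(ValueError):
            generate_gtt_curve(6.0, 20.0, decay_rate=-0.1)
        with pytest.raises(ValueError):
            generate_gtt_curve(9.0, 6.0)

    def test_seeded_noise_reproducible(self):
        kw = dict(peak_time_min=30, duration_min=120, decay_rate=0.02,
                  noise_sd=0.5, seed=42)
        c1 = generate_gtt_curve(6.0, 18.0, **kw)
        c2 = generate_gtt_curve(6.0, 18.0, **kw)
        assert np.array_equal(c1.glucose_mmol_l, c2.glucose_mmol_l)


class TestCalciumGenerator:
    def test_flat_trace_when_baseline_equals_peak(self, default_cal):
        trace = generate_calcium_trace(50.0, 50.0, 300.0, default_cal)
        assert np.allclose(trace.ratio, trace.ratio[0])

    def test_round_trip_identity_at_zero_noise(self, default_cal):
        trace = generate_calcium_trace(35.5, 300.0, 200.0, default_cal)
        conc = ratio_to_concentration(trace.ratio, default_cal)
        assert conc[0] == pytest.approx(35.5, rel=1e-9)
        assert conc.max() == pytest.approx(300.0, rel=1e-3)

    def test_conversion_inverts_forward_model(self, default_cal):
        c = np.array([0.0, 35.5, 64.0, 224.0, 1000.0])
        assert np.allclose(
            ratio_to_concentration(concentration_to_ratio(c, default_cal),
                                   default_cal), c)

    def test_out_of_range_peak_rejected(self, default_cal):
        with pytest.raises(ValueError):
            generate_calcium_trace(35.5, -1.0, 200.0, default_cal)

    def test_stimulus_outside_recording_rejected(self, default_cal):
        with pytest.raises(ValueError):
            generate_calcium_trace(35.5, 100.0, 700.0, default_cal,
                                   duration_s=600.0)
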