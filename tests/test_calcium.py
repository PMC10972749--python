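"""ROI extraction, ratiometric ΔF/F₀, responsiveness and selectivity."""

import numpy as np
import pytest

from reflexkit import (
    CalciumSimParams,
    RoiMask,
    RoiTraceSet,
    StimulusEpoch,
    analyze_session,
    classify_selectivity,
    exclude_unhealthy,
    extract_roi_traces,
    gen_calcium_session,
    ratiometric_dff,
    score_responsiveness,
    tally_responses,
)

EPOCHS = (
    StimulusEpoch("compression", 60.0, 70.0, 100.0),
    StimulusEpoch("inflation", 160.0, 170.0, 200.0),
)


def flat_session(n_rois=1, n_frames=480, fs=2.0, gcamp=100.0, tdtomato=100.0):
    return RoiTraceSet(
        gcamp=np.full((n_rois, n_frames), gcamp),
        tdtomato=np.full((n_rois, n_frames), tdtomato),
        sampling_rate_hz=fs,
    )


class TestRoiExtraction:
    def test_uniform_frames_give_constant_traces(self):
        stack = {
            "gcamp": np.full((5, 4, 4), 7.0),
            "tdtomato": np.full((5, 4, 4), 3.0),
        }
        masks = [RoiMask(1, ((0, 0), (1, 1)))]
        out = extract_roi_traces(stack, masks, sampling_rate_hz=2.0)
        assert np.allclose(out.gcamp, 7.0) and np.allclose(out.tdtomato, 3.0)

    def test_disjoint_rois_separate_constant_values(self):
        g = np.zeros((3, 2, 2))
        g[:, 0, 0] = 10.0
        g[:, 1, 1] = 20.0
        stack = {"gcamp": g, "tdtomato": np.ones_like(g)}
        masks = [RoiMask(1, ((0, 0),)), RoiMask(2, ((1, 1),))]
        out = extract_roi_traces(stack, masks, sampling_rate_hz=1.0)
        assert np.allclose(out.gcamp[0], 10.0) and np.allclose(out.gcamp[1], 20.0)

    def test_means_match_bruteforce_pixel_average(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(1, 100, size=(6, 8, 9))
        r = rng.uniform(1, 100, size=(6, 8, 9))
        pixels = tuple((int(a), int(b)) for a, b in
                       {(int(i), int(j)) for i, j in rng.integers(0, 8, size=(10, 2))})
        out = extract_roi_traces(
            {"gcamp": g, "tdtomato": r}, [RoiMask(5, pixels)], sampling_rate_hz=1.0
        )
        brute = np.array([
            np.mean([g[f, i, j] for i, j in pixels]) for f in range(6)
        ])
        np.testing.assert_allclose(out.gcamp[0], brute)

    def test_label_image_masks(self):
        labels = np.array([[1, 1], [0, 2]])
        g = np.zeros((2, 2, 2))
        g[:, 0, :] = 4.0
        g[:, 1, 1] = 9.0
        out = extract_roi_traces(
            {"gcamp": g, "tdtomato": np.ones_like(g)}, labels, sampling_rate_hz=1.0
        )
        assert out.roi_ids == [1, 2]
        assert np.allclose(out.gcamp[0], 4.0) and np.allclose(out.gcamp[1], 9.0)

    def test_out_of_bounds_pixel_names_roi(self):
        stack = {"gcamp": np.ones((2, 2, 2)), "tdtomato": np.ones((2, 2, 2))}
        with pytest.raises(ValueError, match="ROI 9"):
            extract_roi_traces(stack, [RoiMask(9, ((5, 0),))], sampling_rate_hz=1.0)

    def test_overlapping_rois_rejected(self):
        stack = {"gcamp": np.ones((2, 2, 2)), "tdtomato": np.ones((2, 2, 2))}
        masks = [RoiMask(1, ((0, 0),)), RoiMask(2, ((0, 0),))]
        with pytest.raises(ValueError, match="overlap"):
            extract_roi_traces(stack, masks, sampling_rate_hz=1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            RoiMask(3, ())


class TestUnhealthyExclusion:
    def test_constant_high_gcamp_is_flagged(self):
        traces = flat_session(n_rois=10)
        traces.gcamp[3] = 1000.0  # constant, far above the cohort
        rng = np.random.default_rng(1)
        for i in range(10):
            if i != 3:
                traces.gcamp[i] = 100.0 + rng.normal(0, 5.0, traces.n_frames)
        flags = exclude_unhealthy(traces)
        assert flags[3] is True
        assert sum(flags.values()) == 1

    def test_normal_variability_not_flagged(self):
        rng = np.random.default_rng(2)
        traces = flat_session(n_rois=5)
        traces.gcamp[:] = 100.0 + rng.normal(0, 5.0, traces.gcamp.shape)
        assert not any(exclude_unhealthy(traces).values())

    def test_synthetic_unhealthy_set_recovered(self):
        p = CalciumSimParams(n_rois=50, unhealthy_rois=[7, 31], seed=3)
        traces, truth = gen_calcium_session(p)
        flags = exclude_unhealthy(traces)
        assert sorted(r for r, f in flags.items() if f) == truth.unhealthy_rois


class TestRatiometricDff:
    def test_equal_channels_give_zero_dff(self):
        traces = flat_session()
        (p,) = ratiometric_dff(traces, EPOCHS)
        assert np.allclose(p.dff, 0.0)

    def test_shared_bleach_envelope_cancels(self):
        p = CalciumSimParams(n_rois=3, noise_sd=0.0, bleach_tau_s=100.0)
        traces, _ = gen_calcium_session(p)
        profiles = ratiometric_dff(traces, list(p.epochs))
        for prof in profiles:
            assert np.max(np.abs(prof.dff)) < 1e-10

    def test_common_channel_scaling_is_invariant(self):
        p = CalciumSimParams(n_rois=2, responder_map={0: ["compression"]}, noise_sd=0.0)
        traces, _ = gen_calcium_session(p)
        scaled = RoiTraceSet(
            gcamp=traces.gcamp * 4.2,
            tdtomato=traces.tdtomato * 4.2,
            sampling_rate_hz=traces.sampling_rate_hz,
        )
        a = ratiometric_dff(traces, list(p.epochs))
        b = ratiometric_dff(scaled, list(p.epochs))
        np.testing.assert_allclose(a[0].dff, b[0].dff, atol=1e-12)

    def test_step_from_100_to_150_peaks_at_half(self):
        traces = flat_session()
        i0 = traces.index_at(60.0)
        traces.gcamp[0, i0 : i0 + 10] = 150.0
        (p,) = ratiometric_dff(traces, EPOCHS)
        assert p.dff.max() == pytest.approx(0.5)

    def test_insufficient_baseline_errors(self):
        traces = flat_session(n_frames=100)
        with pytest.raises(ValueError, match="baseline"):
            ratiometric_dff(traces, [StimulusEpoch("compression", 5.0, 10.0, 10.0)])

    def test_nonpositive_tdtomato_errors(self):
        traces = flat_session()
        traces.tdtomato[0, 5] = 0.0
        with pytest.raises(ValueError, match="tdTomato"):
            ratiometric_dff(traces, EPOCHS)


class TestResponsiveness:
    def session_with_peak(self, peak_dff, seed=0, noise=0.02):
        rng = np.random.default_rng(seed)
        traces = flat_session()
        traces.gcamp[0] += rng.normal(0, noise * 100.0, traces.n_frames)
        i0 = traces.index_at(62.0)
        traces.gcamp[0, i0 : i0 + 6] += peak_dff * 100.0
        return traces

    def test_suprathreshold_in_epoch_peak_is_responsive(self):
        traces = self.session_with_peak(1.0)
        profiles = ratiometric_dff(traces, EPOCHS)
        profiles = score_responsiveness(profiles, traces, EPOCHS)
        assert profiles[0].responsive["compression"] is True
        assert profiles[0].response_magnitude["compression"] == pytest.approx(1.0, rel=0.1)

    def test_subthreshold_peak_is_not_responsive(self):
        traces = self.session_with_peak(0.0, noise=0.02)
        profiles = score_responsiveness(
            ratiometric_dff(traces, EPOCHS), traces, EPOCHS
        )
        # peak is ~2 s.d. noise excursion at most 3 s.d. is required
        mag = profiles[0].response_magnitude["compression"]
        thr = profiles[0].session_mean + 3 * profiles[0].session_sd
        assert profiles[0].responsive["compression"] == (mag > 0 and mag >= thr)

    def test_monotone_in_peak_height(self):
        lo = self.session_with_peak(0.5, seed=1)
        hi = self.session_with_peak(2.0, seed=1)
        get = lambda tr: score_responsiveness(
            ratiometric_dff(tr, EPOCHS), tr, EPOCHS
        )[0].responsive["compression"]
        assert not (get(lo) and not get(hi))

    def test_epoch_outside_session_errors(self):
        traces = flat_session(n_frames=100)  # 50 s at 2 Hz
        profiles = ratiometric_dff(
            traces, [StimulusEpoch("compression", 25.0, 30.0, 30.0)]
        )
        with pytest.raises(ValueError, match="outside"):
            score_responsiveness(
                profiles, traces, [StimulusEpoch("inflation", 80.0, 90.0, 90.0)]
            )

    def test_synthetic_responders_recovered_exactly_at_zero_noise(self, calcium_session):
        params, traces, truth = calcium_session
        profiles = analyze_session(traces, list(params.epochs))
        for label in ("compression", "inflation"):
            called = sorted(
                p.roi_id for p in profiles if p.responsive.get(label)
            )
            assert called == truth.responders[label]


class TestSelectivity:
    def profile_with(self, rc, ri):
        traces = flat_session()
        profiles = score_responsiveness(
            ratiometric_dff(traces, EPOCHS), traces, EPOCHS
        )
        p = profiles[0]
        p.response_magnitude = {"compression": rc, "inflation": ri}
        p.responsive = {"compression": rc > 0, "inflation": ri > 0}
        p.session_sd = 0.01
        return p

    @pytest.mark.parametrize(
        "rc,ri,expected",
        [
            (3.0, 1.0, "compression_selective"),  # Rc/Ri = 3 > 2
            (1.0, 1.0, "polymodal"),  # interior point
            (0.4, 1.0, "inflation_selective"),  # Rc/Ri = 0.4 < 0.5
            (2.0, 1.0, "polymodal"),  # boundary Rc/Ri = 2
            (0.5, 1.0, "polymodal"),  # boundary Rc/Ri = 0.5
        ],
    )
    def test_rc_ri_thresholds(self, rc, ri, expected):
        assert classify_selectivity(self.profile_with(rc, ri)) == expected

    def test_scale_invariance_of_rc_ri(self):
        a = classify_selectivity(self.profile_with(3.0, 1.0))
        b = classify_selectivity(self.profile_with(0.3, 0.1))
        assert a == b == "compression_selective"

    def test_nonresponsive_cell_left_unclassified(self):
        p = self.profile_with(0.0, 0.0)
        assert classify_selectivity(p) == "nonresponsive"
        assert p.rc_ri is None

    def test_missing_magnitude_errors(self):
        p = self.profile_with(1.0, 1.0)
        del p.response_magnitude["inflation"]
        with pytest.raises(ValueError, match="inflation"):
            classify_selectivity(p)


class TestTally:
    def test_counts_partition_and_percentages(self):
        t = tally_responses(
            counts={"compression_only": 91, "inflation_only": 64, "both": 29,
                    "neither": 1119}
        )
        assert t.total == 1303
        assert t.any_compression == 120 and t.any_inflation == 93
        p = t.percentages()
        assert p["any_compression"] == 9.2
        assert p["any_inflation"] == 7.1
        assert p["compression_stretch_insensitive"] == 75.8
        assert p["compression_also_inflation"] == 24.2

    def test_flags_route_equals_counts_route(self):
        flags = [(True, False)] * 3 + [(False, True)] * 2 + [(True, True)] + \
            [(False, False)] * 4
        t = tally_responses(flags)
        assert (t.compression_only, t.inflation_only, t.both, t.neither) == (3, 2, 1, 4)
        assert t.total == 10

    def test_zero_responder_cohort(self):
        t = tally_responses(counts={"neither": 50})
        p = t.percentages()
        assert p["any_compression"] == 0.0 and p["neither"] == 100.0
        assert "compression_stretch_insensitive" not in p

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unexpected"):
            tally_responses(counts={"maybe": 1})

    def test_full_pipeline_tally_matches_ground_truth(self, calcium_session):
        params, traces, truth = calcium_session
        profiles = analyze_session(traces, list(params.epochs))
        healthy = [p for p in profiles if not p.excluded_unhealthy]
        t = tally_responses(
            (p.responsive["compression"], p.responsive["inflation"]) for p in healthy
        )
        assert (t.compression_only, t.inflation_only, t.both) == (10, 5, 2)
        assert t.total == 98  # 100 ROIs minus 2 unhealthy
        for p in profiles:
            assert p.selectivity == truth.selectivity[p.roi_id]
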