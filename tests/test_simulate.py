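"""Design tables, subject profiles, planted dynamics, projection, artifacts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepmeg import anatomy, pipeline, simulate
from deepmeg.errors import InvalidConfigError


class TestDesign:
    def test_face_trial_counts(self):
        design = simulate.generate_design(seed=0)
        faces = simulate.face_trials(design)
        assert len(faces) == 384
        counts = faces.groupby(["emotion", "gaze"]).size()
        assert (counts == 96).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_every_block_is_a_full_factorial(self, seed):
        faces = simulate.face_trials(simulate.generate_design(seed))
        for _, block in faces.groupby("block"):
            cell_counts = block.groupby(["identity", "emotion", "gaze"]).size()
            assert len(cell_counts) == 64
            assert (cell_counts == 1).all()

    def test_timing_invariants(self):
        design = simulate.generate_design(seed=5)
        assert design["fixation_duration_s"].between(0.7, 0.9).all()
        assert design["isi_s"].between(1.0, 2.0).all()
        assert design["onset_s"].is_monotonic_increasing

    def test_determinism_and_seed_sensitivity(self):
        d1 = simulate.generate_design(seed=7)
        d2 = simulate.generate_design(seed=7)
        d3 = simulate.generate_design(seed=8)
        pd.testing.assert_frame_equal(d1, d2)
        assert not d1["is_target"].equals(d3["is_target"])

    def test_target_count_mean_is_60(self):
        totals = [
            simulate.generate_design(seed)["is_target"].sum() for seed in range(800)
        ]
        assert np.mean(totals) == pytest.approx(60.0, abs=0.5)
        assert min(totals) >= 6 * 8 and max(totals) <= 6 * 12


class TestSubjectProfiles:
    def test_anxiety_mean_and_range(self):
        profiles = simulate.generate_subject_profiles(10_000, seed=0)
        scores = np.array([p.anxiety_score for p in profiles])
        assert scores.mean() == pytest.approx(26.0, abs=0.2)
        assert scores.min() >= 20.0 and scores.max() <= 38.0

    def test_zero_slope_gives_unit_gains(self):
        profiles = simulate.generate_subject_profiles(
            20, seed=1, anxiety_slopes={s: 0.0 for s in simulate.STRUCTURES}
        )
        for p in profiles:
            assert all(g == 1.0 for g in p.gain_multipliers.values())

    def test_gain_is_linear_in_score(self):
        profiles = simulate.generate_subject_profiles(50, seed=2)
        slope = simulate.DEFAULT_SOURCE_PARAMS["amygdala"].anxiety_slope
        for p in profiles:
            assert p.gain_multipliers["amygdala"] == pytest.approx(
                1.0 + slope * (p.anxiety_score - 26.0)
            )

    def test_truncation_range_must_contain_mean(self):
        with pytest.raises(InvalidConfigError):
            simulate.generate_subject_profiles(
                5, seed=0, anxiety=simulate.AnxietyConfig(mean=50.0)
            )


class TestSourceTimecourses:
    @pytest.fixture()
    def flat_profile(self):
        return simulate.SubjectProfile("sub01", 26.0, {s: 1.0 for s in simulate.STRUCTURES})

    @pytest.fixture()
    def tiny_design(self):
        design = simulate.generate_design(seed=3)
        return design[design["block"] == 1].reset_index(drop=True)

    def _nojitter(self, params):
        from dataclasses import replace

        return {
            s: replace(p, trial_amplitude_jitter=0.0, trial_latency_jitter_s=0.0)
            for s, p in params.items()
        }

    def test_null_model_is_condition_blind(self, tiny_design, flat_profile):
        params = self._nojitter(simulate.null_source_params())
        traces = simulate.simulate_source_timecourses(
            tiny_design, flat_profile, params, seed=0
        )
        faces = traces.design
        ref = traces.amplitudes[0]
        for t in range(1, len(faces)):
            np.testing.assert_allclose(traces.amplitudes[t], ref, rtol=1e-12)

    def test_early_emotion_effect_scales_peak_by_exact_ratio(
        self, tiny_design, flat_profile
    ):
        from dataclasses import replace

        params = self._nojitter(simulate.null_source_params())
        # isolate the early component: no sustained term under the peak
        params["amygdala"] = replace(
            params["amygdala"], emotion_effect_early=0.3, sustained_fraction=0.0
        )
        traces = simulate.simulate_source_timecourses(
            tiny_design, flat_profile, params, seed=0
        )
        faces = traces.design
        peak = np.argmin(np.abs(traces.times - 0.140))
        fearful = traces.amplitudes[faces["emotion"] == "fearful", 0, 0, peak]
        neutral = traces.amplitudes[faces["emotion"] == "neutral", 0, 0, peak]
        assert fearful.mean() / neutral.mean() == pytest.approx(1.3, rel=1e-9)

    def test_grand_average_peak_latency_in_range(self, tiny_design, flat_profile):
        traces = simulate.simulate_source_timecourses(
            tiny_design, flat_profile, seed=4
        )
        grand = traces.amplitudes[:, 0].mean(axis=(0, 1))  # amygdala, both hemis
        peak_t = traces.times[np.argmax(grand)]
        assert 0.100 <= peak_t <= 0.170

    def test_condition_multiplier_layout(self):
        p = simulate.DEFAULT_SOURCE_PARAMS["amygdala"]
        e_fd, s_fd, l_fd = simulate.condition_multipliers(p, "fearful", "direct", "right")
        e_fa, s_fa, l_fa = simulate.condition_multipliers(p, "fearful", "averted", "right")
        e_nd, s_nd, _ = simulate.condition_multipliers(p, "neutral", "direct", "right")
        _, s_fd_l, _ = simulate.condition_multipliers(p, "fearful", "direct", "left")
        assert e_fd == e_fa > e_nd  # early effect is emotion only
        assert s_fd > s_nd > s_fa  # gaze + interaction on sustained term
        assert s_fd > s_fd_l  # interaction is right-lateralized
        assert l_fd == l_fa > 1.0  # late emotion extra


@pytest.fixture(scope="module")
def setup(small_model):
    activation = pipeline.build_activation(small_model)
    design = simulate.generate_design(seed=2)
    design = design[design["block"] == 1].reset_index(drop=True)
    profile = simulate.SubjectProfile(
        "sub01", 26.0, {s: 1.0 for s in simulate.STRUCTURES}
    )
    traces = simulate.simulate_source_timecourses(design, profile, seed=1)
    return small_model, activation, traces


@pytest.fixture(scope="module")
def clean_trials(setup):
    model, activation, traces = setup
    return simulate.project_to_sensors(traces, model.gain, activation, 1e-14)


class TestProjection:
    def test_noiseless_projection_is_exact(self, setup):
        model, activation, traces = setup
        trials = simulate.project_to_sensors(
            traces, model.gain, activation, noise_sd=0.0, seed=0
        )
        topo = activation.topographies[("amygdala", "right")]
        manual = sum(
            np.outer(
                activation.topographies[(s, h)],
                traces.amplitudes[0, si, hi],
            )
            for si, s in enumerate(simulate.STRUCTURES)
            for hi, h in enumerate(simulate.HEMISPHERES)
        )
        np.testing.assert_allclose(trials.data[0], manual, rtol=1e-10)
        assert topo.shape == (model.sensors.n_channels,)

    def test_noise_scaling(self, setup):
        model, activation, traces = setup
        t1 = simulate.project_to_sensors(traces, model.gain, activation, 1e-14, seed=5)
        t2 = simulate.project_to_sensors(traces, model.gain, activation, 2e-14, seed=5)
        clean = simulate.project_to_sensors(traces, model.gain, activation, 0.0, seed=5)
        r1 = (t1.data - clean.data).std()
        r2 = (t2.data - clean.data).std()
        assert r2 / r1 == pytest.approx(2.0, rel=0.02)

    def test_fixed_seed_bit_identical(self, setup):
        model, activation, traces = setup
        a = simulate.project_to_sensors(traces, model.gain, activation, 1e-14, seed=9)
        b = simulate.project_to_sensors(traces, model.gain, activation, 1e-14, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_photodiode_onset_is_trigger_plus_delay(self, setup):
        model, activation, traces = setup
        trials = simulate.project_to_sensors(traces, model.gain, activation, 0.0)
        assert trials.photodiode_sample - trials.trigger_sample == 25  # 20 ms @ 1250 Hz

    def test_hdf5_roundtrip(self, setup, tmp_path):
        model, activation, traces = setup
        trials = simulate.project_to_sensors(traces, model.gain, activation, 1e-14)
        path = tmp_path / "trials.h5"
        simulate.save_trials(trials, path)
        back = simulate.load_trials(path)
        np.testing.assert_array_equal(back.data, trials.data)
        assert back.photodiode_sample == trials.photodiode_sample
        assert len(back.design) == len(trials.design)


class TestArtifacts:
    @pytest.mark.parametrize("rate,expected", [(0.0, 0), (1.0, 64)])
    def test_rate_extremes(self, clean_trials, small_model, rate, expected):
        out = simulate.inject_artifacts(clean_trials, small_model.sensors, rate, seed=0)
        assert out.artifact_flags.sum() == expected

    def test_flag_rate_matches_binomial_oracle(self, clean_trials, small_model):
        rate = 0.1
        fracs = [
            simulate.inject_artifacts(
                clean_trials, small_model.sensors, rate, seed=s
            ).artifact_flags.mean()
            for s in range(300)
        ]
        # binomial oracle: mean rate 0.1, se = sqrt(p(1-p)/(64*300))
        se = np.sqrt(rate * (1 - rate) / (64 * 300))
        assert np.mean(fracs) == pytest.approx(rate, abs=4 * se)

    def test_blinks_are_frontal_and_large(self, clean_trials, small_model):
        out = simulate.inject_artifacts(
            clean_trials, small_model.sensors, 1.0, blink_amplitude=1e-11, seed=1
        )
        delta = np.abs(out.data - clean_trials.data).max(axis=2)  # trials × channels
        y = small_model.sensors.inner_coil_position[:, 1]
        front = delta[:, np.argmax(y)]
        back = delta[:, np.argmin(y)]
        assert np.all(front > 10 * back.max())
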