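"""Simulate one subject's MEG session.

Generates the 6-block × 64-face-trial design (plus blue-dot targets), a
subject anxiety profile, condition-dependent source time courses (early
amygdala peak ~140 ms, sustained 190–350 ms activity), and projects one
block to the sensors with white noise and blink artifacts.
"""

import numpy as np

from deepmeg import pipeline, simulate

design = simulate.generate_design(seed=1)
faces = simulate.face_trials(design)
print(f"trials: {len(design)} total, {len(faces)} faces, "
      f"{int(design['is_target'].sum())} targets")
print(faces.groupby(["emotion", "gaze"]).size().rename("n").to_string())

profile = simulate.generate_subject_profiles(1, seed=2)[0]
print(f"\nsubject anxiety score: {profile.anxiety_score:.1f} STAI units "
      f"(amygdala gain {profile.gain_multipliers['amygdala']:.3f})")

block1 = design[design["block"] == 1].reset_index(drop=True)
traces = simulate.simulate_source_timecourses(block1, profile, seed=3)
grand = traces.amplitudes[:, 0].mean(axis=(0, 1))  # amygdala, both hemispheres
peak_ms = 1e3 * traces.times[np.argmax(grand)]
print(f"amygdala grand-average peak: {1e9 * grand.max():.1f} nAm at {peak_ms:.0f} ms")

model = pipeline.build_source_model(
    pipeline.GeometryConfig(cortex_vertices=2000), patch_vertices=20
)
activation = pipeline.build_activation(model)
trials = simulate.project_to_sensors(
    traces, model.gain, activation, noise_sd=50e-15, seed=4
)
trials = simulate.inject_artifacts(trials, model.sensors, blink_rate=0.05, seed=5)
print(f"\nsensor data: {trials.data.shape} (trials x channels x samples), "
      f"{int(trials.artifact_flags.sum())} trials blink-contaminated")
print(f"peak |field| {1e15 * np.abs(trials.data).max():.0f} fT; "
      f"photodiode onset = trigger + "
      f"{trials.photodiode_sample - trials.trigger_sample} samples (20 ms)")
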