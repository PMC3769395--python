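"""From sensor trials to amygdala measurements for one subject.

Preprocesses one condition's trials into an evoked field (delay
correction, rejection, epoching, baseline, 40 Hz low-pass), applies the
depth-weighted minimum-norm inverse, extracts the per-hemisphere amygdala
norm time course, and prints the five windowed mean amplitudes.
"""

import numpy as np

from deepmeg import extract, inverse, pipeline, preprocess, simulate

model = pipeline.build_source_model(
    pipeline.GeometryConfig(cortex_vertices=2000), patch_vertices=20
)
activation = pipeline.build_activation(model)

design = simulate.generate_design(seed=1)
block = design[design["block"] == 1].reset_index(drop=True)
profile = simulate.generate_subject_profiles(1, seed=2)[0]
traces = simulate.simulate_source_timecourses(block, profile, seed=3)
trials = simulate.project_to_sensors(
    traces, model.gain, activation, noise_sd=50e-15, seed=4
)

trials = preprocess.correct_delay(trials, 0.020)
kept, report = preprocess.reject_artifacts(trials)
evoked = preprocess.epoch_average(kept, ("fearful", "direct"))
print(f"evoked ('fearful','direct'): {evoked.n_trials_averaged} trials, "
      f"{evoked.data.shape[0]} channels x {evoked.data.shape[1]} samples")

operator = inverse.build_operator(model.gain)
print(f"wMNE operator: lambda = {operator.lambda_value:.3e} "
      f"(10% of the weighted lead field's max singular value)")
estimate = inverse.apply_inverse(operator, evoked)

amy = extract.amygdala_timecourse(estimate, model.amygdala["right"])
amy.update(extract.amygdala_timecourse(estimate, model.amygdala["left"]))
for hemi in ("left", "right"):
    peak_ms = 1e3 * estimate.times[np.argmax(amy[hemi])]
    print(f"{hemi:>5} amygdala peak at {peak_ms:.0f} ms")
    rows = extract.window_means(amy[hemi], estimate.times)
    for _, r in rows.iterrows():
        print(f"        {r['window']:>8} ms: {1e9 * r['value']:.3f} nAm")

# Window means are the quantities the group-level ANCOVA consumes; the
# estimated amplitudes are biased low relative to the planted 10 nAm source
# (minimum-norm amplitude spread), but condition contrasts are preserved.
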