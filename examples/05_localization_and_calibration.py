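"""Method-performance studies: localization error and statistical calibration.

1. Deep-source localization: an isolated amygdala node (10 nAm, tangential)
   is projected with noise at SNR 10; the amplitude-weighted center of
   gravity of the estimated deep-source norms is compared with the truth.
2. Calibration: type-I error of every 1-df ANCOVA effect under the null
   generator, and detection power for the planted effect layout.
"""

from deepmeg import pipeline, simulate

loc = pipeline.localization_error_study(n_seeds=100, seed=0, snr=10.0)
print(f"deep-source localization error: {loc['mean_cm']:.2f} cm "
      f"(sd {loc['sd_cm']:.2f}) over 100 noise seeds — inside the 1 cm "
      f"bound expected for isolated amygdala activations")

null_rates = pipeline.detection_rates(
    1000, 15, pipeline.null_amygdala_params(), seed=1, windows=("130-170",)
)
print("\nnull type-I error (nominal 5%), 1000 cohorts:")
for _, row in null_rates.iterrows():
    print(f"  {row['effect']:>24}: {100 * row['rate']:.1f}%")

params = simulate.DEFAULT_SOURCE_PARAMS["amygdala"]
early = pipeline.detection_rates(200, 15, params, seed=2, windows=("130-170",))
late = pipeline.gaze_interaction_rates(200, 15, params, seed=3)
emo = early.loc[early["effect"] == "emotion", "rate"].iloc[0]
print(f"\npower over 200 cohorts at default effect sizes:")
print(f"  early emotion effect:       {100 * emo:.0f}%")
for _, row in late.iterrows():
    print(f"  sustained {row['effect']}: {100 * row['rate']:.0f}%")
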