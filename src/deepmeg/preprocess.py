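"""Event-related field (ERF) preprocessing.

Trial segments become per-condition evoked fields: the projector delay is
folded into the event onsets, contaminated trials are rejected by a
peak-to-peak amplitude threshold, surviving trials are epoched at
[-0.2, +0.6] s around the corrected onset, averaged per condition, baseline
corrected over the 200 ms preceding face onset, and low-pass filtered at
40 Hz with a zero-phase 4th-order Butterworth filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import EmptyConditionError, InvalidConfigError
from .simulate import TrialData

logger = logging.getLogger(__name__)

EPOCH_TMIN, EPOCH_TMAX = -0.2, 0.6
BASELINE = (-0.2, 0.0)  # half-open at 0
DEFAULT_LOWPASS_HZ = 40.0
FILTER_ORDER = 4
#: default rejection threshold, chosen far above clean synthetic trials
DEFAULT_REJECT_THRESHOLD_T = 1.5e-12


@dataclass
class Evoked:
    """Condition-averaged channel × time ERF."""

    condition: tuple  # (emotion, gaze)
    data: np.ndarray  # (n_channels, n_times), tesla
    times: np.ndarray  # seconds relative to (corrected) face onset
    n_trials_averaged: int
    baseline: tuple = BASELINE
    filter_descriptor: dict = field(default_factory=dict)

    @property
    def sfreq(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])


def correct_delay(trials: TrialData, delay_s: float) -> TrialData:
    """Shift event onsets to the photodiode-verified time (trigger + delay).

    A delay that is not an integer number of samples is rounded to the
    nearest sample (logged).
    """
    shift = delay_s * trials.sfreq
    n = int(round(shift))
    if abs(shift - n) > 1e-9:
        logger.info("delay %.6f s rounded to %d samples at %g Hz", delay_s, n, trials.sfreq)
    return TrialData(
        data=trials.data,
        times=trials.times,
        sfreq=trials.sfreq,
        trigger_sample=trials.trigger_sample,
        photodiode_sample=trials.trigger_sample + n,
        design=trials.design,
        artifact_flags=trials.artifact_flags,
        metadata=dict(trials.metadata, delay_s=delay_s),
    )


def _epoch_slice(trials: TrialData) -> slice:
    onset = trials.photodiode_sample
    start = onset + int(round(EPOCH_TMIN * trials.sfreq))
    stop = onset + int(round(EPOCH_TMAX * trials.sfreq)) + 1
    if start < 0 or stop > trials.data.shape[2]:
        raise InvalidConfigError("trial segments do not cover the epoch window")
    return slice(start, stop)


def reject_artifacts(
    trials: TrialData, peak_to_peak_threshold: float = DEFAULT_REJECT_THRESHOLD_T
) -> tuple[TrialData, pd.DataFrame]:
    """Drop trials whose peak-to-peak amplitude exceeds the threshold.

    A trial is rejected when *any* channel's peak-to-peak amplitude within
    the epoch window exceeds the threshold.  Returns the kept trials and a
    per-condition report of kept counts.
    """
    if peak_to_peak_threshold <= 0:
        raise InvalidConfigError("rejection threshold must be positive")
    sl = _epoch_slice(trials)
    seg = trials.data[:, :, sl]
    ptp = seg.max(axis=2) - seg.min(axis=2)
    bad = (ptp > peak_to_peak_threshold).any(axis=1)
    keep = ~bad
    kept = TrialData(
        data=trials.data[keep],
        times=trials.times,
        sfreq=trials.sfreq,
        trigger_sample=trials.trigger_sample,
        photodiode_sample=trials.photodiode_sample,
        design=trials.design[keep].reset_index(drop=True),
        artifact_flags=trials.artifact_flags[keep],
        metadata=dict(trials.metadata, reject_threshold=peak_to_peak_threshold),
    )
    counts = (
        trials.design.assign(kept=keep)
        .groupby(["emotion", "gaze"], sort=True)["kept"]
        .agg(["sum", "count"])
        .rename(columns={"sum": "kept", "count": "total"})
        .reset_index()
    )
    return kept, counts


def lowpass_filter(
    data: np.ndarray, sfreq: float, cutoff_hz: float, order: int = FILTER_ORDER
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along the last axis."""
    b, a = butter(order, cutoff_hz, btype="low", fs=sfreq)
    return filtfilt(b, a, data, axis=-1)


def baseline_correct(data: np.ndarray, times: np.ndarray, baseline=BASELINE) -> np.ndarray:
    """Subtract each channel's mean over the (half-open) baseline window."""
    mask = (times >= baseline[0]) & (times < baseline[1])
    return data - data[..., mask].mean(axis=-1, keepdims=True)


def epoch_average(
    trials: TrialData,
    condition: tuple,
    filter_cutoff_hz: float | None = DEFAULT_LOWPASS_HZ,
) -> Evoked:
    """Average one condition's epochs into an Evoked field.

    Epochs are cut at [-0.2, +0.6] s around the corrected onset, averaged,
    low-pass filtered (zero-phase), and baseline corrected over the 200 ms
    preceding onset.  (Both operations are linear so their order does not
    affect anything downstream; correcting last keeps the baseline-mean
    invariant exact.)
    """
    emotion, gaze = condition
    sel = ((trials.design["emotion"] == emotion) & (trials.design["gaze"] == gaze)).to_numpy()
    if not sel.any():
        raise EmptyConditionError(f"no trials for condition {condition}")
    sl = _epoch_slice(trials)
    epochs = trials.data[sel][:, :, sl].astype(float)
    times = (
        np.arange(sl.stop - sl.start) / trials.sfreq + EPOCH_TMIN
    )
    avg = epochs.mean(axis=0)
    descriptor = {"type": "none"}
    if filter_cutoff_hz is not None:
        avg = lowpass_filter(avg, trials.sfreq, filter_cutoff_hz)
        descriptor = {
            "type": "butterworth",
            "order": FILTER_ORDER,
            "cutoff_hz": filter_cutoff_hz,
            "zero_phase": True,
        }
    avg = baseline_correct(avg, times)
    return Evoked(
        condition=condition,
        data=avg,
        times=times,
        n_trials_averaged=int(sel.sum()),
        filter_descriptor=descriptor,
    )


def save_evoked(evoked: Evoked, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=evoked.data)
        f.create_dataset("times", data=evoked.times)
        f.attrs["emotion"], f.attrs["gaze"] = evoked.condition
        f.attrs["n_trials_averaged"] = evoked.n_trials_averaged


def load_evoked(path) -> Evoked:
    import h5py

    with h5py.File(path, "r") as f:
        return Evoked(
            condition=(str(f.attrs["emotion"]), str(f.attrs["gaze"])),
            data=f["data"][()],
            times=f["times"][()],
            n_trials_averaged=int(f.attrs["n_trials_averaged"]),
        )
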